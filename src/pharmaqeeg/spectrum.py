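"""Power-spectrum container and estimation.

Spectra are estimated on "Still" epochs with a Welch-style averaged modified
periodogram, then transformed to decibels and cleaned of mains (line-noise)
harmonics.  The frequency grid runs 0.1-190 Hz in 0.5 Hz steps by default;
the ``leakage`` knob (0-1) maps monotonically onto the aggressiveness of a
Kaiser taper (beta = 40 * (1 - leakage), 50% overlap), so leakage 0.85 is a
mild taper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "PowerSpectrum",
    "default_grid",
    "compute_spectrum",
    "to_decibels",
    "from_decibels",
    "remove_line_noise",
]

#: analysis range, Hz
FMIN_DEFAULT = 0.1
FMAX_DEFAULT = 190.0
RESOLUTION_DEFAULT = 0.5
LEAKAGE_DEFAULT = 0.85
OVERLAP_DEFAULT = 0.775  # window overlap fraction


def default_grid(
    fmin: float = FMIN_DEFAULT,
    fmax: float = FMAX_DEFAULT,
    resolution: float = RESOLUTION_DEFAULT,
) -> np.ndarray:
    """Frequency grid ``fmin, fmin+resolution, ...`` up to ``fmax``."""
    n = int(np.floor((fmax - fmin) / resolution + 1e-9)) + 1
    return fmin + resolution * np.arange(n)


@dataclass(frozen=True)
class PowerSpectrum:
    """A single-channel power spectrum on a fixed frequency grid.

    Parameters
    ----------
    freqs : ndarray
        Strictly increasing frequency grid in Hz.
    power : ndarray
        Per-bin power, linear (density) or decibel scale per ``scale``.
    scale : {"linear", "db"}
    n_epochs : int
        Number of data epochs pooled into the estimate (0 for model spectra).
    seconds : float
        Total seconds of signal analyzed.
    meta : dict
        Provenance (estimator settings, taper choice, ...).
    """

    freqs: np.ndarray
    power: np.ndarray
    scale: str = "db"
    n_epochs: int = 0
    seconds: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if freqs.ndim != 1 or power.shape != freqs.shape:
            raise ValueError("freqs and power must be 1-d arrays of equal length")
        if freqs.size and np.any(np.diff(freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.scale not in ("linear", "db"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if power.size and not np.all(np.isfinite(power)):
            raise ValueError("power values must be finite")

    def with_power(self, power: np.ndarray, scale: str | None = None) -> "PowerSpectrum":
        return replace(self, power=np.asarray(power, float), scale=scale or self.scale)


def compute_spectrum(
    epochs,
    fs: float,
    fmin: float = FMIN_DEFAULT,
    fmax: float = FMAX_DEFAULT,
    resolution: float = RESOLUTION_DEFAULT,
    leakage: float = LEAKAGE_DEFAULT,
) -> PowerSpectrum:
    """Averaged modified periodogram over sliding windows pooled across epochs.

    Window length is set by the requested resolution (``nperseg = fs /
    resolution``); windows from all epochs are pooled with equal weight per
    window, so longer epochs contribute proportionally.  Epochs shorter than
    one window are skipped with a warning.

    Parameters
    ----------
    epochs : array or sequence of 1-d arrays
        Signal epochs in consistent units (mV).
    fs : float
        Sampling rate, Hz.
    leakage : float in [0, 1]
        Taper aggressiveness; mapped to a Kaiser window with
        ``beta = 40 * (1 - leakage)``.

    Returns
    -------
    PowerSpectrum
        Linear-scale power spectral density on the exact requested grid.
    """
    if isinstance(epochs, np.ndarray) and epochs.ndim == 1:
        epochs = [epochs]
    elif len(epochs) and np.isscalar(epochs[0]):
        epochs = [np.asarray(epochs, dtype=float)]
    if not 0.0 <= leakage <= 1.0:
        raise ValueError("leakage must lie in [0, 1]")
    if fs <= 2 * fmax:
        raise ValueError(f"sampling rate {fs} Hz cannot resolve {fmax} Hz")
    nperseg = int(round(fs / resolution))
    beta = 40.0 * (1.0 - leakage)
    window = sps.windows.kaiser(nperseg, beta)
    noverlap = int(round(OVERLAP_DEFAULT * nperseg))
    step = nperseg - noverlap

    pooled = None
    n_windows_total = 0
    used_epochs = 0
    seconds = 0.0
    welch_freqs = None
    for i, epoch in enumerate(epochs):
        epoch = np.asarray(epoch, dtype=float)
        if epoch.size < nperseg:
            warnings.warn(
                f"epoch {i} ({epoch.size / fs:.2f} s) shorter than the "
                f"{nperseg / fs:.2f} s analysis window; skipped",
                stacklevel=2,
            )
            continue
        f, pxx = sps.welch(
            epoch, fs=fs, window=window, noverlap=noverlap, detrend="constant"
        )
        n_win = 1 + (epoch.size - nperseg) // step
        pooled = pxx * n_win if pooled is None else pooled + pxx * n_win
        n_windows_total += n_win
        used_epochs += 1
        seconds += epoch.size / fs
        welch_freqs = f
    if pooled is None:
        raise ValueError("no epoch was long enough for a single analysis window")
    pooled /= n_windows_total

    grid = default_grid(fmin, fmax, resolution)
    power = np.interp(grid, welch_freqs, pooled)
    meta = {
        "estimator": "welch",
        "window": "kaiser",
        "kaiser_beta": beta,
        "leakage": leakage,
        "nperseg": nperseg,
        "noverlap": noverlap,
        "overlap_fraction": OVERLAP_DEFAULT,
        "n_windows": int(n_windows_total),
        "fs": fs,
    }
    return PowerSpectrum(
        grid, power, scale="linear", n_epochs=used_epochs, seconds=seconds, meta=meta
    )


def to_decibels(spectrum: PowerSpectrum) -> PowerSpectrum:
    """``10 * log10(power)``; requires a linear-scale spectrum with power > 0."""
    if spectrum.scale != "linear":
        raise ValueError("to_decibels expects a linear-scale spectrum")
    if np.any(spectrum.power <= 0):
        bad = int(np.argmax(spectrum.power <= 0))
        raise ValueError(
            f"non-positive power at bin {bad} ({spectrum.freqs[bad]:.2f} Hz); "
            "upstream estimate is invalid"
        )
    return spectrum.with_power(10.0 * np.log10(spectrum.power), scale="db")


def from_decibels(spectrum: PowerSpectrum) -> PowerSpectrum:
    """Inverse of :func:`to_decibels`."""
    if spectrum.scale != "db":
        raise ValueError("from_decibels expects a dB-scale spectrum")
    return spectrum.with_power(10.0 ** (spectrum.power / 10.0), scale="linear")


def remove_line_noise(
    spectrum: PowerSpectrum, base: float = 50.0, halfwidth: float = 1.0
) -> PowerSpectrum:
    """Interpolate across mains harmonics (base, 2*base, ... up to fmax).

    Bins within ``+-halfwidth`` of each harmonic are replaced by linear
    interpolation between the nearest flanking bins; all other bins are
    unchanged.  Idempotent.
    """
    if spectrum.scale != "db":
        raise ValueError("remove_line_noise expects a dB-scale spectrum")
    freqs = spectrum.freqs
    power = spectrum.power.copy()
    fmax = freqs[-1]
    harmonic = base
    while harmonic <= fmax + halfwidth:
        inside = np.abs(freqs - harmonic) <= halfwidth
        if inside.any():
            lo_candidates = np.nonzero(~inside & (freqs < harmonic - halfwidth))[0]
            hi_candidates = np.nonzero(~inside & (freqs > harmonic + halfwidth))[0]
            idx = np.nonzero(inside)[0]
            if lo_candidates.size and hi_candidates.size:
                lo, hi = lo_candidates[-1], hi_candidates[0]
                power[idx] = np.interp(
                    freqs[idx], [freqs[lo], freqs[hi]], [power[lo], power[hi]]
                )
            elif lo_candidates.size:
                warnings.warn(
                    f"notch at {harmonic:g} Hz touches the grid edge; "
                    "extrapolating from the low side",
                    stacklevel=2,
                )
                power[idx] = power[lo_candidates[-1]]
            elif hi_candidates.size:
                warnings.warn(
                    f"notch at {harmonic:g} Hz touches the grid edge; "
                    "extrapolating from the high side",
                    stacklevel=2,
                )
                power[idx] = power[hi_candidates[0]]
        harmonic += base
    meta = dict(spectrum.meta)
    meta["line_noise"] = {"base": base, "halfwidth": halfwidth}
    return replace(spectrum, power=power, meta=meta)
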