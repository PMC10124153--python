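"""Per-band metrics of the reconstructed periodic component.

Within each band of a condition-specific scheme, the Gaussian peaks whose
*center* falls inside the band limits are summed into a band curve, from
which three metrics are taken: peak amplitude (curve maximum, dB), modal
frequency (frequency of that maximum, Hz — absent when the band holds no
peak, since no frequency can be measured where there is no amplitude), and
AUC (trapezoidal area of the curve over the band interval, dB*Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BandScheme
from .decomposition import SpectralDecomposition, eval_gaussians

__all__ = ["BandMetrics", "reconstruct_band_curve", "band_parameters",
           "band_metrics_table"]

#: evaluation grid step inside a band, Hz
BAND_GRID_STEP = 0.01


@dataclass(frozen=True)
class BandMetrics:
    """Metrics of one band's reconstructed periodic curve."""

    band: str
    amplitude: float            # dB, >= 0
    modal_frequency: float | None  # Hz, None when amplitude == 0
    auc: float                  # dB*Hz, >= 0
    n_peaks: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.auc < 0:
            raise ValueError("amplitude and AUC must be non-negative")
        if self.amplitude == 0 and self.modal_frequency is not None:
            raise ValueError("modal frequency must be absent when amplitude is 0")


def reconstruct_band_curve(
    fit: SpectralDecomposition | list,
    scheme: BandScheme,
    band: str,
    step: float = BAND_GRID_STEP,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Sum of the fit's Gaussians whose center lies inside ``band``.

    Membership is by center frequency (half-open [low, high); the top band
    includes its upper edge).  Returns (freqs, curve, n_peaks); the curve is
    identically zero when no peak qualifies.
    """
    bands = scheme.bands
    if band not in bands:
        raise ValueError(f"unknown band {band!r}; scheme has {list(bands)}")
    lo, hi = bands[band]
    peaks = getattr(fit, "peaks", fit)
    top = hi == scheme.fmax
    members = [p for p in peaks if lo <= p.mu < hi or (top and p.mu == hi)]
    freqs = np.arange(lo, hi + step / 2, step)
    curve = eval_gaussians(members, freqs)
    return freqs, curve, len(members)


def band_parameters(
    freqs: np.ndarray, curve: np.ndarray, band: str = "", n_peaks: int = 0
) -> BandMetrics:
    """Amplitude / modal frequency / AUC of one band curve.

    The modal frequency is the argmax refined by a parabolic fit through
    the three samples around it; a zero curve is the valid empty case
    (amplitude 0, AUC 0, modal frequency absent).
    """
    curve = np.asarray(curve, dtype=float)
    amplitude = float(curve.max(initial=0.0))
    if amplitude <= 0.0:
        return BandMetrics(band=band, amplitude=0.0, modal_frequency=None,
                           auc=0.0, n_peaks=n_peaks)
    i = int(np.argmax(curve))
    modal = float(freqs[i])
    if 0 < i < curve.size - 1:
        y0, y1, y2 = curve[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            modal += 0.5 * (y0 - y2) / denom * float(freqs[1] - freqs[0])
    auc = float(np.trapezoid(curve, freqs))
    return BandMetrics(band=band, amplitude=amplitude, modal_frequency=modal,
                       auc=max(auc, 0.0), n_peaks=n_peaks)


def band_metrics_table(
    fit: SpectralDecomposition,
    scheme: BandScheme,
    animal: str = "",
    region: str = "",
    condition: str | None = None,
) -> pd.DataFrame:
    """Tidy long-format metrics for every band of the scheme.

    Columns: animal, region, condition, band, amplitude_db, modal_freq_hz,
    auc, n_peaks — the input shape for the stats stage and external ANOVA.
    """
    condition = scheme.condition if condition is None else condition
    rows = []
    for band in scheme.labels:
        freqs, curve, n = reconstruct_band_curve(fit, scheme, band)
        m = band_parameters(freqs, curve, band=band, n_peaks=n)
        rows.append(
            {
                "animal": animal,
                "region": region,
                "condition": condition,
                "band": band,
                "amplitude_db": m.amplitude,
                "modal_freq_hz": np.nan if m.modal_frequency is None else m.modal_frequency,
                "auc": m.auc,
                "n_peaks": m.n_peaks,
            }
        )
    return pd.DataFrame(rows)
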