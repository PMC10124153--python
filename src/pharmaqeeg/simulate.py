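"""Ground-truthed synthetic data: spectra, EEG-like time series, locomotion
traces, and exposure-linked cohorts.

The generator emulates the statistical structure the analysis assumes —
decibel spectra equal to a Lorentzian-family aperiodic background plus
Gaussian oscillatory bumps plus noise; time-domain signals realizing such
spectra (spectral shaping of white noise, which guarantees the target
spectrum in expectation); rectangular amplitude artifacts with analytically
exact masks; straight-line locomotion bouts; and paired cohorts in which
compound-session spectral parameters drift monotonically (linearly by
default) with plasma exposure, plus additive experiment/age covariate
effects.  Every draw is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decomposition import FAMILIES, GaussianPeak, eval_aperiodic, eval_gaussians
from .spectrum import FMAX_DEFAULT, FMIN_DEFAULT, PowerSpectrum, default_grid

__all__ = [
    "GroundTruth",
    "AnimalRecord",
    "SyntheticCohort",
    "make_spectrum",
    "make_timeseries",
    "inject_artifacts",
    "make_tracking",
    "make_cohort",
    "DEFAULT_VEHICLE_TRUTH",
]


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters of one spectrum.

    ``aperiodic`` maps parameter names to values for ``family`` (offset
    ``b`` in dB, exponent ``X``, knee ``k``, optional decay amplitude ``c``
    in dB and rate ``d`` per Hz); ``peaks`` are Gaussian oscillatory bumps;
    ``noise_sd`` is per-bin dB noise.
    """

    family: str = "lorentzian"
    aperiodic: dict = field(default_factory=lambda: {"b": 0.0, "X": 1.0, "k": 0.0})
    peaks: tuple = ()
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown aperiodic family {self.family!r}")
        missing = set(FAMILIES[self.family]) - set(self.aperiodic)
        if missing:
            raise ValueError(f"family {self.family!r} missing parameters {missing}")
        if self.aperiodic["X"] <= 0:
            raise ValueError("exponent X must be positive")
        if self.aperiodic.get("k", 0.0) < 0:
            raise ValueError("knee k must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        peaks = tuple(
            p if isinstance(p, GaussianPeak) else GaussianPeak(*p)
            for p in self.peaks
        )
        for p in peaks:
            if not (FMIN_DEFAULT <= p.mu <= FMAX_DEFAULT):
                raise ValueError(
                    f"peak center {p.mu} Hz outside the analysis range "
                    f"[{FMIN_DEFAULT}, {FMAX_DEFAULT}] Hz"
                )
        object.__setattr__(self, "peaks", peaks)

    def curve(self, freqs) -> np.ndarray:
        """Noiseless model spectrum (dB) on ``freqs``."""
        return eval_aperiodic(self.family, self.aperiodic, freqs) + eval_gaussians(
            self.peaks, freqs
        )

    def shifted(self, shifts: dict) -> "GroundTruth":
        """New truth with additive parameter shifts.

        Keys: aperiodic names (``"b"``, ``"X"``, ...) or ``"peak<i>.<p>"``
        with ``<p>`` in {a, mu, sigma} addressing the i-th peak.
        """
        aperiodic = dict(self.aperiodic)
        peaks = [[p.a, p.mu, p.sigma] for p in self.peaks]
        for key, delta in shifts.items():
            if key in aperiodic:
                aperiodic[key] += delta
            elif key.startswith("peak") and "." in key:
                idx_s, pname = key[4:].split(".", 1)
                i = int(idx_s)
                if not 0 <= i < len(peaks):
                    raise KeyError(f"no peak {i} in truth with {len(peaks)} peaks")
                j = {"a": 0, "mu": 1, "sigma": 2}[pname]
                peaks[i][j] += delta
            else:
                raise KeyError(f"unknown parameter {key!r}")
        return replace(
            self,
            aperiodic=aperiodic,
            peaks=tuple(GaussianPeak(*p) for p in peaks),
        )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "aperiodic": dict(self.aperiodic),
            "peaks": [[p.a, p.mu, p.sigma] for p in self.peaks],
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            family=d["family"],
            aperiodic=dict(d["aperiodic"]),
            peaks=tuple(tuple(p) for p in d["peaks"]),
            noise_sd=d["noise_sd"],
        )


def make_spectrum(truth: GroundTruth, grid=None, seed: int | None = None) -> PowerSpectrum:
    """dB spectrum = truth model curve + iid Gaussian noise of sd
    ``truth.noise_sd`` (zero noise gives the exact curve)."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < FMIN_DEFAULT - 1e-9 or grid[-1] > FMAX_DEFAULT + 1e-9:
        raise ValueError("grid must lie within the 0.1-190 Hz analysis range")
    power = truth.curve(grid)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        power = power + rng.normal(0.0, truth.noise_sd, size=grid.size)
    return PowerSpectrum(grid, power, scale="db", meta={"truth": truth.to_dict()})


def make_timeseries(
    truth: GroundTruth, duration: float, fs: float, seed: int | None = None
) -> np.ndarray:
    """Real-valued signal (mV) whose Welch dB spectrum matches the truth curve.

    White Gaussian noise is shaped in the frequency domain by the target
    amplitude spectrum: the one-sided PSD of the output equals the truth
    model curve (in linear units) in expectation.
    """
    if fs < 2 * FMAX_DEFAULT:
        raise ValueError(
            f"fs={fs} is below Nyquist for the {FMAX_DEFAULT} Hz analysis range"
        )
    if duration < 10.0:
        raise ValueError("duration must be at least 10 s")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    # evaluate the model curve away from f=0 (families are defined for f>0)
    target_db = np.zeros_like(f)
    target_db[1:] = truth.curve(np.maximum(f[1:], 1e-6))
    psd = 10.0 ** (target_db / 10.0)
    gain = np.sqrt(psd * fs / 2.0)  # white noise one-sided PSD is 2/fs
    gain[0] = 0.0
    return np.fft.irfft(spec * gain, n)


def inject_artifacts(signal, fs: float, events):
    """Add rectangular excursions to ``signal``.

    ``events`` are (start_s, duration_s, amplitude_mv) tuples; events must
    be disjoint and inside the signal extent.  Returns the modified signal
    and the exact injected [start, end) intervals.
    """
    signal = np.asarray(signal, dtype=float).copy()
    duration = signal.size / fs
    intervals = []
    for start, dur, amp in events:
        if start < 0 or start + dur > duration + 1e-9:
            raise ValueError(f"event ({start}, {dur}) outside signal extent")
        intervals.append((float(start), float(start + dur)))
    intervals_sorted = sorted(intervals)
    for (s1, e1), (s2, e2) in zip(intervals_sorted, intervals_sorted[1:]):
        if s2 < e1:
            raise ValueError("artifact events overlap")
    for (start, dur, amp), (s, e) in zip(events, intervals):
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        signal[i0:i1] += amp
    return signal, intervals_sorted


def make_tracking(duration: float, bouts, sample_rate: float = 25.0) -> pd.DataFrame:
    """Center-of-mass trajectory with straight-line locomotion bouts.

    ``bouts`` are (start_s, duration_s, speed_cm_s) tuples (disjoint); the
    animal moves in a straight line at the stated speed within each bout
    and is stationary elsewhere.  Headings alternate between bouts so the
    trace does not run away in one direction.
    """
    for _, _, speed in bouts:
        if speed < 0:
            raise ValueError("bout speed must be non-negative")
    spans = sorted((s, s + d) for s, d, _ in bouts)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("bouts overlap")
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    speed_series = np.zeros(n)
    heading = np.zeros(n)
    for idx, (start, dur, speed) in enumerate(bouts):
        in_bout = (t >= start) & (t < start + dur)
        speed_series[in_bout] = speed
        heading[in_bout] = (idx % 4) * np.pi / 2.0
    dt = 1.0 / sample_rate
    dx = speed_series * np.cos(heading) * dt
    dy = speed_series * np.sin(heading) * dt
    x = np.concatenate([[0.0], np.cumsum(dx[:-1])])
    y = np.concatenate([[0.0], np.cumsum(dy[:-1])])
    return pd.DataFrame({"time_s": t, "x_cm": x, "y_cm": y})


# ---------------------------------------------------------------------------
# cohorts

#: Vehicle-session generating parameters: Lorentzian background plus seven
#: oscillatory bumps (delta through a small HFO bump).  Amplitudes and
#: widths are of the order seen in rodent cortical screw-electrode spectra.
DEFAULT_VEHICLE_TRUTH = GroundTruth(
    family="lorentzian",
    aperiodic={"b": 5.0, "X": 1.5, "k": 0.05},
    peaks=(
        (2.0, 3.0, 1.0),    # delta
        (3.0, 7.0, 1.5),    # theta
        (2.0, 14.0, 2.5),   # beta
        (1.5, 30.0, 3.0),   # low-gamma
        (1.5, 55.0, 4.0),   # mid-gamma
        (1.2, 90.0, 5.0),   # high-gamma
        (1.2, 150.0, 6.0),  # HFO
    ),
    noise_sd=0.2,
)

#: additive covariate coefficients (per parameter): value += coef_exp *
#: (experiment - 1) + coef_age * (age_days - 100)
DEFAULT_COVARIATE_EFFECTS = {
    "b": (0.3, 0.002),
    "X": (0.05, 0.0005),
}


@dataclass(frozen=True)
class AnimalRecord:
    animal: str
    experiment: int
    age_days: float
    exposure: float  # ng/ml for the compound session (0 under vehicle)
    truths: dict  # condition -> GroundTruth


@dataclass(frozen=True)
class SyntheticCohort:
    """Paired synthetic cohort: every animal has a vehicle and a compound
    session (Latin-square-like paired design)."""

    animals: tuple
    effect_model: dict
    seed: int

    @property
    def conditions(self):
        return tuple(self.animals[0].truths)

    def exposures_frame(self) -> pd.DataFrame:
        rows = [
            {"animal": a.animal, "condition": cond,
             "exposure_ng_ml": a.exposure if cond != "vehicle" else 0.0}
            for a in self.animals
            for cond in a.truths
        ]
        return pd.DataFrame(rows)

    def covariates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"animal": a.animal, "experiment": a.experiment,
                 "age_days": a.age_days}
                for a in self.animals
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "effect_model": self.effect_model,
                "animals": [
                    {
                        "animal": a.animal,
                        "experiment": a.experiment,
                        "age_days": a.age_days,
                        "exposure": a.exposure,
                        "truths": {c: t.to_dict() for c, t in a.truths.items()},
                    }
                    for a in self.animals
                ],
            },
            indent=2,
        )


def make_cohort(
    n_per_experiment: int,
    effect_model: dict,
    seed: int,
    base_truth: GroundTruth = DEFAULT_VEHICLE_TRUTH,
    covariate_effects: dict = None,
    condition: str = "compound",
    animal_jitter: float = 0.03,
) -> SyntheticCohort:
    """Generate a paired vehicle/compound cohort.

    Each animal's compound truth equals its vehicle truth plus
    ``effect_model`` slopes times its exposure (linear-in-exposure effects;
    the analysis only assumes monotonicity) plus additive experiment/age
    covariate terms.  Experiment 1 animals are younger with higher
    exposures, experiment 2 older with lower exposures, mirroring a
    two-cohort design.

    Parameters
    ----------
    effect_model : dict
        Parameter -> slope per ng/ml, e.g. ``{"X": 0.05, "peak2.a": 0.1}``.
    animal_jitter : float
        Relative sd of per-animal variation of every truth parameter.
    """
    if n_per_experiment < 3:
        raise ValueError("need at least 3 animals per experiment")
    if not effect_model:
        raise ValueError("effect model must name at least one parameter")
    covariate_effects = (
        DEFAULT_COVARIATE_EFFECTS if covariate_effects is None else covariate_effects
    )
    rng = np.random.default_rng(seed)
    animals = []
    for experiment in (1, 2):
        for j in range(n_per_experiment):
            # experiment 1: younger animals, higher exposures on average;
            # the ranges overlap so exposure is not collinear with cohort
            if experiment == 1:
                age = float(rng.normal(69.0, 5.0))
                exposure = float(rng.uniform(5.0, 20.0))
            else:
                age = float(rng.normal(147.0, 30.0))
                exposure = float(rng.uniform(2.0, 14.0))
            vehicle = _jitter_truth(base_truth, rng, animal_jitter)
            shifts = {k: slope * exposure for k, slope in effect_model.items()}
            for param, (ce, ca) in covariate_effects.items():
                shifts[param] = shifts.get(param, 0.0) + ce * (experiment - 1) + ca * (
                    age - 100.0
                )
            compound = vehicle.shifted(shifts)
            animals.append(
                AnimalRecord(
                    animal=f"rat{experiment}{j + 1:02d}",
                    experiment=experiment,
                    age_days=age,
                    exposure=exposure,
                    truths={"vehicle": vehicle, condition: compound},
                )
            )
    return SyntheticCohort(
        animals=tuple(animals), effect_model=dict(effect_model), seed=seed
    )


def _jitter_truth(truth: GroundTruth, rng, rel_sd: float) -> GroundTruth:
    if rel_sd == 0:
        return truth
    aperiodic = {
        k: v * (1.0 + rng.normal(0.0, rel_sd)) if k != "k"
        else max(v * (1.0 + rng.normal(0.0, rel_sd)), 0.0)
        for k, v in truth.aperiodic.items()
    }
    peaks = tuple(
        (
            p.a * (1.0 + rng.normal(0.0, rel_sd)),
            p.mu * (1.0 + rng.normal(0.0, rel_sd / 3.0)),
            p.sigma * (1.0 + rng.normal(0.0, rel_sd)),
        )
        for p in truth.peaks
    )
    return replace(truth, aperiodic=aperiodic, peaks=peaks)
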