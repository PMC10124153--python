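"""Data-driven oscillatory-band delimitation.

Rather than fixing canonical band limits, the band scheme for each dosing
condition is derived from the pooled distribution of fitted Gaussian peak
centers (across animals and regions): a Gaussian kernel-density estimate of
the centers is computed on a frequency grid, and band boundaries are placed
at the valleys (local density minima) between consecutive oscillatory
modes — or, alternatively, at the inflection points flanking each valley.
Seven bands get the conventional ascending labels delta, theta, beta,
low-gamma, mid-gamma, high-gamma, HFO; any other count gets generic names.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .spectrum import FMAX_DEFAULT, FMIN_DEFAULT

__all__ = ["BandScheme", "pool_centers", "kde_density", "derive_band_limits",
           "CANONICAL_LABELS"]

CANONICAL_LABELS = (
    "delta", "theta", "beta", "low_gamma", "mid_gamma", "high_gamma", "hfo",
)

KDE_BANDWIDTH_DEFAULT = 1.0  # Hz
KDE_GRID_STEP_DEFAULT = 0.1  # Hz


@dataclass(frozen=True)
class BandScheme:
    """Condition-specific ordered band limits with labels and the KDE curve."""

    condition: str
    limits: tuple  # internal boundaries, Hz, strictly increasing
    labels: tuple
    grid: np.ndarray = None
    density: np.ndarray = None
    fmin: float = FMIN_DEFAULT
    fmax: float = FMAX_DEFAULT

    def __post_init__(self) -> None:
        limits = tuple(float(x) for x in self.limits)
        if any(b <= a for a, b in zip(limits, limits[1:])):
            raise ValueError("band limits must be strictly increasing")
        if len(self.labels) != len(limits) + 1:
            raise ValueError("number of bands must equal number of limits + 1")
        object.__setattr__(self, "limits", limits)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def bands(self) -> dict:
        """label -> (low, high) half-open band intervals covering the range."""
        edges = (self.fmin,) + self.limits + (self.fmax,)
        return {
            label: (edges[i], edges[i + 1]) for i, label in enumerate(self.labels)
        }

    def band_of(self, freq: float) -> str:
        for label, (lo, hi) in self.bands.items():
            if lo <= freq < hi or (hi == self.fmax and freq == hi):
                return label
        raise ValueError(f"{freq} Hz outside the analysis range")

    def to_table(self):
        """Table-shaped rows (band, lower, upper) with edge bands rendered
        as '<first limit' / '>last limit'."""
        import pandas as pd

        rows = []
        for i, (label, (lo, hi)) in enumerate(self.bands.items()):
            if i == 0:
                shown = f"<{hi:g}"
            elif i == len(self.labels) - 1:
                shown = f">{lo:g}"
            else:
                shown = f"{lo:g}-{hi:g}"
            rows.append(
                {"band": label, "lower_hz": lo, "upper_hz": hi, "range": shown}
            )
        return pd.DataFrame(rows)


def pool_centers(fits_by_condition: dict) -> dict:
    """Pool Gaussian peak centers across animals and regions per condition.

    ``fits_by_condition`` maps condition label -> iterable of decomposition
    results (anything with a ``peaks`` attribute, or a bare peak list).
    """
    pooled = {}
    for condition, fits in fits_by_condition.items():
        centers = []
        for fit in fits:
            peaks = getattr(fit, "peaks", fit)
            centers.extend(p.mu for p in peaks)
        if not centers:
            raise ValueError(f"condition {condition!r} contributed zero peaks")
        pooled[condition] = np.asarray(centers, dtype=float)
    return pooled


def kde_density(
    centers,
    bandwidth: float = KDE_BANDWIDTH_DEFAULT,
    grid=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of peak centers on a frequency grid.

    ``bandwidth`` is the kernel standard deviation in Hz (not a relative
    factor).  Returns (grid, density); density integrates to ~1 over a
    sufficiently wide grid.
    """
    centers = np.asarray(centers, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if centers.size < 2:
        raise ValueError("need at least 2 centers for a density estimate")
    if grid is None:
        grid = np.arange(FMIN_DEFAULT, FMAX_DEFAULT + 1e-9, KDE_GRID_STEP_DEFAULT)
    else:
        grid = np.asarray(grid, dtype=float)
    sd = centers.std(ddof=1)
    if sd == 0:
        density = sstats.norm.pdf(grid, loc=centers[0], scale=bandwidth)
    else:
        kde = sstats.gaussian_kde(centers, bw_method=bandwidth / sd)
        density = kde(grid)
    return grid, density


def derive_band_limits(
    grid,
    density,
    method: str = "minima",
    condition: str = "",
    mode_threshold: float = 0.15,
) -> BandScheme:
    """Place band boundaries between the modes of a center-density curve.

    ``method="minima"`` puts one boundary at the density minimum between
    each pair of consecutive modes; ``method="inflection"`` instead returns
    the two second-difference sign changes flanking each valley.  Modes
    below ``mode_threshold`` times the global maximum are ignored as noise.
    A unimodal density yields a single band and no internal limits.
    """
    grid = np.asarray(grid, dtype=float)
    density = np.asarray(density, dtype=float)
    modes = _find_modes(density, mode_threshold)
    limits: list[float] = []
    for m1, m2 in zip(modes, modes[1:]):
        seg = density[m1 : m2 + 1]
        # flat valleys (density ~0 between distant modes) are tie-broken at
        # the plateau center, not at an arbitrary argmin edge
        low = seg.min()
        flat = np.flatnonzero(seg <= low + 1e-12 * max(density.max(), 1.0))
        valley = m1 + int(flat[len(flat) // 2])
        if method == "minima":
            limits.append(float(grid[valley]))
        elif method == "inflection":
            d2 = np.gradient(np.gradient(density, grid), grid)
            left = valley
            while left > m1 and d2[left - 1] > 0:
                left -= 1
            right = valley
            while right < m2 and d2[right + 1] > 0:
                right += 1
            limits.extend([float(grid[left]), float(grid[right])])
        else:
            raise ValueError(f"unknown method {method!r}")
    limits = sorted(set(limits))
    n_bands = len(limits) + 1
    labels = (
        CANONICAL_LABELS
        if n_bands == len(CANONICAL_LABELS)
        else tuple(f"band{i + 1}" for i in range(n_bands))
    )
    return BandScheme(
        condition=condition,
        limits=tuple(limits),
        labels=labels,
        grid=grid,
        density=density,
        fmin=float(grid[0]),
        fmax=float(grid[-1]),
    )


def _find_modes(density: np.ndarray, threshold: float) -> list[int]:
    floor = threshold * density.max()
    modes = []
    for i in range(1, density.size - 1):
        if density[i] > density[i - 1] and density[i] >= density[i + 1]:
            if density[i] >= floor:
                modes.append(i)
    # endpoint modes (monotone edge)
    if density[0] > density[1] and density[0] >= floor:
        modes.insert(0, 0)
    if density[-1] > density[-2] and density[-1] >= floor:
        modes.append(density.size - 1)
    return modes
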