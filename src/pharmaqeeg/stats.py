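"""Permutation-based inference linking spectra and spectral parameters to
drug plasma exposure.

Four pieces, mirroring the analysis they serve:

- :func:`cbp_paired_test` — paired cluster-based permutation test across
  frequency bins.  Per-bin paired t statistics; contiguous supra-threshold
  bins form clusters whose mass (sum of t, sign-preserving) is compared to
  a max-|mass| null built from sign-flips of the subject difference
  spectra.  When ``2**n_pairs <= n_perm`` the sign-flip null is enumerated
  exhaustively (deterministic); otherwise random flips are drawn.
- :func:`residualize` — OLS residuals of a per-animal metric on intercept +
  covariates (experiment number, age), merging the two experiments.
- :func:`transform_to_normal` — rank-based inverse-normal transformation
  (ranks -> fractional ranks -> normal quantiles), strictly rank-preserving.
- :func:`spearman_perm` / :func:`exposure_correlation` — Spearman rank
  correlation with a permutation p-value; exposure-response rows are built
  from compound-minus-vehicle residual contrasts (amplitude, AUC, aperiodic
  parameters) or compound-only residuals (modal frequency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

__all__ = [
    "Cluster",
    "ClusterResult",
    "cbp_paired_test",
    "residualize",
    "transform_to_normal",
    "spearman_perm",
    "exposure_correlation",
]

N_PERM_DEFAULT = 1000
CLUSTER_ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class Cluster:
    """One contiguous supra-threshold cluster of frequency bins."""

    start: int   # first bin index
    stop: int    # one past the last bin index
    mass: float  # sum of per-bin t values (sign-preserving)
    p: float

    @property
    def bins(self) -> range:
        return range(self.start, self.stop)


@dataclass(frozen=True)
class ClusterResult:
    clusters: tuple
    n_permutations: int
    exhaustive: bool
    t_values: np.ndarray = field(repr=False, default=None)
    threshold: float = np.nan

    def significant(self, alpha: float = 0.05) -> tuple:
        return tuple(c for c in self.clusters if c.p < alpha)

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "exhaustive": self.exhaustive,
            "threshold": float(self.threshold),
            "clusters": [
                {"start": c.start, "stop": c.stop, "mass": c.mass, "p": c.p,
                 "sig_05": c.p < 0.05, "sig_01": c.p < 0.01}
                for c in self.clusters
            ],
        }


def _cluster_masses(t: np.ndarray, threshold: float):
    """(start, stop, mass) of maximal contiguous runs with |t| > threshold."""
    above = np.abs(t) > threshold
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    out = []
    for i0, i1 in zip(edges[::2], edges[1::2]):
        out.append((int(i0), int(i1), float(t[i0:i1].sum())))
    return out


def _max_cluster_mass(t: np.ndarray, threshold: float) -> float:
    masses = _cluster_masses(t, threshold)
    return max((abs(m) for _, _, m in masses), default=0.0)


def _tstats(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def cbp_paired_test(
    spectra_a,
    spectra_b,
    n_perm: int = N_PERM_DEFAULT,
    cluster_alpha: float = CLUSTER_ALPHA_DEFAULT,
    seed: int | None = None,
) -> ClusterResult:
    """Paired cluster-based permutation test between two spectrum sets.

    Parameters
    ----------
    spectra_a, spectra_b : (n_subjects, n_bins) arrays
        Paired dB spectra, one row per subject, same subject order.
    n_perm : int
        Number of sign-flip permutations; when ``2**n_subjects <= n_perm``
        all sign patterns are enumerated instead and the p-values are exact.
    cluster_alpha : float
        Two-sided alpha of the cluster-forming paired-t threshold.
    seed : int, optional
        Seed for the random sign-flips (ignored in the exhaustive case).

    Returns
    -------
    ClusterResult
        Clusters with sign-preserving mass and permutation p-values
        (p >= 1/n_null by the inclusion of the identity flip / the +1/+1
        convention; never 0).
    """
    a = np.asarray(spectra_a, dtype=float)
    b = np.asarray(spectra_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("spectra_a and spectra_b must be equal-shape 2-d arrays")
    n, n_bins = a.shape
    if n < 5:
        raise ValueError(f"need at least 5 subject pairs, got {n}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse",
                      stacklevel=2)
    diffs = a - b
    threshold = float(sstats.t.ppf(1.0 - cluster_alpha / 2.0, n - 1))
    t_obs = _tstats(diffs)
    observed = _cluster_masses(t_obs, threshold)
    if not observed:
        return ClusterResult(clusters=(), n_permutations=n_perm,
                             exhaustive=False, t_values=t_obs,
                             threshold=threshold)

    exhaustive = 2**n <= n_perm
    if exhaustive:
        signs = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)],
            dtype=float,
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))

    # sign flips leave d_i^2 unchanged: per-permutation variance follows
    # from the flipped mean alone
    sum_sq = (diffs**2).sum(axis=0)
    means = signs @ diffs / n
    var = (sum_sq - n * means**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / np.sqrt(var / n)
    t_perm = np.where(var == 0, 0.0, t_perm)
    null = np.fromiter(
        (_max_cluster_mass(row, threshold) for row in t_perm),
        dtype=float, count=t_perm.shape[0],
    )

    clusters = []
    for i0, i1, mass in observed:
        if exhaustive:
            p = float(np.mean(null >= abs(mass) - 1e-12))
        else:
            p = (1.0 + float(np.sum(null >= abs(mass) - 1e-12))) / (n_perm + 1.0)
        clusters.append(Cluster(start=i0, stop=i1, mass=mass, p=p))
    return ClusterResult(
        clusters=tuple(clusters),
        n_permutations=int(signs.shape[0]),
        exhaustive=exhaustive,
        t_values=t_obs,
        threshold=threshold,
    )


def residualize(values, covariates: pd.DataFrame):
    """OLS residuals of ``values`` on an intercept plus covariate columns.

    Residuals sum to zero and are exactly orthogonal to every covariate.
    Covariates with no variation are treated as absorbed by the intercept;
    genuinely collinear columns raise an error naming them.
    """
    y = np.asarray(values, dtype=float)
    X = covariates.apply(pd.to_numeric).astype(float)
    if len(X) != y.size:
        raise ValueError("values and covariates must align row-wise")
    keep = [c for c in X.columns if X[c].nunique() > 1]
    design = sm.add_constant(X[keep], has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the columns involved in the collinearity via QR diagonal
        q, r = np.linalg.qr(design.to_numpy())
        diag = np.abs(np.diag(r))
        bad = [design.columns[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"covariates are rank-deficient (collinear: {bad})")
    model = sm.OLS(y, design).fit()
    return np.asarray(model.resid)


def transform_to_normal(values) -> np.ndarray:
    """Two-step rank-based inverse-normal transformation.

    Ranks (average ranks for ties) -> fractional ranks r/(n+1) -> standard
    normal quantiles.  Strictly rank-preserving, hence Spearman-invariant.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 values")
    if np.all(y == y[0]):
        raise ValueError("all values equal; ranks undefined")
    ranks = sstats.rankdata(y)
    return sstats.norm.ppf(ranks / (y.size + 1.0))


def spearman_perm(
    x, y, n_perm: int = N_PERM_DEFAULT, seed: int | None = None
) -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed permutation p-value.

    ``y`` is shuffled ``n_perm`` times; p = (1 + #{|rho_perm| >= |rho|}) /
    (n_perm + 1), so p is never 0 and the observed statistic counts as one
    permutation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must be equal length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; rank correlation undefined")
    rho = float(sstats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    # Spearman rho is the Pearson correlation of the ranks; precompute
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(ry_c)
        rho_p = float((rx_c * perm).sum() / denom)
        if abs(rho_p) >= abs(rho) - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return rho, p


APERIODIC_PARAMS = ("offset", "slope", "knee")


def exposure_correlation(
    metrics: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    compound: str,
    vehicle: str = "vehicle",
    n_perm: int = N_PERM_DEFAULT,
    seed: int | None = None,
    min_n: int = 4,
    exclude=(),
) -> pd.DataFrame:
    """Exposure-response table: one permutation-Spearman row per
    (parameter, band, region).

    ``metrics`` is tidy long format with columns animal, region, condition,
    parameter, band (empty for aperiodic parameters), value.  For amplitude,
    AUC and aperiodic parameters the correlated quantity is
    ``residualize(compound) - residualize(vehicle)`` per animal; for modal
    frequency it is the compound residual alone, dropping animals without a
    measurable modal frequency.  Rows that end with fewer than ``min_n``
    animals, or a constant contrast, are flagged rather than omitted.

    ``exclude`` lists animal ids removed up front (exposure outliers are
    accepted as an explicit exclusion list).
    """
    required = {"animal", "region", "condition", "parameter", "band", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(required)}")
    metrics = metrics[~metrics["animal"].isin(exclude)]
    exposures = exposures[~exposures["animal"].isin(exclude)]
    covariates = covariates.set_index("animal")
    expo = (
        exposures[exposures["condition"] == compound]
        .set_index("animal")["exposure_ng_ml"]
    )

    rng = np.random.default_rng(seed)
    rows = []
    combos = (
        metrics[["parameter", "band", "region"]]
        .drop_duplicates()
        .sort_values(["parameter", "band", "region"])
    )
    for parameter, band, region in combos.itertuples(index=False):
        sub = metrics[
            (metrics["parameter"] == parameter)
            & (metrics["band"] == band)
            & (metrics["region"] == region)
        ]
        comp = sub[sub["condition"] == compound].set_index("animal")["value"]
        veh = sub[sub["condition"] == vehicle].set_index("animal")["value"]
        if parameter == "modal_frequency":
            comp = comp.dropna()
            animals = comp.index.intersection(expo.index)
            contrast_type = "compound_only"
        else:
            animals = comp.index.intersection(veh.index).intersection(expo.index)
            contrast_type = "vehicle_difference"
        animals = animals.sort_values()
        row = {
            "parameter": parameter, "band": band, "region": region,
            "contrast_type": contrast_type, "n": int(len(animals)),
            "rho": np.nan, "p": np.nan, "flag": "",
        }
        if len(animals) < min_n:
            row["flag"] = "insufficient n"
            rows.append(row)
            continue
        cov = covariates.loc[animals, ["experiment", "age_days"]]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            if contrast_type == "compound_only":
                contrast = residualize(comp.loc[animals].to_numpy(), cov)
            else:
                contrast = residualize(
                    comp.loc[animals].to_numpy(), cov
                ) - residualize(veh.loc[animals].to_numpy(), cov)
            rho, p = spearman_perm(
                expo.loc[animals].to_numpy(), contrast,
                n_perm=n_perm, seed=sub_seed,
            )
            row.update(rho=rho, p=p)
        except ValueError as exc:
            row["flag"] = f"degenerate: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
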