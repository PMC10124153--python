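# Methods

## Spectral model and fitting domain

The decomposition operates on decibel-scale spectra: the aperiodic families
are applied literally in dB units, so the Lorentzian background
`b + 1/(f^X + k)` has offset `b` in dB, a dimensionless exponent ("slope")
`X`, and a knee parameter `k` whose bend sits near `f = k^(1/X)` Hz. Two
properties of this parameterization matter for everything downstream:

- the background's total dynamic range over the analysis band is bounded by
  `1/k` dB, so small knees (k ≪ 1) produce the tens-of-dB range real EEG
  spectra show, while k ≳ 1 compresses the whole aperiodic term under ~1 dB;
- consequently the information the data carry about `(X, k)` collapses as
  `k` grows (see "Attainability" below).

A config switch `aperiodic_log_form` is deliberately *not* provided as a
second fitting path: the literal dB form is the single supported
convention, applied consistently from simulation through fitting, so
round-trips are exact by construction.

## Aperiodic fitting

Bounded trust-region least squares (`X ∈ (0, 20]`, `k ≥ 0`, decay rate
`d > 0`) from three fixed, data-informed starts (offset from the
high-frequency median; exponent/knee/decay-rate triples spanning shallow to
steep regimes). Peak robustness is iterated clipping: residuals above
max(75th percentile, 2.5 × noise SD) are masked and the fit repeated until
the mask stabilizes (≤ 4 rounds). The noise SD is estimated from first
differences of the residual (MAD/√2), which is immune to smooth peak
structure even when peaks cover most of the spectrum; the 2.5-SD guard
keeps ordinary noise bins in the fit, so peakless spectra are not biased
low. The reported RMSE is always over all bins.

## Family selection

All four families are fitted and compared by RMSE. Families within
max(1e-6, 2% relative) of the minimum are treated as tied and the one with
fewer parameters wins. The 2% band is set by two scales measured on
synthetic spectra at the study noise (0.2 dB per bin): a nesting family
gains ~0.3% RMSE by fitting noise (≈ p/2N for p extra parameters on N=380
bins) and up to ~1.3% by partially mimicking a lower family's shape,
while genuine family mismatch costs ≥ 5–8%. Selection accuracy at study
noise is ≥ 90% for the mutually non-nested generators (Lorentzian;
power law + decay) and the nested pure power law resolves correctly by
parsimony.

Two caveats, both verified by simulation:

- **Lorentzian + decay is effectively unidentifiable** on this grid: a free
  exponential decay reproduces a knee's low-frequency saturation to within
  ~2% RMSE, so the five-parameter family loses the parsimony tie-break to
  power law + decay most of the time. It is retained as a candidate but no
  accuracy claim is made for it.
- Family selection runs on the spectrum *before* peak removal (the RMSE
  table mirrors fitting the background to the full spectrum), so strong
  oscillatory peaks can distort the comparison; the pipeline therefore
  defaults to the fixed Lorentzian family — the analysis path the
  comparison supports overall — and `family="auto"` is best used on
  peak-poor spectra.

## Periodic fitting

Greedy extraction (largest residual maximum ≥ `min_height`, half-height
width guess, subtract, repeat to `max_peaks=8`) followed by a joint bounded
refit of all Gaussians, with three structural refinements:

- **overlap pruning**: a component whose center lies within 0.75 widths of
  a larger component is a split fit of a single bump; drop it and refit;
- **split-and-refit**: conversely, one wide component can hide two genuine
  neighbors — each component is tentatively replaced by two offset halves
  and the split is kept only if RMSE improves by > 5% (noise-level gains
  never qualify, so this cannot reintroduce spurious splits);
- a final **joint refinement** of aperiodic + peak parameters together on
  the raw spectrum (on by default), which is what makes noiseless
  round-trips exact to machine precision.

`min_height="auto"` is max(2 × noise SD, 0.05 dB); the absolute floor
guards noiseless input where the noise estimate is ~0. Width bounds are
[0.5, 24] Hz. Peaks below the height threshold or outside the width bounds
after refinement are dropped; output is sorted by center.

## Band delimitation

Peak centers are pooled per dosing condition across animals and regions and
smoothed with a Gaussian KDE. The bandwidth is expressed in Hz (kernel SD),
default 1.0 Hz on a 0.1 Hz grid — the bandwidth should exceed the
center-estimation scatter of a single mode (~0.1–0.5 Hz here) and stay
below half the smallest inter-mode gap (~4 Hz between delta and theta).
Band boundaries default to the density minima between consecutive modes;
an inflection-point variant (the two second-difference sign changes
flanking each valley) is available but yields two limits per valley and is
not the default. Flat valleys between distant modes are tie-broken at the
plateau center. Local maxima below 15% of the global maximum are ignored:
in an N-animal cohort a genuine mode draws ~N clustered centers while a
stray fitted peak contributes a singleton whose density maximum is ~1/N of
a mode's (~8–10% at N=12), so the threshold separates the two populations
with margin. Exactly seven bands receive the conventional ascending labels
(δ, θ, β, low-γ, mid-γ, high-γ, HFO); any other count gets generic names
and downstream code must locate bands by frequency.

## Band metrics

Band membership is by center frequency (half-open intervals; the top band
includes its upper edge) — a peak whose tail crosses a limit but whose
center does not stays outside. The band curve is the sum of member
Gaussians on a 0.01 Hz grid; amplitude is the curve maximum, modal
frequency its location with parabolic refinement (absent when the band is
empty — no frequency can be measured where there is no amplitude), and AUC
the trapezoidal integral over the band interval only (tails outside the
band are not chased; at fitted widths the truncation error is ≪ 1%).

## Statistics

**CBP test.** Per-bin paired t statistics; contiguous bins exceeding the
two-sided t threshold at `cluster_alpha` (default 0.05) form clusters with
mass = Σt (sign-preserving, so increase and decrease clusters keep their
direction). The null is max |mass| over sign-flips of the subject
difference spectra: exhaustive enumeration of all 2ⁿ patterns when
2ⁿ ≤ `n_perm` (deterministic, exact p-values), otherwise `n_perm` random
flips with the +1/+1 convention (p never 0). Type-I error at n=8 pairs is
calibrated within the binomial band around 0.05 (measured over 300 null
simulations — with exhaustive flips each simulation is deterministic, so
300 bounds the binomial CI at ±0.025 and costs a third of a larger run).

**Residualization.** OLS of each metric on intercept + experiment number +
age (statsmodels); residuals are exactly orthogonal to the covariates.
Exposure itself is left raw, so any component of a drug effect that is
collinear with the cohort split is deliberately removed — the synthetic
cohorts therefore draw exposures with overlapping ranges between
experiments, as in a realistic two-cohort design.

**Rank-normal transform.** ranks → r/(n+1) → Φ⁻¹; strictly rank-preserving
(hence Spearman-invariant). Provided for ANOVA-style downstream use.

**Permutation Spearman.** ρ from rank correlation (average ranks for
ties); y is shuffled `n_perm` times (exchangeable under the null, so
shuffling x would be equivalent); two-tailed p = (1 + #{|ρ*| ≥ |ρ|}) /
(n_perm + 1). Amplitude/AUC/aperiodic rows correlate the
compound-minus-vehicle residual difference with exposure; modal-frequency
rows use the compound residual alone with pairwise deletion of animals
lacking a measurable modal frequency. Rows with < `min_n` animals or a
constant contrast are flagged, never silently dropped. Exposure outliers
are handled as an explicit exclusion list.

## Synthetic data and study conditions

The generator's defaults define the study conditions used throughout the
tests and the acceptance script:

- vehicle background `b=5, X=1.5, k=0.05` (dynamic range ≈ 12 dB, the
  regime where slope and knee are well identified) and seven bumps
  (δ 2 dB@3 Hz, θ 3@7, β 2@14, low-γ 1.5@30, mid-γ 1.5@55, high-γ 1.2@90,
  HFO 1.2@150, widths 1–6 Hz);
- per-bin spectral noise 0.2 dB;
- paired vehicle/compound design, 2 experiments × n animals; experiment 1
  younger (69 ± 5 d) with exposures U(5, 20) ng/ml, experiment 2 older
  (147 ± 30 d) with U(2, 14) — higher exposure in the younger cohort, with
  overlap; 3% per-animal parameter jitter; additive experiment/age
  covariate effects on offset and slope;
- compound effects linear in exposure (`parameter → slope per ng/ml`); the
  analysis only assumes monotonicity, so the linear map is the simplest
  testable choice. The end-to-end recovery condition uses slope +0.15 per
  ng/ml on `X` (≈ 3 × the slope-estimation noise across the exposure
  range) and +0.10 dB per ng/ml on the β amplitude;
- time series by spectral shaping of white Gaussian noise (the one-sided
  PSD equals the target curve in expectation); rectangular artifacts, so
  expected masks are analytically exact; straight-line locomotion bouts.

What the generator does **not** emulate: multi-channel spatial structure,
non-Gaussian or frequency-correlated spectral noise, non-stationarity
within a session, HFO waveform shape (HFOs exist only as high-frequency
spectral bumps), or behavioral states beyond Still/Moving. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to every property of real recordings.

## Attainability of the recovery targets

Recovery tolerances are only meaningful where the Fisher information
allows them; Cramér–Rao analysis on the standard grid at 0.2 dB bin noise
gives:

- **Aperiodic grid.** For knee cells k ≥ 1 the bound already exceeds a 10%
  median relative error (X: 12–28% at k=1, ≈ 45–75% at k=10; the measured
  estimator matches the bound). The 10%-median target is therefore met for
  k=0 cells and is reported — not met — for k ≥ 1; this is a property of
  the dB-Lorentzian family, not of the optimizer. Noiseless recovery is
  exact (< 0.1% everywhere, typically ~1e-8).
- **Overlapping peak pairs.** For two Gaussians 1.5σ apart the amplitude
  SEs at 0.2 dB are ~2.8 dB on amplitudes of 2–3 dB — unresolvable by any
  estimator. The pair-recovery test runs at 0.01 dB, where the bound sits
  comfortably inside 10%.
- **Wide peaks.** Center SE ≈ (s/a)·√(2σΔ/√π); the seven-peak recovery
  fixture uses widths 1–6 Hz, keeping the per-peak median center error
  below 0.5 Hz with margin (a σ=12 Hz, 0.8 dB bump would sit at ~0.9 Hz SE
  and fail any estimator).

## Numerical and problem-size choices

Optimizer tolerances 1e-13 (trf); three multistarts per family; exhaustive
CBP enumeration switches on at 2ⁿ ≤ n_perm; permutation p-value comparisons
use a 1e-12 slack to absorb rank-tie rounding. Monte-Carlo sizes: 50 seeds
per cell for aperiodic recovery and family selection, 20 for the
seven-peak fixture, 300 null simulations / 50 power runs for CBP, one
12-animal × 3-region cohort for the end-to-end check — sizes chosen so the
binomial/median CIs are decisively inside (or outside) the targets. One
pipeline seed fans out deterministically to stage seeds via a counter
scheme; every stochastic result is bit-reproducible under a fixed seed.

## Known limitations

- `family="auto"` is unreliable on strongly peaked spectra (see above).
- The KDE mode threshold assumes roughly balanced contributions per
  animal; a condition where only a small minority of animals express a band
  (e.g., drug-induced HFO in a subset) can fall below the 15% threshold.
- The CBP cluster-forming threshold is the conventional paired-t quantile;
  no threshold-free variant is provided.
- Modal-frequency correlations use pairwise deletion, so their rows can
  have smaller n than amplitude/AUC rows from the same cohort.
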