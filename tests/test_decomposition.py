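"""Periodic/aperiodic decomposition: exact noiseless recovery, Monte-Carlo
recovery under noise, family selection, and model/results invariants."""

import itertools

import numpy as np
import pytest

import pharmaqeeg as pq
from pharmaqeeg.decomposition import (
    FAMILIES,
    GaussianPeak,
    eval_aperiodic,
    fit_aperiodic,
    fit_periodic,
    select_family,
)

from conftest import APERIODIC, NOISE_SD, PEAKS7


def rel_err(est, true):
    """Relative error with a unit floor so k=0 cells stay well-defined."""
    return abs(est - true) / max(abs(true), 1.0)


class TestEvalAperiodic:
    def test_lorentzian_reference_value(self):
        out = eval_aperiodic("lorentzian", {"b": 0.0, "X": 1.0, "k": 0.0}, [2.0])
        assert out[0] == pytest.approx(0.5)

    def test_powerlaw_is_lorentzian_without_knee(self):
        f = np.linspace(0.5, 150, 57)
        p = {"b": 2.0, "X": 1.3}
        np.testing.assert_allclose(
            eval_aperiodic("powerlaw", p, f),
            eval_aperiodic("lorentzian", {**p, "k": 0.0}, f),
        )

    def test_degenerate_decay_rate(self):
        out = eval_aperiodic(
            "lorentzian_expdecay",
            {"b": 1.0, "X": 1.0, "k": 1.0, "c": 2.0, "d": 0.0},
            [1.0],
        )
        assert out[0] == pytest.approx(3.5)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            eval_aperiodic("powerlaw", {"b": 0.0, "X": 1.0}, [0.0, 1.0])


class TestFitAperiodic:
    def test_noiseless_recovery_with_grid_oracle(self, lorentzian_truth):
        spec = pq.make_spectrum(lorentzian_truth)
        fit = fit_aperiodic(spec, "lorentzian")
        true = lorentzian_truth.aperiodic
        for name, value in true.items():
            assert rel_err(fit.params[name], value) < 1e-3
        assert fit.rmse < 1e-6
        # coarse grid-search oracle: no grid point beats the LS optimum
        freqs, power = spec.freqs, spec.power
        for b, X, k in itertools.product(
            np.linspace(3, 7, 9), np.linspace(0.5, 3, 11), [0.0, 0.25, 0.5, 1.0, 2.0]
        ):
            rmse = np.sqrt(np.mean(
                (eval_aperiodic("lorentzian", {"b": b, "X": X, "k": k}, freqs)
                 - power) ** 2
            ))
            assert fit.rmse <= rmse + 1e-9

    def test_noisy_recovery_median_within_10pct(self, lorentzian_truth):
        import dataclasses
        truth = dataclasses.replace(lorentzian_truth, noise_sd=NOISE_SD)
        errs = {name: [] for name in APERIODIC}
        for seed in range(15):
            fit = fit_aperiodic(pq.make_spectrum(truth, seed=seed), "lorentzian")
            for name, value in APERIODIC.items():
                errs[name].append(rel_err(fit.params[name], value))
        for name, es in errs.items():
            assert np.median(es) < 0.10, name

    def test_recovery_under_peak_contamination(self, lorentzian_truth):
        import dataclasses
        truth = dataclasses.replace(
            lorentzian_truth, peaks=((5.0, 12.0, 3.0),)
        )
        fit = fit_aperiodic(pq.make_spectrum(truth), "lorentzian")
        assert rel_err(fit.params["X"], APERIODIC["X"]) < 0.05
        assert rel_err(fit.params["k"], APERIODIC["k"]) < 0.05

    def test_too_few_bins_rejected(self):
        spec = pq.PowerSpectrum(np.arange(1.0, 5.0), np.zeros(4), scale="db")
        with pytest.raises(ValueError):
            fit_aperiodic(spec, "lorentzian")


class TestSelectFamily:
    def test_deterministic_table(self, lorentzian_truth):
        import dataclasses
        truth = dataclasses.replace(lorentzian_truth, noise_sd=NOISE_SD)
        spec = pq.make_spectrum(truth, seed=0)
        b1, t1 = select_family(spec)
        b2, t2 = select_family(spec)
        assert b1 == b2
        assert {f: t1[f].rmse for f in t1} == {f: t2[f].rmse for f in t2}

    def test_nested_powerlaw_resolved_by_parsimony(self):
        truth = pq.GroundTruth(
            family="powerlaw", aperiodic={"b": 5.0, "X": 1.5}, noise_sd=NOISE_SD
        )
        best, table = select_family(pq.make_spectrum(truth, seed=1))
        assert best == "powerlaw"
        # the knee family fits a nested model at least as well numerically
        assert table["powerlaw"].rmse <= table["lorentzian"].rmse \
            + 0.02 * table["powerlaw"].rmse + 1e-6

    def test_lorentzian_data_selects_lorentzian(self):
        # k=0.5 puts the knee's curvature signature at its most visible
        # (the dB-Lorentzian's dynamic range is 1/k, its bend near k^(1/X))
        truth = pq.GroundTruth(
            aperiodic={"b": 5.0, "X": 1.5, "k": 0.5}, noise_sd=NOISE_SD
        )
        hits = sum(
            select_family(pq.make_spectrum(truth, seed=s))[0] == "lorentzian"
            for s in range(10)
        )
        assert hits >= 9

    def test_single_family_rejected(self, lorentzian_truth):
        with pytest.raises(ValueError):
            select_family(pq.make_spectrum(lorentzian_truth), families=["powerlaw"])


class TestFitPeriodic:
    GRID = np.arange(0.5, 190.0, 0.5)

    def test_zero_residual_gives_no_peaks(self):
        assert fit_periodic(self.GRID, np.zeros_like(self.GRID)) == []

    def test_single_noiseless_gaussian_exact(self):
        peak = GaussianPeak(3.0, 10.0, 1.0)
        found = fit_periodic(self.GRID, peak(self.GRID))
        assert len(found) == 1
        assert rel_err(found[0].a, 3.0) < 1e-3
        assert abs(found[0].mu - 10.0) < 1e-3
        assert rel_err(found[0].sigma, 1.0) < 1e-3

    def test_two_overlapping_gaussians_recovered(self, rng):
        # a 1.5-sigma-separated pair is statistically resolvable only at low
        # bin noise (the pair's Fisher information collapses as components
        # align); 0.01 dB keeps the information bound well inside 10%
        truth = [GaussianPeak(3.0, 10.0, 2.0), GaussianPeak(2.0, 13.0, 2.0)]
        curve = sum(p(self.GRID) for p in truth)
        amp_errs, mu_errs = [], []
        for _ in range(15):
            noisy = curve + rng.normal(0, 0.01, self.GRID.size)
            found = fit_periodic(self.GRID, noisy)
            if len(found) < 2:
                amp_errs.append(1.0)
                mu_errs.append(1.0)
                continue
            for t in truth:
                match = min(found, key=lambda p: abs(p.mu - t.mu))
                amp_errs.append(rel_err(match.a, t.a))
                mu_errs.append(abs(match.mu - t.mu) / t.mu)
        assert np.median(amp_errs) < 0.10
        assert np.median(mu_errs) < 0.10

    def test_thresholds_and_bounds_respected(self, rng):
        residual = rng.normal(0, 0.3, self.GRID.size)
        residual += GaussianPeak(4.0, 40.0, 3.0)(self.GRID)
        found = fit_periodic(
            self.GRID, residual, min_height=1.0, width_bounds=(0.5, 12.0)
        )
        for p in found:
            assert p.a >= 1.0
            assert 0.5 <= p.sigma <= 12.0


class TestSpectralModel:
    def test_noiseless_roundtrip(self, seven_peak_truth):
        spec = pq.make_spectrum(seven_peak_truth)
        fit = pq.SpectralModel(spec, family="lorentzian").fit()
        assert fit.rmse < 0.05
        np.testing.assert_allclose(fit.fitted, spec.power, atol=0.05)
        assert len(fit.peaks) == 7

    def test_full_rmse_never_worse_than_aperiodic(self, seven_peak_truth):
        import dataclasses
        for seed in range(5):
            truth = dataclasses.replace(seven_peak_truth, noise_sd=NOISE_SD)
            fit = pq.SpectralModel(
                pq.make_spectrum(truth, seed=seed), family="lorentzian"
            ).fit()
            assert fit.rmse <= fit.aperiodic.rmse + 1e-9

    def test_fixed_family_skips_selection(self, lorentzian_truth):
        fit = pq.SpectralModel(
            pq.make_spectrum(lorentzian_truth), family="lorentzian"
        ).fit()
        assert fit.rmse_table == {}
        assert fit.aperiodic.family == "lorentzian"

    def test_recovery_across_parameter_factorial(self):
        # small factorial of exponent x knee cells, noiseless: <0.1% each
        for X in (0.5, 1.0, 2.0):
            for k in (0.0, 0.1):
                truth = pq.GroundTruth(
                    aperiodic={"b": 5.0, "X": X, "k": k}
                )
                fit = fit_aperiodic(pq.make_spectrum(truth), "lorentzian")
                assert rel_err(fit.params["X"], X) < 1e-3, (X, k)
                assert rel_err(fit.params["k"], k) < 1e-3, (X, k)

    def test_summary_lists_parameters(self, lorentzian_truth):
        fit = pq.SpectralModel(
            pq.make_spectrum(lorentzian_truth), family="lorentzian"
        ).fit()
        text = fit.summary()
        assert "lorentzian" in text
        assert "RMSE" in text

    def test_results_serializable(self, seven_peak_truth):
        fit = pq.SpectralModel(
            pq.make_spectrum(seven_peak_truth), family="lorentzian"
        ).fit()
        d = fit.to_dict()
        assert d["family"] == "lorentzian"
        assert len(d["peaks"]) == 7

    def test_invalid_rmse_relation_rejected(self, lorentzian_truth):
        from pharmaqeeg.decomposition import AperiodicFit, SpectralDecomposition

        spec = pq.make_spectrum(lorentzian_truth)
        ap = AperiodicFit(family="lorentzian", b=5.0, X=1.5, k=0.5, rmse=0.1)
        with pytest.raises(ValueError):
            SpectralDecomposition(
                aperiodic=ap, peaks=[], rmse=0.2, spectrum=spec
            )
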