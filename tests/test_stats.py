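"""Inferential machinery: CBP test against exhaustive enumeration,
residualization orthogonality, rank-normal transform, permutation Spearman."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import pharmaqeeg as pq


def cbp_oracle(diffs, cluster_alpha=0.05):
    """Independent brute-force CBP: explicit loops, exhaustive sign-flips."""
    n, nb = diffs.shape
    thr = sstats.t.ppf(1 - cluster_alpha / 2, n - 1)

    def masses(d):
        t = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(n))
        out, i = [], 0
        while i < nb:
            if abs(t[i]) > thr:
                j = i
                while j < nb and abs(t[j]) > thr:
                    j += 1
                out.append((i, j, t[i:j].sum()))
                i = j
            else:
                i += 1
        return out

    observed = masses(diffs)
    null = []
    for signs in itertools.product([1, -1], repeat=n):
        d2 = np.array(signs)[:, None] * diffs
        null.append(max((abs(m) for _, _, m in masses(d2)), default=0.0))
    null = np.array(null)
    return [
        (i0, i1, mass, float(np.mean(null >= abs(mass) - 1e-12)))
        for i0, i1, mass in observed
    ]


class TestCbpPairedTest:
    def test_identical_spectra_no_clusters(self, rng):
        a = rng.normal(0, 1, (8, 50))
        res = pq.cbp_paired_test(a, a.copy(), n_perm=500)
        assert res.clusters == ()

    def test_matches_exhaustive_enumeration_exactly(self, rng):
        a = rng.normal(0, 1, (8, 60))
        b = rng.normal(0, 1, (8, 60))
        a[:, 20:35] += 3.0
        res = pq.cbp_paired_test(a, b, n_perm=1000)
        assert res.exhaustive
        oracle = cbp_oracle(a - b)
        assert len(res.clusters) == len(oracle)
        for c, (i0, i1, mass, p) in zip(res.clusters, oracle):
            assert (c.start, c.stop) == (i0, i1)
            assert c.mass == pytest.approx(mass)
            assert c.p == p  # exact, both sides enumerate all 256 flips

    def test_injected_offset_detected(self, rng):
        a = rng.normal(0, 1, (8, 100))
        b = rng.normal(0, 1, (8, 100))
        a[:, 40:61] += 10.0
        res = pq.cbp_paired_test(a, b, n_perm=1000)
        sig = res.significant(0.05)
        assert sig
        covered = set()
        for c in sig:
            covered |= set(range(c.start, c.stop))
        assert len(covered & set(range(40, 61))) >= 0.8 * 21

    def test_seed_determinism_random_branch(self, rng):
        a = rng.normal(0, 1, (12, 40))
        b = rng.normal(0, 1, (12, 40))
        a[:, 10:20] += 2.0
        r1 = pq.cbp_paired_test(a, b, n_perm=300, seed=4)
        r2 = pq.cbp_paired_test(a, b, n_perm=300, seed=4)
        assert not r1.exhaustive
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]

    def test_too_few_pairs_rejected(self, rng):
        a = rng.normal(0, 1, (4, 20))
        with pytest.raises(ValueError):
            pq.cbp_paired_test(a, a, n_perm=100)

    def test_small_nperm_warns(self, rng):
        a = rng.normal(0, 1, (6, 20))
        b = a + rng.normal(0, 1, (6, 20))
        with pytest.warns(UserWarning):
            pq.cbp_paired_test(a, b, n_perm=50)


class TestResidualize:
    def test_constant_covariates_center_values(self, rng):
        y = rng.normal(5, 2, 10)
        cov = pd.DataFrame({"experiment": [1] * 10, "age_days": [70.0] * 10})
        res = pq.residualize(y, cov)
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-10)

    def test_exact_linear_dependence_gives_zero(self):
        age = np.array([60, 70, 80, 90, 100, 110.0])
        cov = pd.DataFrame({"experiment": [1, 1, 1, 2, 2, 2], "age_days": age})
        res = pq.residualize(2.0 * age, cov)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_orthogonality(self, rng):
        age = rng.uniform(60, 180, 20)
        exp = rng.integers(1, 3, 20)
        cov = pd.DataFrame({"experiment": exp, "age_days": age})
        res = pq.residualize(2 * age + rng.normal(0, 1, 20), cov)
        assert abs(res.sum()) < 1e-8
        assert abs(np.dot(res, age - age.mean())) < 1e-7
        assert abs(np.dot(res, exp - exp.mean())) < 1e-7

    def test_collinear_covariates_named(self):
        cov = pd.DataFrame(
            {"experiment": [1, 2, 1, 2], "age_days": [2.0, 4.0, 2.0, 4.0]}
        )
        with pytest.raises(ValueError, match="collinear"):
            pq.residualize(np.arange(4.0), cov)


class TestTransformToNormal:
    def test_rank_preserving(self, rng):
        y = rng.exponential(2.0, 50)
        z = pq.transform_to_normal(y)
        np.testing.assert_array_equal(np.argsort(y), np.argsort(z))

    def test_output_nearly_symmetric(self, rng):
        y = rng.exponential(1.0, 50) ** 2  # strongly skewed input
        z = pq.transform_to_normal(y)
        assert abs(sstats.skew(z)) < 0.3

    def test_spearman_invariance(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        before = sstats.spearmanr(x, y).statistic
        after = sstats.spearmanr(pq.transform_to_normal(x), y).statistic
        assert before == pytest.approx(after)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pq.transform_to_normal(np.ones(10))


class TestSpearmanPerm:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, p = pq.spearman_perm(x, np.exp(x), n_perm=500, seed=0)
        assert rho == pytest.approx(1.0)

    def test_perfect_antimonotone_minimal_p(self):
        x = np.arange(12.0)
        rho, p = pq.spearman_perm(x, -(x**3), n_perm=1000, seed=0)
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(1.0 / 1001.0)

    def test_agrees_with_exhaustive_enumeration(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho_obs = sstats.spearmanr(x, y).statistic
        count = sum(
            abs(sstats.spearmanr(x, np.array(perm)).statistic)
            >= abs(rho_obs) - 1e-12
            for perm in itertools.permutations(y)
        )
        exact_p = count / 720.0
        _, p = pq.spearman_perm(x, y, n_perm=1000, seed=3)
        assert p == pytest.approx(exact_p, abs=2 / np.sqrt(1000))

    def test_determinism_and_errors(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        assert pq.spearman_perm(x, y, 200, seed=1) == \
            pq.spearman_perm(x, y, 200, seed=1)
        with pytest.raises(ValueError):
            pq.spearman_perm(np.ones(8), y)
        with pytest.raises(ValueError):
            pq.spearman_perm(x[:3], y[:3])


def tidy_metrics_from(values_by_condition, parameter="amplitude", band="beta"):
    rows = []
    for cond, values in values_by_condition.items():
        for i, v in enumerate(values):
            rows.append({
                "animal": f"r{i}", "region": "parietal", "condition": cond,
                "parameter": parameter, "band": band, "value": v,
            })
    return pd.DataFrame(rows)


class TestExposureCorrelation:
    @staticmethod
    def cohort_tables(n=12, seed=0, slope=1.0, noise=0.1):
        rng = np.random.default_rng(seed)
        exposure = rng.uniform(2, 20, n)
        experiment = np.array([1] * (n // 2) + [2] * (n - n // 2))
        age = np.where(experiment == 1, rng.normal(69, 5, n), rng.normal(147, 30, n))
        veh = rng.normal(5, noise, n)
        comp = veh + slope * exposure + rng.normal(0, noise, n)
        metrics = tidy_metrics_from({"vehicle": veh, "compound": comp})
        exposures = pd.DataFrame({
            "animal": [f"r{i}" for i in range(n)] * 2,
            "condition": ["compound"] * n + ["vehicle"] * n,
            "exposure_ng_ml": np.concatenate([exposure, np.zeros(n)]),
        })
        covariates = pd.DataFrame({
            "animal": [f"r{i}" for i in range(n)],
            "experiment": experiment, "age_days": age,
        })
        return metrics, exposures, covariates

    def test_positive_effect_recovered(self):
        metrics, exposures, covariates = self.cohort_tables()
        out = pq.exposure_correlation(
            metrics, exposures, covariates, compound="compound",
            n_perm=1000, seed=1,
        )
        row = out.iloc[0]
        assert row["n"] == 12
        assert row["rho"] > 0.6
        assert row["p"] < 0.05

    def test_identical_conditions_flagged_degenerate(self):
        metrics, exposures, covariates = self.cohort_tables(slope=0.0, noise=0.0)
        veh = metrics[metrics.condition == "vehicle"]["value"].to_numpy()
        metrics.loc[metrics.condition == "compound", "value"] = veh
        out = pq.exposure_correlation(
            metrics, exposures, covariates, compound="compound", seed=1
        )
        assert out.iloc[0]["flag"].startswith("degenerate")

    def test_insufficient_n_flagged_not_dropped(self):
        metrics, exposures, covariates = self.cohort_tables(n=3)
        out = pq.exposure_correlation(
            metrics, exposures, covariates, compound="compound", seed=1
        )
        assert len(out) == 1
        assert out.iloc[0]["flag"] == "insufficient n"

    def test_modal_frequency_uses_compound_only_and_drops_missing(self):
        metrics, exposures, covariates = self.cohort_tables()
        metrics["parameter"] = "modal_frequency"
        # two animals have no measurable modal frequency under compound
        metrics.loc[
            (metrics.condition == "compound")
            & (metrics.animal.isin(["r0", "r1"])), "value",
        ] = np.nan
        out = pq.exposure_correlation(
            metrics, exposures, covariates, compound="compound",
            n_perm=500, seed=2,
        )
        row = out.iloc[0]
        assert row["contrast_type"] == "compound_only"
        assert row["n"] == 10

    def test_exclusion_list_respected(self):
        metrics, exposures, covariates = self.cohort_tables()
        out = pq.exposure_correlation(
            metrics, exposures, covariates, compound="compound",
            seed=1, exclude=("r0", "r5"),
        )
        assert out.iloc[0]["n"] == 10
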