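"""Tests for the ΔID regression, power, paired comparisons and the load."""

import math

import numpy as np
import pandas as pd
import pytest

from inbredsim.depression import (
    aggregate_replicates,
    bootstrap_compare,
    correlation_matrix,
    delta_id,
    expected_delta_id,
    inbreeding_load,
    paired_t,
    power,
    summarize_replicate,
)


class TestDeltaId:
    def test_exact_linear_case(self):
        f = np.linspace(0, 0.5, 20)
        w = np.exp(0.5 - 2.0 * f)
        res = delta_id(f, w)
        assert res.delta_id == pytest.approx(2.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.5, abs=1e-10)
        assert res.p < 1e-12

    def test_constant_fitness_zero_slope(self):
        res = delta_id(np.array([0.0, 0.1, 0.2, 0.3]), np.full(4, 0.8))
        assert res.delta_id == pytest.approx(0.0, abs=1e-12)

    def test_zero_fitness_excluded(self):
        f = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        w = np.array([1.0, 0.9, 0.0, 0.7, 0.6])
        res = delta_id(f, w)
        assert res.n_used == 4 and res.n_excluded == 1

    def test_constant_f_flagged(self):
        res = delta_id(np.full(5, 0.2), np.array([1, 0.9, 0.8, 0.7, 0.6]))
        assert res.degenerate
        assert math.isnan(res.slope)

    def test_sampling_theory_recovery(self, rng):
        """Noisy cloud with true slope -1.5: estimate within 3 SE of 1.5."""
        f = rng.uniform(0, 0.4, 100)
        w = np.exp(-1.5 * f + rng.normal(0, 0.3, 100))
        res = delta_id(f, w)
        assert abs(res.delta_id - 1.5) < 3 * res.stderr

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            delta_id(np.array([0.1, 0.2]), np.array([1.0, 0.9]))


class TestPower:
    def test_trivial_extremes(self):
        assert power([0.001] * 10) == 100.0
        assert power([0.5] * 10) == 0.0

    def test_type_one_error_is_test_size(self, rng):
        """Null (no depression): ~5% of replicates reach P < 0.05."""
        pvals = []
        for _ in range(2000):
            f = rng.uniform(0, 0.3, 30)
            w = np.exp(rng.normal(0, 0.2, 30))
            pvals.append(delta_id(f, w).p)
        got = power(pvals)
        se = 100 * math.sqrt(0.05 * 0.95 / 2000)
        assert abs(got - 5.0) < 3.5 * se


class TestBootstrap:
    def test_identical_pairs_zero_width(self, rng):
        d = np.full(50, 0.7)
        res = bootstrap_compare(d, d, rng=rng)
        assert res.mean_difference == 0.0
        assert res.ci_low == res.ci_high == 0.0

    def test_constant_offset(self, rng):
        ref = np.linspace(1, 2, 40)
        res = bootstrap_compare(ref, ref - 0.3, rng=rng)
        assert res.mean_difference == pytest.approx(0.3)
        assert res.ci_low == pytest.approx(0.3) and res.ci_high == pytest.approx(0.3)

    def test_gaussian_differences_ci_behaviour(self, rng):
        """CI covers the true mean difference and excludes 0 (mu=0.1, n=2000)."""
        est = rng.normal(0, 1, 2000)
        ref = est + rng.normal(0.1, 0.5, 2000)
        res = bootstrap_compare(ref, est, n_boot=1000, rng=rng)
        assert res.ci_low < 0.1 < res.ci_high
        assert res.ci_low > 0.0  # SE ~ 0.011, so 0 is ~9 SE away

    def test_converges_to_plain_mean_difference(self, rng):
        ref = rng.normal(0.2, 0.4, 300)
        est = rng.normal(0.0, 0.4, 300)
        res = bootstrap_compare(ref, est, n_boot=10**4, rng=rng)
        plain = float((ref - est).mean())
        assert res.mean_difference == pytest.approx(plain)
        assert abs((res.ci_low + res.ci_high) / 2 - plain) < 0.01


class TestPairedT:
    def test_identical_pairs_convention(self):
        t, p = paired_t(np.ones(5), np.ones(5))
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_difference_convention(self):
        t, p = paired_t(np.ones(5) + 0.2, np.ones(5))
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_antisymmetric_differences(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])
        t, _ = paired_t(a, b)
        assert t == pytest.approx(0.0)

    def test_textbook_five_pairs(self):
        """Hand computation: d=(1,2,0,1,1), mean 1, sd sqrt(0.5), t=sqrt(10)."""
        a = np.array([5.0, 7.0, 4.0, 6.0, 8.0])
        b = np.array([4.0, 5.0, 4.0, 5.0, 7.0])
        t, p = paired_t(a, b)
        assert t == pytest.approx(math.sqrt(10), abs=1e-12)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(math.sqrt(10), 4), abs=1e-12)


class TestLoad:
    def test_hand_single_locus(self):
        load = inbreeding_load(np.array([0.5]), np.array([0.2]), np.array([0.0]))
        assert load.d[0] == pytest.approx(0.1)
        assert load.b == pytest.approx(0.05)

    def test_additive_locus_contributes_nothing(self):
        load = inbreeding_load(np.array([0.3]), np.array([0.4]), np.array([0.5]))
        assert load.b == 0.0 and load.v_d == 0.0
        assert load.v_a > 0

    def test_fixed_or_lost_contribute_nothing(self):
        load = inbreeding_load(np.array([0.0, 1.0]), np.array([0.2, 0.2]),
                               np.array([0.1, 0.1]))
        assert load.b == 0.0 and load.v_a == 0.0 and load.v_d == 0.0

    def test_variance_components_hand(self):
        # q=0.5, s=0.2, h=0: d=0.1, alpha=s/2+d(1-2q)=0.1
        load = inbreeding_load(np.array([0.5]), np.array([0.2]), np.array([0.0]))
        assert load.alpha[0] == pytest.approx(0.1)
        assert load.v_a == pytest.approx(2 * 0.1**2 * 0.25)
        assert load.v_d == pytest.approx(0.05**2)

    def test_log_scale_load_exceeds_b_for_strong_s(self):
        q = np.array([0.1, 0.1])
        s = np.array([0.01, 0.5])
        h = np.array([0.2, 0.1])
        b = inbreeding_load(q, s, h).b
        b_log = expected_delta_id(q, s, h)
        assert b_log > b
        # and they agree in the weak-effect limit
        weak = expected_delta_id(np.array([0.1]), np.array([0.001]), np.array([0.2]))
        weak_b = inbreeding_load(np.array([0.1]), np.array([0.001]), np.array([0.2])).b
        assert weak == pytest.approx(weak_b, rel=1e-2)


class TestSummaries:
    def _table(self, rng, n=40):
        ibd = rng.uniform(0, 0.4, n)
        return pd.DataFrame({
            "IBD": ibd,
            "COPY": ibd.copy(),
            "NOISY": ibd + rng.normal(0, 0.05, n),
        }), np.exp(-1.0 * ibd + rng.normal(0, 0.1, n))

    def test_estimator_equal_to_ibd_has_r_one_and_same_did(self, rng):
        table, w = self._table(rng)
        summ = summarize_replicate(table, w)
        assert summ.loc["COPY", "r_ibd"] == pytest.approx(1.0)
        assert summ.loc["COPY", "delta_id"] == pytest.approx(
            summ.loc["IBD", "delta_id"])

    def test_affine_transform_scales_delta_id_exactly(self, rng):
        """F' = c + a F  =>  ΔID' = ΔID / a (the F_HOM inflation identity)."""
        table, w = self._table(rng)
        a, c = 3.7, -0.2
        did = delta_id(table["IBD"].to_numpy(), w).delta_id
        did_t = delta_id(c + a * table["IBD"].to_numpy(), w).delta_id
        assert did_t == pytest.approx(did / a, rel=1e-10)

    def test_degenerate_column_gives_nan_correlation(self, rng):
        table, w = self._table(rng)
        table["CONST"] = 0.5
        summ = summarize_replicate(table, w)
        assert math.isnan(summ.loc["CONST", "r_ibd"])
        corr = correlation_matrix(table)
        assert corr["CONST"].drop("CONST").isna().all()

    def test_aggregate_power_and_bootstrap(self, rng):
        summaries = []
        for _ in range(20):
            table, w = self._table(rng)
            summaries.append(summarize_replicate(table, w))
        agg = aggregate_replicates(summaries, rng=rng)
        assert set(agg["summary"].index) == {"IBD", "COPY", "NOISY"}
        assert agg["power"]["IBD"] >= 0.0
        comp = agg["delta_id_vs_ibd"]
        assert comp.loc["COPY", "mean_difference"] == pytest.approx(0.0, abs=1e-12)
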