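"""Unit and property tests for the independent-case p-value combiners."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, kstest

from pathlancaster import (
    ChiSquareWeights,
    PValueVector,
    fisher_combine,
    good_combine,
    good_null_cdf,
    lancaster_combine,
    lancaster_pvalue_independent,
    lancaster_statistic,
    regular_z_combine,
    weighted_z_combine,
)


class TestLancasterStatistic:
    @pytest.mark.parametrize(
        "p, w, expected",
        [
            ((0.5, 0.5), (2, 2), 2.77259),
            ((1.0,), (3,), 0.0),
            ((0.05,), (2,), 5.99146),
        ],
    )
    def test_frozen_examples(self, p, w, expected):
        pv = PValueVector([f"t{i}" for i in range(len(p))], p)
        assert lancaster_statistic(pv, ChiSquareWeights(w)) == pytest.approx(
            expected, abs=1e-5
        )

    def test_matches_numeric_chi2_inverse(self, rng):
        """General weights agree with the scipy chi-square inverse CDF."""
        p = rng.uniform(0.01, 0.99, 6)
        w = rng.uniform(0.5, 8.0, 6)
        pv = PValueVector([str(i) for i in range(6)], p)
        expected = sum(chi2.ppf(1 - pi, wi) for pi, wi in zip(p, w))
        assert lancaster_statistic(pv, ChiSquareWeights(w)) == pytest.approx(
            expected, rel=1e-9
        )

    def test_rejects_nonpositive_p_and_length_mismatch(self):
        with pytest.raises(ValueError):
            PValueVector(["a"], [0.0])
        pv = PValueVector(["a", "b"], [0.5, 0.5])
        with pytest.raises(ValueError):
            lancaster_statistic(pv, ChiSquareWeights([2.0]))


class TestLancasterPValue:
    def test_survival_at_zero_is_one(self):
        res = lancaster_pvalue_independent(0.0, ChiSquareWeights([2, 2]))
        assert res.p_value == 1.0
        assert res.null_params["df"] == 4.0

    def test_chi2_4df_survival(self):
        res = lancaster_pvalue_independent(2.77259, ChiSquareWeights([2, 2]))
        assert res.p_value == pytest.approx(0.59657, abs=1e-5)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            lancaster_pvalue_independent(-0.1, ChiSquareWeights([2]))


class TestFisher:
    def test_frozen_example(self):
        res = fisher_combine(PValueVector(["a", "b"], [0.5, 0.5]))
        assert res.statistic == pytest.approx(2.77259, abs=1e-5)
        assert res.p_value == pytest.approx(0.59657, abs=1e-5)

    def test_single_test_identity(self, rng):
        for p1 in rng.uniform(0.001, 1.0, 20):
            res = fisher_combine(PValueVector(["a"], [p1]))
            assert res.p_value == pytest.approx(p1, rel=1e-10)

    def test_equals_lancaster_w2_on_random_vectors(self, rng):
        """Fisher is Lancaster with w = 2: statistic bit-for-bit, p to 1e-10."""
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = rng.uniform(1e-6, 1.0, m)
            pv = PValueVector([str(i) for i in range(m)], p)
            f = fisher_combine(pv)
            l = lancaster_combine(pv, ChiSquareWeights.uniform(m))
            assert f.statistic == l.statistic
            assert f.p_value == pytest.approx(l.p_value, abs=1e-10)


class TestWeightedZ:
    def test_centered_inputs_give_half(self):
        res = weighted_z_combine(PValueVector(["a", "b"], [0.5, 0.5]), [3.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.5, abs=1e-12)

    def test_single_test_identity(self):
        res = weighted_z_combine(PValueVector(["a"], [0.123]), [2.0])
        assert res.p_value == pytest.approx(0.123, rel=1e-10)

    def test_frozen_example(self):
        res = weighted_z_combine(PValueVector(["a", "b"], [0.05, 0.05]), [1.0, 1.0])
        assert res.statistic == pytest.approx(2.32617, abs=1e-5)
        assert res.p_value == pytest.approx(0.01000, abs=1e-5)

    def test_equal_weights_reduce_to_regular_z(self, rng):
        p = rng.uniform(0.01, 0.99, 5)
        pv = PValueVector([str(i) for i in range(5)], p)
        wz = weighted_z_combine(pv, [4.0] * 5)
        rz = regular_z_combine(pv)
        assert wz.statistic == pytest.approx(rz.statistic, rel=1e-12)

    def test_boundary_p_clamped_not_infinite(self):
        res = weighted_z_combine(PValueVector(["a", "b"], [1.0, 0.5]), [1.0, 1.0])
        assert np.isfinite(res.statistic)


class TestGood:
    def test_null_cdf_endpoints_and_frozen_value(self):
        w = ChiSquareWeights([1.0, 2.0])
        assert good_null_cdf(0.0, w) == 0.0
        assert good_null_cdf(1.0, w) == pytest.approx(1.0, abs=1e-12)
        assert good_null_cdf(0.25, w) == pytest.approx(0.75, abs=1e-12)

    def test_null_cdf_matches_monte_carlo(self, rng):
        """Closed form vs empirical CDF of Q = prod p_i^{w_i}, w=(1,2,3)."""
        w = np.array([1.0, 2.0, 3.0])
        u = rng.random((200_000, 3))
        q_draws = np.prod(u**w, axis=1)
        grid = np.linspace(0.001, 0.999, 99)
        cdf = good_null_cdf(grid, ChiSquareWeights(w))
        emp = np.searchsorted(np.sort(q_draws), grid) / q_draws.size
        assert np.max(np.abs(cdf - emp)) < 0.005

    def test_valid_cdf_for_random_distinct_weights(self, rng):
        for _ in range(20):
            w = ChiSquareWeights(rng.uniform(0.5, 10.0, 4))
            grid = np.linspace(0, 1, 101)
            cdf = good_null_cdf(grid, w)
            assert np.all(cdf >= -1e-12) and np.all(cdf <= 1 + 1e-12)
            assert np.all(np.diff(cdf) >= -1e-9)

    def test_tied_weights_rejected_by_closed_form(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            good_null_cdf(0.5, ChiSquareWeights([2.0, 2.0, 3.0]))

    def test_equal_weights_reduce_to_fisher(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 8))
            p = rng.uniform(1e-4, 1.0, m)
            pv = PValueVector([str(i) for i in range(m)], p)
            g = good_combine(pv, ChiSquareWeights.uniform(m, 1.0))
            f = fisher_combine(pv)
            assert g.statistic == pytest.approx(f.statistic / 2.0, rel=1e-12)
            assert g.p_value == pytest.approx(f.p_value, abs=1e-10)

    def test_single_test_identity(self):
        res = good_combine(PValueVector(["a"], [0.321]), ChiSquareWeights([5.0]))
        assert res.p_value == pytest.approx(0.321, rel=1e-10)

    def test_closed_form_matches_monte_carlo_pvalue(self, rng):
        pv = PValueVector(["a", "b"], [0.1, 0.2])
        w = ChiSquareWeights([1.0, 2.0])
        res = good_combine(pv, w)
        u = rng.random((400_000, 2))
        draws = -(np.log(u) * w.values).sum(axis=1)
        mc = np.mean(draws >= res.statistic)
        se = np.sqrt(mc * (1 - mc) / draws.shape[0])
        assert abs(res.p_value - mc) < 3 * se

    def test_partial_ties_use_seeded_monte_carlo(self):
        pv = PValueVector(["a", "b", "c"], [0.1, 0.2, 0.3])
        w = ChiSquareWeights([2.0, 2.0, 5.0])
        r1 = good_combine(pv, w, mc_draws=50_000, seed=9)
        r2 = good_combine(pv, w, mc_draws=50_000, seed=9)
        assert r1.p_value == r2.p_value
        assert r1.null_params["monte_carlo_draws"] == 50_000


class TestNullUniformity:
    """Under iid Uniform inputs every combiner's p-value is Uniform(0,1)."""

    M = 5
    REPS = 20_000

    def _pvalues(self, combiner, rng):
        out = np.empty(self.REPS)
        ids = [str(i) for i in range(self.M)]
        for r in range(self.REPS):
            pv = PValueVector(ids, rng.random(self.M))
            out[r] = combiner(pv)
        return out

    def test_lancaster_uniform(self, rng):
        w = ChiSquareWeights([1.0, 2.0, 3.0, 4.0, 5.0])
        p = self._pvalues(lambda pv: lancaster_combine(pv, w).p_value, rng)
        assert kstest(p, "uniform").pvalue > 0.001

    def test_fisher_uniform(self, rng):
        p = self._pvalues(lambda pv: fisher_combine(pv).p_value, rng)
        assert kstest(p, "uniform").pvalue > 0.001

    def test_weighted_z_uniform(self, rng):
        zw = [1.0, 2.0, 1.5, 0.5, 3.0]
        p = self._pvalues(lambda pv: weighted_z_combine(pv, zw).p_value, rng)
        assert kstest(p, "uniform").pvalue > 0.001

    def test_good_uniform(self, rng):
        w = ChiSquareWeights([1.0, 2.0, 3.0, 4.0, 5.0])
        p = self._pvalues(lambda pv: good_combine(pv, w).p_value, rng)
        assert kstest(p, "uniform").pvalue > 0.001


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    data=st.lists(
        st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8
    ),
    idx=st.integers(min_value=0, max_value=7),
    factor=st.floats(min_value=0.05, max_value=0.95),
)
def test_combiners_monotone_in_each_pvalue(data, idx, factor):
    """Decreasing any single p never increases the combined p-value."""
    m = len(data)
    idx = idx % m
    ids = [str(i) for i in range(m)]
    w = ChiSquareWeights([1.0 + 0.5 * i for i in range(m)])
    lower = list(data)
    lower[idx] = data[idx] * factor
    pv_hi, pv_lo = PValueVector(ids, data), PValueVector(ids, lower)
    assert lancaster_combine(pv_lo, w).p_value <= lancaster_combine(pv_hi, w).p_value + 1e-12
    assert fisher_combine(pv_lo).p_value <= fisher_combine(pv_hi).p_value + 1e-12
    assert (
        weighted_z_combine(pv_lo, w.values).p_value
        <= weighted_z_combine(pv_hi, w.values).p_value + 1e-12
    )
    assert good_combine(pv_lo, w).p_value <= good_combine(pv_hi, w).p_value + 1e-12
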