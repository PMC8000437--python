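"""Index tests: AUC/DeLong, IDI, continuous NRI against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import macrohier as mh


def brute_force_auc(scores, outcome):
    """Exhaustive pair counting: P(score_event > score_nonevent) + half ties."""
    ev = scores[outcome == 1]
    ne = scores[outcome == 0]
    wins = sum((x > y) + 0.5 * (x == y) for x in ev for y in ne)
    return wins / (len(ev) * len(ne))


class TestAuc:
    def test_perfect_separation(self):
        res = mh.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert res.estimate == 1.0

    def test_all_ties_give_half(self):
        res = mh.auc([0.5] * 6, [1, 1, 0, 0, 0, 0])
        assert res.estimate == 0.5

    def test_small_example_pair_enumeration(self):
        """Events (0.9, 0.4) vs non-events (0.5, 0.3, 0.1): 5 of the 6
        event/non-event pairs are concordant and there are no ties."""
        scores = np.array([0.9, 0.4, 0.5, 0.3, 0.1])
        outcome = np.array([1, 1, 0, 0, 0])
        res = mh.auc(scores, outcome)
        assert res.estimate == pytest.approx(brute_force_auc(scores, outcome))
        assert res.estimate == pytest.approx(5 / 6)

    def test_one_class_raises(self):
        with pytest.raises(ValueError, match="event"):
            mh.auc([0.1, 0.2], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**9))
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        outcome = np.zeros(n, dtype=int)
        outcome[: int(rng.integers(1, n - 1))] = 1
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        res = mh.auc(scores, outcome)
        assert res.estimate == pytest.approx(brute_force_auc(scores, outcome))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**9))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        outcome = (rng.random(30) < 0.4).astype(int)
        if outcome.min() == outcome.max():
            outcome[0] = 1 - outcome[0]
        a = mh.auc(scores, outcome).estimate
        b = mh.auc(np.exp(2.0 * scores) + 3.0, outcome).estimate
        assert a == pytest.approx(b)

    def test_delong_ci_contains_estimate(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=200) + 0.8 * (rng.random(200) < 0.3)
        outcome = (rng.random(200) < 0.3).astype(int)
        res = mh.auc(scores, outcome)
        assert 0.0 <= res.ci_low <= res.estimate <= res.ci_high <= 1.0


class TestAucDifference:
    def test_printed_table_arithmetic(self):
        """Extended 0.706 minus base 0.564 gives the printed difference 0.142."""
        assert round(0.706 - 0.564, 3) == pytest.approx(0.142)

    def test_identical_scores_give_zero(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        res = mh.auc_difference(p, p, y)
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            mh.auc_difference([0.1, 0.2], [0.1], [1, 0])

    def test_delong_ci_against_paired_bootstrap(self):
        """DeLong interval for the AUC difference agrees with a 10,000-draw
        paired bootstrap on toy data (Monte-Carlo tolerance)."""
        rng = np.random.default_rng(12)
        n = 120
        y = np.r_[np.ones(30, dtype=int), np.zeros(90, dtype=int)]
        signal = rng.normal(size=n)
        p_base = 0.3 * y + rng.normal(scale=1.0, size=n)
        p_ext = p_base + 0.8 * y + rng.normal(scale=0.5, size=n)
        res = mh.auc_difference(p_base, p_ext, y)
        boots = []
        for _ in range(10_000):
            idx = np.r_[rng.integers(0, 30, 30), 30 + rng.integers(0, 90, 90)]
            boots.append(mh.auc_difference(p_base[idx], p_ext[idx], y[idx]).estimate)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert res.ci_low == pytest.approx(lo, abs=0.05)
        assert res.ci_high == pytest.approx(hi, abs=0.05)


class TestIdi:
    def test_identical_models_zero(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        y = np.r_[np.ones(10, dtype=int), np.zeros(30, dtype=int)]
        assert mh.idi(p, p, y).estimate == 0.0

    def test_hand_computation(self):
        """Events: base (0.2, 0.4) -> ext (0.3, 0.5); non-events: (0.1, 0.3)
        -> (0.1, 0.2).  IDI = 0.10 - (-0.05) = 0.15."""
        res = mh.idi([0.2, 0.4, 0.1, 0.3], [0.3, 0.5, 0.1, 0.2], [1, 1, 0, 0])
        assert res.estimate == pytest.approx(0.15)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**9))
    def test_equals_discrimination_slope_difference(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        y = (rng.random(n) < 0.3).astype(int)
        if y.min() == y.max():
            y[:2] = [0, 1]
        p_base, p_ext = rng.random(n), rng.random(n)
        slope = lambda p: p[y == 1].mean() - p[y == 0].mean()
        res = mh.idi(p_base, p_ext, y)
        assert res.estimate == pytest.approx(slope(p_ext) - slope(p_base), abs=1e-12)

    def test_one_class_raises(self):
        with pytest.raises(ValueError, match="event"):
            mh.idi([0.1], [0.2], [1])


class TestNri:
    def test_identical_models_all_ties(self):
        rng = np.random.default_rng(0)
        p = rng.random(30)
        y = np.r_[np.ones(10, dtype=int), np.zeros(20, dtype=int)]
        res, dec = mh.nri_continuous(p, p, y)
        assert res.estimate == 0.0
        assert dec.u1 == dec.d1 == dec.u0 == dec.d0 == 0.0

    def test_hand_count(self):
        """Events: 2 of 3 up, 1 down; non-events: 3 of 4 down, 1 up.
        NRI = 1/3 + 1/2 = 5/6."""
        p_base = np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        p_ext = np.array([0.6, 0.7, 0.4, 0.4, 0.3, 0.2, 0.6])
        y = np.array([1, 1, 1, 0, 0, 0, 0])
        res, dec = mh.nri_continuous(p_base, p_ext, y)
        assert res.estimate == pytest.approx(5 / 6)
        assert dec.nri1 == pytest.approx(1 / 3)
        assert dec.nri0 == pytest.approx(1 / 2)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(3)
        n = 200
        y = (rng.random(n) < 0.25).astype(int)
        p_base, p_ext = rng.random(n), rng.random(n)
        res, dec = mh.nri_continuous(p_base, p_ext, y)
        assert res.estimate == pytest.approx(dec.nri1 + dec.nri0, abs=1e-15)
        assert dec.u1 + dec.d1 <= 1.0 and dec.u0 + dec.d0 <= 1.0

    def test_printed_weight_row_reproduced(self):
        """Printed down/up proportions for base + pre-pregnancy weight give
        NRI 0.538 with CI (0.330, 0.746)."""
        res, dec = mh.nri_from_proportions(u1=0.567, d1=0.433, u0=0.298,
                                           d0=0.702, n1=97, n0=755)
        assert round(res.estimate, 3) == pytest.approx(0.538)
        assert res.ci_low == pytest.approx(0.330, abs=0.005)
        assert res.ci_high == pytest.approx(0.746, abs=0.005)
        assert round(100 * dec.nri1, 1) == pytest.approx(13.4)

    def test_printed_gdm_row_reproduced(self):
        res, _ = mh.nri_from_proportions(u1=0.2165, d1=0.7835, u0=0.1589,
                                         d0=0.8411, n1=97, n0=755)
        assert round(res.estimate, 3) == pytest.approx(0.115)
        assert res.ci_low == pytest.approx(-0.057, abs=0.005)
        assert res.ci_high == pytest.approx(0.287, abs=0.005)

    def test_one_class_raises(self):
        with pytest.raises(ValueError, match="event"):
            mh.nri_continuous([0.1], [0.2], [0])

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            mh.nri_from_proportions(u1=0.8, d1=0.4, u0=0.1, d0=0.2, n1=10, n0=10)


class TestNullCalibration:
    def test_nri_and_idi_reject_near_nominal_rate(self):
        """With outcome-independent noise added to the base risks, the NRI and
        IDI z-tests reject at roughly the nominal 5 % level."""
        rng = np.random.default_rng(2024)
        reps = 600
        rej_nri = rej_idi = 0
        y = np.r_[np.ones(80, dtype=int), np.zeros(400, dtype=int)]
        for _ in range(reps):
            p_base = rng.uniform(0.05, 0.4, len(y))
            p_ext = p_base + rng.normal(scale=0.01, size=len(y))
            res_nri, _ = mh.nri_continuous(p_base, p_ext, y)
            res_idi = mh.idi(p_base, p_ext, y)
            rej_nri += res_nri.p_value < 0.05
            rej_idi += res_idi.p_value < 0.05
        assert 0.02 <= rej_nri / reps <= 0.09
        assert 0.02 <= rej_idi / reps <= 0.09


class TestSampleSize:
    def test_study_value(self):
        assert mh.sample_size_min(0.10, 0.02, alpha=0.05) == 864

    def test_zero_proportion(self):
        assert mh.sample_size_min(0.0, 0.02) == 0

    def test_direct_arithmetic(self):
        assert mh.sample_size_min(0.5, 0.05, z=1.96) == 384

    def test_z_override(self):
        # a coarser Z rounds through to a different truncated n
        assert mh.sample_size_min(0.10, 0.02, z=1.962) == 866

    def test_bad_margin(self):
        with pytest.raises(ValueError, match="margin"):
            mh.sample_size_min(0.1, 0.0)
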