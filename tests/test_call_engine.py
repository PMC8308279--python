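"""Detection calls, change calls and signal log ratios."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from crconsensus.call_engine import (
    change_pvalue,
    classify_change,
    detection_call,
    discrimination_scores,
    signal_log_ratio,
    tukey_biweight,
)
from conftest import make_pair_set


class TestDiscriminationScores:
    @pytest.mark.parametrize(
        "pm, mm, expected",
        [
            ([200, 200], [100, 100], [1 / 3, 1 / 3]),
            ([150, 80], [150, 80], [0.0, 0.0]),
            ([300, 100], [100, 300], [0.5, -0.5]),
        ],
    )
    def test_examples(self, pm, mm, expected):
        scores = discrimination_scores(make_pair_set(pm, mm))
        assert scores == pytest.approx(expected)

    def test_rejects_non_positive_intensity(self):
        with pytest.raises(ValueError):
            make_pair_set([100, -5], [50, 50])


class TestDetectionCall:
    def test_strong_signal_is_present(self):
        # ten identical scores above tau: exact one-sided p = 1/2^10
        res = detection_call(np.full(10, 0.5))
        assert res.p_value == pytest.approx(1 / 1024, abs=1e-15)
        assert res.call == "present"

    def test_scores_at_tau_are_absent(self):
        res = detection_call(np.full(8, 0.015))
        assert res.p_value == 1.0
        assert res.call == "absent"

    def test_marginal_band(self):
        # positive ranks {1,3,4,5,6}, negative rank {2}: p = 3/64 ~ 0.047,
        # inside the marginal band [0.04, 0.06)
        scores = 0.015 + np.array([0.1, -0.2, 0.3, 0.4, 0.5, 0.6])
        res = detection_call(scores)
        assert res.p_value == pytest.approx(3 / 64, abs=1e-15)
        assert res.call == "marginal"

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            detection_call(np.array([]))

    @given(
        scores=st.lists(st.floats(-0.9, 0.9), min_size=2, max_size=9),
        idx=st.integers(0, 8),
        bump=st.floats(0.01, 0.5),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_p_nonincreasing_in_any_score(self, scores, idx, bump):
        # Monotonicity holds for tie-free magnitude configurations; exact
        # magnitude ties can flip it because mid-ranking conditions the null
        # on a different rank multiset, so tied cases are filtered out.
        idx = idx % len(scores)
        raised = list(scores)
        raised[idx] += bump

        def tie_free(vals):
            mags = [abs(v - 0.015) for v in vals]
            return 0.0 not in mags and len(set(mags)) == len(mags)

        assume(tie_free(scores) and tie_free(raised))
        before = detection_call(np.array(scores)).p_value
        after = detection_call(np.array(raised)).p_value
        assert after <= before + 1e-12


class TestChangePvalue:
    def test_identical_chips_give_half(self):
        b = make_pair_set([200, 300, 400], [100, 150, 180])
        assert change_pvalue(b, b) == 0.5

    def test_uniform_increase_tail(self):
        b = make_pair_set([200] * 10, [100] * 10)
        e = make_pair_set([410, 420, 430, 440, 450, 460, 470, 480, 490, 500], [100] * 10)
        # every background-adjusted difference positive; mid-p tail of the
        # top statistic is half the point mass: 1/2^(n+1)
        assert change_pvalue(b, e) == pytest.approx(1 / 2**11, abs=1e-15)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        pm_b = rng.uniform(200, 900, 11)
        pm_e = rng.uniform(200, 900, 11)
        b = make_pair_set(pm_b, pm_b * 0.4)
        e = make_pair_set(pm_e, pm_e * 0.4)
        assert change_pvalue(b, e) == pytest.approx(1 - change_pvalue(e, b), abs=1e-12)

    def test_mismatched_probe_sets_rejected(self):
        b = make_pair_set([200], [100], probe="a")
        e = make_pair_set([200], [100], probe="b")
        with pytest.raises(ValueError):
            change_pvalue(b, e)


class TestClassifyChange:
    @pytest.mark.parametrize(
        "p, call",
        [
            (0.001, "increase"),
            (0.0025, "increase"),
            (0.0026, "marginal_increase"),
            (0.003, "marginal_increase"),
            (0.5, "no_change"),
            (0.9969, "no_change"),
            (0.997, "marginal_decrease"),
            (0.9975, "marginal_decrease"),
            (0.998, "decrease"),
            (1.0, "decrease"),
        ],
    )
    def test_thresholds_and_boundaries(self, p, call):
        assert classify_change(p) == call

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify_change(1.2)

    @given(st.floats(0, 1, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partitions_unit_interval(self, p):
        assert classify_change(p) in {
            "increase",
            "marginal_increase",
            "no_change",
            "marginal_decrease",
            "decrease",
        }


def brute_force_biweight(x, c=5.0, eps=1e-4):
    """Direct evaluation of the one-step biweight weighted mean."""
    x = np.asarray(x, dtype=float)
    t = float(np.median(x))
    s = float(np.median(np.abs(x - t)))
    num = den = 0.0
    for xi in x:
        u = (xi - t) / (c * s + eps)
        w = (1 - u * u) ** 2 if abs(u) < 1 else 0.0
        num += w * xi
        den += w
    return num / den


class TestSignalLogRatio:
    def test_exact_doubling_gives_one(self):
        b = make_pair_set([200, 300, 400, 500], [100, 120, 150, 180])
        e = make_pair_set([400, 600, 800, 1000], [200, 240, 300, 360])
        assert signal_log_ratio(b, e) == pytest.approx(1.0, abs=1e-12)

    def test_identity_gives_zero(self):
        b = make_pair_set([250, 300, 350], [120, 140, 160])
        assert signal_log_ratio(b, b) == pytest.approx(0.0, abs=1e-12)

    def test_outlier_downweighted_matches_brute_force(self):
        ratios = np.array([1.0, 1.0, 1.0, 1.0, 5.0])
        est = tukey_biweight(ratios)
        assert est == pytest.approx(brute_force_biweight(ratios), abs=1e-12)
        assert est < np.mean(ratios)

    @pytest.mark.parametrize("k", [1, 3, -2])
    def test_shift_equivariance(self, k):
        rng = np.random.default_rng(11)
        pm = rng.uniform(300, 900, 11)
        b = make_pair_set(pm, pm * 0.45)
        e = make_pair_set(pm * 2.0**k, pm * 0.45 * 2.0**k)
        base = signal_log_ratio(b, b)
        assert signal_log_ratio(b, e) == pytest.approx(base + k, abs=1e-9)

    @given(
        st.lists(st.floats(-4, 4, allow_nan=False), min_size=1, max_size=15),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_biweight_matches_brute_force(self, ratios):
        assert tukey_biweight(np.array(ratios)) == pytest.approx(
            brute_force_biweight(ratios), abs=1e-10
        )
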