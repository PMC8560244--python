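import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mheval import entropy as ent

LN2 = math.log(2.0)


class TestExactMeasures:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((4, 0), 0.0),
            ((7, 7), 1.0),
            ((9, 5), 0.9402859586706311),  # frozen from -sum(p*log2(p))
        ],
    )
    def test_entropy_values(self, counts, expected):
        assert ent.exact_entropy(counts) == pytest.approx(expected, abs=1e-9)

    def test_entropy_rejects_empty(self):
        with pytest.raises(ValueError):
            ent.exact_entropy((0, 0))

    def test_gain_ratio_fixture(self):
        part = ent.PartitionCounts(np.array([[6, 2], [3, 3]]))
        c = ent.exact_gain_ratio((9, 5), part)
        assert c.gain == pytest.approx(0.04812703040826949, abs=1e-9)
        assert c.split_info == pytest.approx(0.9852281360342515, abs=1e-9)
        assert c.gain_ratio == pytest.approx(0.048848615511520824, abs=1e-9)

    def test_perfect_split_has_unit_everything(self):
        part = ent.PartitionCounts(np.array([[7, 0], [0, 7]]))
        c = ent.exact_gain_ratio((7, 7), part)
        assert (c.gain, c.split_info, c.gain_ratio) == (1.0, 1.0, 1.0)

    def test_one_branch_split_is_invalid_not_an_exception(self):
        part = ent.PartitionCounts(np.array([[9, 5], [0, 0]]))
        c = ent.exact_gain_ratio((9, 5), part)
        assert not c.valid

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=40), min_size=2, max_size=5))
    def test_entropy_bounds(self, counts):
        total = sum(counts)
        if total == 0:
            return
        h = ent.exact_entropy(counts)
        m = len(counts)
        assert -1e-12 <= h <= math.log2(m) + 1e-9
        nonzero = [c for c in counts if c > 0]
        if len(nonzero) == 1:
            assert h == pytest.approx(0.0, abs=1e-9)
        if len(set(counts)) == 1:
            assert h == pytest.approx(math.log2(m), abs=1e-9)


class TestMaclaurin:
    def test_ln_values(self):
        assert ent.maclaurin_ln(1.0) == 0.0
        assert ent.maclaurin_ln(0.5) == pytest.approx(-2.0 / 3.0, abs=1e-12)
        assert ent.maclaurin_ln(0.9) == pytest.approx(-0.10533333333333333, abs=1e-12)

    @pytest.mark.parametrize("x", [0.0, -0.5, 1.5])
    def test_ln_domain(self, x):
        with pytest.raises(ValueError):
            ent.maclaurin_ln(x)

    def test_plogp_values(self):
        assert ent.approx_plogp(2, 2) == 0.0
        assert ent.approx_plogp(0, 5) == 0.0
        assert ent.approx_plogp(1, 2) == pytest.approx(-1.0 / 3.0, abs=1e-12)
        assert ent.approx_plogp(1, 3) == pytest.approx(-80.0 / 243.0, abs=1e-12)
        with pytest.raises(ValueError):
            ent.approx_plogp(4, 3)

    def test_plogp_equals_fraction_times_polynomial_ln_exhaustively(self):
        # the closed rational form must agree with (a/b)*maclaurin_ln(a/b)
        for b in range(1, 51):
            for a in range(1, b + 1):
                direct = (a / b) * ent.maclaurin_ln(a / b)
                assert ent.approx_plogp(a, b) == pytest.approx(direct, abs=1e-12)

    def test_approx_entropy_values(self):
        assert ent.approx_entropy((4, 0)) == 0.0
        assert ent.approx_entropy((7, 7)) == pytest.approx((2.0 / 3.0) / LN2, abs=1e-9)
        assert ent.approx_entropy((1, 1, 1)) == pytest.approx(
            3.0 * (80.0 / 243.0) / LN2, abs=1e-9
        )

    def test_relative_error_small_for_balanced_proportions(self):
        # within class proportions in [0.4, 0.6] the cubic surrogate stays
        # within 5% of the true entropy; the error grows quickly outside
        worst = 0.0
        for b in range(5, 61):
            for a in range(int(np.ceil(0.4 * b)), int(0.6 * b) + 1):
                exact = ent.exact_entropy((a, b - a))
                approx = ent.approx_entropy((a, b - a))
                worst = max(worst, abs(approx - exact) / exact)
        assert worst <= 0.05


class TestApproxGainRatio:
    def test_perfect_split_ratio_is_one(self):
        part = ent.PartitionCounts(np.array([[7, 0], [0, 7]]))
        c = ent.approx_gain_ratio((7, 7), part)
        assert c.valid
        assert c.gain_ratio == pytest.approx(1.0, abs=1e-12)

    def test_fixture_close_to_exact(self):
        part = ent.PartitionCounts(np.array([[6, 2], [3, 3]]))
        exact = ent.exact_gain_ratio((9, 5), part)
        approx = ent.approx_gain_ratio((9, 5), part)
        assert abs(approx.gain_ratio - exact.gain_ratio) <= 0.02

    def test_ratio_invariant_to_common_scaling_of_terms(self):
        # recompute the ratio in nats (dropping the 1/ln2 prefactor from all
        # three entropy terms): the quotient must be unchanged
        part = ent.PartitionCounts(np.array([[6, 2], [3, 3]]))
        c = ent.approx_gain_ratio((9, 5), part)
        total = 14
        info_s = -(ent.approx_plogp(9, 14) + ent.approx_plogp(5, 14))
        cond = 0.0
        split = 0.0
        for row in part.table:
            s_j = int(row.sum())
            cond -= (s_j / total) * sum(ent.approx_plogp(int(x), s_j) for x in row)
            split -= ent.approx_plogp(s_j, total)
        assert (info_s - cond) / split == pytest.approx(c.gain_ratio, rel=1e-12)

    def test_degenerate_split_invalid(self):
        part = ent.PartitionCounts(np.array([[9, 5], [0, 0]]))
        assert not ent.approx_gain_ratio((9, 5), part).valid


class TestDiscretization:
    def test_equal_division_fixture(self):
        c = ent.discretize_continuous([1, 2, 3, 4], ["A", "A", "B", "B"], n_points=3)
        assert c.valid
        assert c.threshold == pytest.approx(2.5)
        assert c.gain == pytest.approx(1.0, abs=1e-12)
        assert c.gain_ratio == pytest.approx(1.0, abs=1e-12)

    def test_interleaved_labels_have_weak_best_split(self):
        c = ent.discretize_continuous([1, 2, 3, 4], ["A", "B", "A", "B"], n_points=3)
        assert c.gain < 0.32

    def test_constant_values_invalid_and_bad_args(self):
        assert not ent.discretize_continuous([2, 2, 2], ["A", "B", "A"]).valid
        with pytest.raises(ValueError):
            ent.discretize_continuous([1, 2], ["A", "B"], n_points=0)
        with pytest.raises(ValueError):
            ent.discretize_continuous([1.0], ["A"])

    def test_tam_mode_matches_exact_on_clean_fixture(self):
        e = ent.discretize_continuous([1, 2, 3, 4], ["A", "A", "B", "B"], mode="exact")
        t = ent.discretize_continuous([1, 2, 3, 4], ["A", "A", "B", "B"], mode="tam")
        assert e.threshold == t.threshold

    def test_midpoint_candidate_alternative(self):
        c = ent.discretize_continuous(
            [1, 2, 3, 4], ["A", "A", "B", "B"], midpoint_candidates=True
        )
        assert c.threshold == pytest.approx(2.5)


class TestInstrumentation:
    def test_approx_path_makes_zero_log_calls(self):
        ent.reset_transcendental_counter()
        part = ent.PartitionCounts(np.array([[6, 2], [3, 3]]))
        ent.approx_gain_ratio((9, 5), part)
        ent.approx_entropy((9, 5))
        ent.discretize_continuous([1, 2, 3, 4], ["A", "A", "B", "B"], mode="tam")
        assert ent.transcendental_call_count() == 0

    def test_exact_path_is_counted(self):
        ent.reset_transcendental_counter()
        ent.exact_entropy((9, 5))
        assert ent.transcendental_call_count() > 0
        ent.reset_transcendental_counter()


class TestRankAgreement:
    def test_argmax_attribute_agreement_under_bounded_proportions(self):
        assert ent.gain_ratio_rank_agreement(seed=20240917) >= 0.95
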