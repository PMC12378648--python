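import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autotrunc import (
    AmpliconModel,
    QualityProfile,
    TruncationError,
    TruncationPoint,
    aggregate_truncation,
    apply_overlap_constraint,
    find_truncation_point,
    profile_fastq,
    recommend_strategy,
)

from conftest import make_record


def profile_from_medians(medians, grand_mean):
    """Synthetic profile: the detector only reads medians + grand mean."""
    medians = np.asarray(medians, dtype=float)
    n = medians.size
    return QualityProfile(
        n_reads=10,
        max_len=n,
        coverage=np.full(n, 10),
        pos_mean=medians.copy(),
        pos_median=medians,
        grand_mean=grand_mean,
        source="synthetic",
    )


class TestFindTruncationPoint:
    def test_micro_matrix_crossing(self, micro_matrix_records):
        p = profile_fastq(micro_matrix_records)
        # medians (40,38,25,10) vs grand mean 28.25: first drop at cycle 3
        assert find_truncation_point(p).length == 2

    def test_no_crossing_keeps_full_length(self):
        p = profile_from_medians([30] * 6, 30.0)
        tp = find_truncation_point(p)
        assert tp.length == 6

    def test_plateau_then_drop(self):
        p = profile_from_medians([30, 30, 30, 20, 20], 26.0)
        assert find_truncation_point(p).length == 3

    def test_crossing_must_be_strict(self):
        # median exactly equal to the average never triggers
        p = profile_from_medians([30, 26, 26], 26.0)
        assert find_truncation_point(p).length == 3

    def test_crossing_at_position_one_is_an_error(self):
        p = profile_from_medians([10, 40, 40], 30.0)
        with pytest.raises(TruncationError, match="position 1"):
            find_truncation_point(p)

    def test_tail_degradation_never_lengthens_truncation(self):
        # lowering medians after cycle k (grand mean held fixed) can only
        # move the first crossing earlier or keep it
        base = np.array([38.0, 38, 36, 34, 30, 24, 20, 18])
        gm = 30.0
        ref = find_truncation_point(profile_from_medians(base, gm)).length
        for k in range(2, 8):
            worse = base.copy()
            worse[k:] -= 5
            got = find_truncation_point(profile_from_medians(worse, gm)).length
            assert got <= ref


class TestAggregate:
    def test_exact_mean(self):
        pts = [TruncationPoint(f"f{i}", "forward", n) for i, n in enumerate([220, 230, 240])]
        assert aggregate_truncation(pts, "forward") == 230

    def test_single_file_identity(self):
        assert aggregate_truncation([TruncationPoint("f", "reverse", 187)], "reverse") == 187

    def test_floor_rounding(self):
        pts = [TruncationPoint("a", "forward", 221), TruncationPoint("b", "forward", 222)]
        assert aggregate_truncation(pts, "forward") == 221  # mean 221.5 floors

    def test_directions_kept_separate(self):
        pts = [
            TruncationPoint("a", "forward", 250),
            TruncationPoint("b", "reverse", 100),
        ]
        assert aggregate_truncation(pts, "forward") == 250
        assert aggregate_truncation(pts, "reverse") == 100
        with pytest.raises(ValueError):
            aggregate_truncation([pts[0]], "reverse")


class TestOverlapConstraint:
    def test_constraint_lengthens_forward_minimally(self):
        plan = apply_overlap_constraint(230, 160, AmpliconModel(400))
        assert (plan.r1_final, plan.r2_final) == (252, 160)
        assert plan.constrained and plan.feasible
        assert plan.expected_overlap == 12

    def test_inactive_when_overlap_sufficient(self):
        plan = apply_overlap_constraint(290, 160, AmpliconModel(400))
        assert plan.r1_final == 290 and not plan.constrained and plan.feasible

    def test_infeasible_capped_at_read_length(self):
        plan = apply_overlap_constraint(250, 80, AmpliconModel(400))
        assert plan.r1_final == 300
        assert not plan.feasible
        assert plan.expected_overlap == -20

    @settings(max_examples=300, deadline=None)
    @given(
        r1=st.integers(1, 300),
        r2=st.integers(1, 300),
        amplicon=st.integers(50, 580),
        min_overlap=st.integers(1, 100),
    )
    def test_algebraic_properties(self, r1, r2, amplicon, min_overlap):
        model = AmpliconModel(amplicon, min_overlap)
        plan = apply_overlap_constraint(r1, r2, model)
        # forward-only adjustment
        assert plan.r2_final == r2
        assert plan.r1_final >= plan.r1_raw
        assert plan.r1_final <= model.max_read_len
        if plan.feasible:
            # overlap guarantee
            assert plan.expected_overlap >= min_overlap
            if plan.constrained:
                # minimality: one base less would break the guarantee
                assert (plan.r1_final - 1) + r2 - amplicon < min_overlap
            # idempotence on the final lengths
            again = apply_overlap_constraint(plan.r1_final, plan.r2_final, model)
            assert (again.r1_final, again.r2_final) == (plan.r1_final, plan.r2_final)
            assert not again.constrained


class TestRecommendStrategy:
    def _reverse_profile(self, tail_q):
        quals = [35] * 80 + [tail_q] * 20
        return profile_fastq([make_record("r", quals)])

    def test_infeasible_forces_single_end(self):
        plan = apply_overlap_constraint(250, 80, AmpliconModel(400))
        rec = recommend_strategy(plan, self._reverse_profile(35))
        assert rec.strategy == "single_forward"
        assert "overlap infeasible" in rec.rationale

    def test_good_reverse_tail_keeps_pairing(self):
        plan = apply_overlap_constraint(290, 160, AmpliconModel(400))
        rec = recommend_strategy(plan, self._reverse_profile(35))
        assert rec.strategy == "paired"

    def test_poor_reverse_tail_forces_single_end(self):
        plan = apply_overlap_constraint(290, 160, AmpliconModel(400))
        rec = recommend_strategy(plan, self._reverse_profile(12))
        assert rec.strategy == "single_forward"
        assert "reverse tail quality" in rec.rationale


def test_amplicon_model_validation():
    with pytest.raises(ValueError):
        AmpliconModel(0)
    with pytest.raises(ValueError):
        AmpliconModel(400, min_overlap=0)
    with pytest.raises(ValueError):
        AmpliconModel(400, min_overlap=600, max_read_len=300)
    assert AmpliconModel(400).min_overlap == 12
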