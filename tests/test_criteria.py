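import math

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from gistvol.cohort import TimepointSummary
from gistvol.criteria import (
    Category,
    Criteria,
    CutoffSet,
    Direction,
    ELLIPSOID_CUTOFFS,
    RECIST_CUTOFFS,
    SPHERE_CUTOFFS,
    classify_choi,
    classify_recist,
    classify_size_change,
    classify_volume,
    derive_sphere_cutoffs,
    ellipsoid_volume,
    invert_sphere_cutoffs,
    relative_change,
    sphere_volume,
)


def summary(pid="P1", tp=0, diameter=100.0, volume=20.0, density=None,
            density_change=None):
    return TimepointSummary(
        patient_id=pid,
        timepoint_months=tp,
        sum_longest_diameter_mm=diameter,
        total_volume_mL=volume,
        mean_density_HU=density,
        mean_relative_density_change_pct=density_change,
    )


class TestGeometry:
    def test_relative_change(self):
        assert relative_change(100, 70) == pytest.approx(-30)
        assert relative_change(50, 50) == 0
        assert relative_change(10, 12) == pytest.approx(20)

    def test_relative_change_bad_baseline(self):
        with pytest.raises(ValueError):
            relative_change(0, 10)

    def test_sphere_volume_closed_form(self):
        assert sphere_volume(2.0) == pytest.approx(math.pi * 8 / 6)

    def test_sphere_diameter_reduction_30pct_leaves_0p343(self):
        assert sphere_volume(0.7) / sphere_volume(1.0) == pytest.approx(0.343)

    def test_sphere_doubling_scales_by_8(self):
        assert sphere_volume(2.0) / sphere_volume(1.0) == pytest.approx(8.0)

    def test_ellipsoid_sphere_special_case(self):
        assert ellipsoid_volume(1, 1, 1) == pytest.approx(sphere_volume(2.0))
        assert ellipsoid_volume(1, 1, 2) == pytest.approx(8 * math.pi / 3)

    def test_ellipsoid_single_axis_shrink_is_proportional(self):
        v0 = ellipsoid_volume(10, 10, 20)
        v1 = ellipsoid_volume(10, 10, 20 * 0.7)
        assert relative_change(v0, v1) == pytest.approx(-30.0)

    def test_non_positive_inputs(self):
        with pytest.raises(ValueError):
            sphere_volume(0)
        with pytest.raises(ValueError):
            ellipsoid_volume(1, -1, 2)


class TestCutoffDerivation:
    def test_recist_to_sphere(self):
        assert SPHERE_CUTOFFS.pr_cutoff_pct == pytest.approx(-65.7)
        assert SPHERE_CUTOFFS.pd_cutoff_pct == pytest.approx(72.8)

    def test_degenerate(self):
        c = derive_sphere_cutoffs(CutoffSet(Criteria.RECIST, 0.0, 0.0))
        assert c.pr_cutoff_pct == 0 and c.pd_cutoff_pct == 0

    def test_cube_law_50(self):
        c = derive_sphere_cutoffs(CutoffSet(Criteria.RECIST, -50.0, 50.0))
        assert c.pr_cutoff_pct == pytest.approx(-87.5)
        assert c.pd_cutoff_pct == pytest.approx(237.5)

    def test_inversion_recovers_recist(self):
        back = invert_sphere_cutoffs(SPHERE_CUTOFFS)
        assert back.pr_cutoff_pct == pytest.approx(-30.0, abs=1e-9)
        assert back.pd_cutoff_pct == pytest.approx(20.0, abs=1e-9)

    def test_cutoff_set_json_roundtrip(self):
        assert CutoffSet.from_dict(SPHERE_CUTOFFS.to_dict()) == SPHERE_CUTOFFS


class TestClassifyRecist:
    def test_pr_boundary_inclusive(self):
        call = classify_recist(summary(tp=3, diameter=70), summary())
        assert call.category is Category.PR

    def test_sd_below_pd(self):
        call = classify_recist(summary(tp=3, diameter=119), summary())
        assert call.category is Category.SD

    def test_new_lesion_overrides(self):
        call = classify_recist(summary(tp=3, diameter=90), summary(), new_lesion=True)
        assert call.category is Category.PD

    def test_new_lesion_overrides_size_pr(self):
        call = classify_recist(summary(tp=3, diameter=60), summary(), new_lesion=True)
        assert call.category is Category.PD

    def test_mismatched_targets_rejected(self):
        s0 = TimepointSummary("P1", 0, 100, 20, lesion_ids=("A", "B"))
        s3 = TimepointSummary("P1", 3, 70, 10, lesion_ids=("A", "C"))
        with pytest.raises(ValueError, match="mismatched"):
            classify_recist(s3, s0)


class TestClassifyVolume:
    def test_sphere_pr_boundary(self):
        call = classify_volume(summary(tp=3, volume=6.8), summary(), SPHERE_CUTOFFS)
        assert call.category is Category.PR  # -66% <= -65.7%

    def test_minus_30_splits_criteria(self):
        s0, s3 = summary(), summary(tp=3, volume=14.0)
        assert (
            classify_volume(s3, s0, ELLIPSOID_CUTOFFS).category is Category.PR
        )
        assert classify_volume(s3, s0, SPHERE_CUTOFFS).category is Category.SD

    def test_unchanged_is_sd(self):
        s0, s3 = summary(), summary(tp=3)
        for cutoffs in (SPHERE_CUTOFFS, ELLIPSOID_CUTOFFS):
            assert classify_volume(s3, s0, cutoffs).category is Category.SD

    def test_recist_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            classify_volume(summary(tp=3), summary(), RECIST_CUTOFFS)


class TestClassifyChoi:
    def test_size_pr(self):
        call = classify_choi(
            summary(tp=3, diameter=88, density_change=-5.0), summary()
        )
        assert call.category is Category.PR

    def test_density_pr_despite_size_growth(self):
        call = classify_choi(
            summary(tp=3, diameter=104, density_change=-20.0), summary()
        )
        assert call.category is Category.PR

    def test_size_pd(self):
        call = classify_choi(
            summary(tp=3, diameter=111, density_change=-2.0), summary()
        )
        assert call.category is Category.PD

    def test_new_nodule_is_pd_even_with_density_response(self):
        call = classify_choi(
            summary(tp=3, diameter=95, density_change=-40.0),
            summary(),
            new_nodule=True,
        )
        assert call.category is Category.PD

    def test_missing_density_flagged_and_classified_on_size(self):
        call = classify_choi(summary(tp=3, diameter=88), summary())
        assert call.density_missing
        assert call.category is Category.PR
        call = classify_choi(summary(tp=3, diameter=95), summary())
        assert call.category is Category.SD


class TestClassifySizeChange:
    @pytest.mark.parametrize("baseline,value,expected", [
        (100, 80, Direction.DECREASE),  # boundary inclusive
        (100, 81, Direction.NO_CHANGE),
        (10, 12, Direction.INCREASE),
        (100, 100, Direction.NO_CHANGE),
    ])
    def test_directions(self, baseline, value, expected):
        assert classify_size_change(baseline, value).direction is expected

    def test_custom_threshold(self):
        assert (
            classify_size_change(100, 91, threshold_pct=10).direction
            is Direction.NO_CHANGE
        )
        assert (
            classify_size_change(100, 90, threshold_pct=10).direction
            is Direction.DECREASE
        )


_ORDER = {Category.PR: 0, Category.SD: 1, Category.PD: 2}


class TestConsistencyProperties:
    @given(
        st.floats(min_value=10.0, max_value=200.0),
        st.floats(min_value=0.2, max_value=2.5),
    )
    def test_sphere_equals_recist_under_cube_law(self, d0, factor):
        """Isotropic change: volume moves as the cube of the diameter.

        Histories landing exactly on a cut-off boundary are excluded: there
        float rounding can legitimately put the 1D and 3D changes on
        opposite sides of their (equivalent) thresholds.
        """
        assume(abs(factor - 0.7) > 1e-9 and abs(factor - 1.2) > 1e-9)
        s0 = summary(diameter=d0, volume=d0**3 / 1000.0)
        s3 = summary(tp=3, diameter=d0 * factor, volume=(d0 * factor) ** 3 / 1000.0)
        assert (
            classify_recist(s3, s0).category
            is classify_volume(s3, s0, SPHERE_CUTOFFS).category
        )

    @given(
        st.floats(min_value=5.0, max_value=60.0),
        st.floats(min_value=0.2, max_value=1.0),
        st.floats(min_value=0.2, max_value=2.5),
    )
    def test_ellipsoid_equals_recist_under_single_axis_change(
        self, r3, aspect, factor
    ):
        """Prolate spheroid, only r3 changes, measured diameter = 2 r3."""
        assume(abs(factor - 0.7) > 1e-9 and abs(factor - 1.2) > 1e-9)
        r1 = aspect * r3
        v0 = ellipsoid_volume(r1, r1, r3) / 1000.0
        v1 = ellipsoid_volume(r1, r1, r3 * factor) / 1000.0
        s0 = summary(diameter=2 * r3, volume=v0)
        s3 = summary(tp=3, diameter=2 * r3 * factor, volume=v1)
        assert (
            classify_recist(s3, s0).category
            is classify_volume(s3, s0, ELLIPSOID_CUTOFFS).category
        )

    @given(st.lists(st.floats(min_value=1.0, max_value=300.0), min_size=2,
                    max_size=20, unique=True))
    def test_monotone_in_size_change(self, diameters):
        """PR -> SD -> PD order as the size change increases."""
        s0 = summary()
        cats = [
            _ORDER[classify_recist(summary(tp=3, diameter=d), s0).category]
            for d in sorted(diameters)
        ]
        assert cats == sorted(cats)
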