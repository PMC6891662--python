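"""Bead grading arithmetic and image-measurement recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoquant import beads, synthetic as syn
from immunoquant.errors import DomainError, NoBeadError


class TestGradeScheme:
    @pytest.mark.parametrize(
        "value,part,grade",
        [
            (0.0, "area", 0),
            (0.1, "area", 1),
            (0.25, "area", 1),  # upper-inclusive
            (0.3333, "area", 2),
            (1.0, "area", 4),
            (0.0, "thickness", 0),
            (0.2, "thickness", 1),
            (0.5, "thickness", 3),
            (1.0, "thickness", 5),
            (2.0, "thickness", 6),
            (3.5, "thickness", 6),  # clamps beyond last bin
        ],
    )
    def test_grade_assignment(self, value, part, grade):
        assert beads.assign_grade(value, part) == grade

    def test_area_fraction_above_one_rejected(self):
        with pytest.raises(DomainError):
            beads.assign_grade(1.2, "area")

    def test_negative_value_rejected(self):
        with pytest.raises(DomainError):
            beads.assign_grade(-0.1, "thickness")


class TestScalarFormulas:
    @pytest.mark.parametrize("deg,a", [(0, 0.0), (360, 1.0), (120, 1 / 3)])
    def test_area_fraction(self, deg, a):
        assert beads.area_fraction(deg) == pytest.approx(a)

    def test_area_fraction_domain(self):
        with pytest.raises(DomainError):
            beads.area_fraction(361)

    @pytest.mark.parametrize(
        "area_mult,t", [(1.0, 0.0), (4.0, 1.0), (2.25, 0.5)]
    )
    def test_thickness_ratio(self, area_mult, t):
        r = 37.0
        assert beads.thickness_ratio(area_mult * math.pi * r**2, r) == pytest.approx(t)

    def test_thickness_ratio_floors_at_zero(self):
        assert beads.thickness_ratio(0.5 * math.pi * 100, 10.0) == 0.0

    def test_thickness_ratio_needs_positive_radius(self):
        with pytest.raises(DomainError):
            beads.thickness_ratio(100.0, 0.0)


class TestEncapsulationIndex:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["area_grade", "thickness_grade"])

    def test_all_zero_grades(self):
        s = beads.encapsulation_index(self._table([(0, 0)] * 10))
        assert s.encapsulation_index == 0.0
        assert s.encapsulation_rate == 0.0

    def test_maximum_grades(self):
        s = beads.encapsulation_index(self._table([(4, 6)] * 10))
        assert s.encapsulation_index == 10.0
        assert s.encapsulation_rate == 1.0

    def test_mixed_cohort_weighted_sum(self):
        # half at (4,6) contributing 10, half at (2,2) contributing 4
        s = beads.encapsulation_index(self._table([(4, 6)] * 5 + [(2, 2)] * 5))
        assert s.encapsulation_index == pytest.approx(7.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(DomainError):
            beads.encapsulation_index(self._table([]))

    def test_p_vectors_sum_to_one(self, rng):
        ag = rng.integers(0, 5, 37)
        tg = rng.integers(0, 7, 37)
        s = beads.encapsulation_index(
            pd.DataFrame({"area_grade": ag, "thickness_grade": tg})
        )
        assert s.p_area.sum() == pytest.approx(1.0, abs=1e-9)
        assert s.p_thickness.sum() == pytest.approx(1.0, abs=1e-9)

    @given(
        grades=st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 6)), min_size=1, max_size=60
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_index_equals_mean_grade_sum_and_stays_bounded(self, grades):
        df = pd.DataFrame(grades, columns=["area_grade", "thickness_grade"])
        s = beads.encapsulation_index(df)
        expected = (df["area_grade"] + df["thickness_grade"]).mean()
        assert s.encapsulation_index == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= s.encapsulation_index <= 10.0

    @given(
        grades=st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 6)), min_size=1, max_size=30
        ),
        data=st.data(),
    )
    @settings(deadline=None, derandomize=True)
    def test_single_bead_grade_increase_never_decreases_index(self, grades, data):
        df = pd.DataFrame(grades, columns=["area_grade", "thickness_grade"])
        base = beads.encapsulation_index(df).encapsulation_index
        i = data.draw(st.integers(0, len(df) - 1))
        col = data.draw(st.sampled_from(["area_grade", "thickness_grade"]))
        top = 4 if col == "area_grade" else 6
        bumped = df.copy()
        bumped.loc[i, col] = min(top, bumped.loc[i, col] + 1)
        assert beads.encapsulation_index(bumped).encapsulation_index >= base


class TestSegmentation:
    def test_bare_bead_radius_recovered(self):
        img, _ = syn.generate_bead_image(syn.BeadTruth(bead_radius=40))
        seg = beads.segment_bead(img)
        assert seg.radius_px == pytest.approx(40.0, rel=0.03)
        assert seg.center[0] == pytest.approx((img.shape[0] - 1) / 2, abs=2)

    def test_blank_image_raises(self):
        with pytest.raises(NoBeadError):
            beads.segment_bead(np.full((128, 128), 10.0))

    def test_full_capsule_radius_from_inner_band(self):
        # the bead circle must come from the bright inner band, not the annulus
        img, _ = syn.generate_bead_image(
            syn.BeadTruth(bead_radius=40, coverage_deg=360, thickness_ratio=1.0)
        )
        seg = beads.segment_bead(img)
        assert seg.radius_px == pytest.approx(40.0, rel=0.03)
        assert seg.capsule_mask.sum() > 0


class TestCoverageAndArea:
    def test_no_capsule_gives_zero_coverage(self):
        img, _ = syn.generate_bead_image(syn.BeadTruth(bead_radius=40))
        m = beads.measure_bead(img)
        assert m.coverage_deg == 0.0

    def test_half_arc_measured_within_two_degrees(self):
        img, _ = syn.generate_bead_image(
            syn.BeadTruth(bead_radius=40, coverage_deg=180, thickness_ratio=0.5)
        )
        m = beads.measure_bead(img)
        assert m.coverage_deg == pytest.approx(180.0, abs=2.0)

    def test_full_annulus_saturates_at_360(self):
        img, _ = syn.generate_bead_image(
            syn.BeadTruth(bead_radius=40, coverage_deg=360, thickness_ratio=0.6)
        )
        assert beads.measure_bead(img).coverage_deg == 360.0

    def test_bead_only_footprint_area(self):
        img, _ = syn.generate_bead_image(syn.BeadTruth(bead_radius=40))
        seg = beads.segment_bead(img)
        area = beads.measure_total_area(seg, pixel_size=1.0)
        assert area == pytest.approx(math.pi * 40**2, rel=0.02)

    def test_full_annulus_footprint_area(self):
        img, _ = syn.generate_bead_image(
            syn.BeadTruth(bead_radius=40, coverage_deg=360, thickness_ratio=1.0)
        )
        seg = beads.segment_bead(img)
        area = beads.measure_total_area(seg, pixel_size=1.0)
        assert area == pytest.approx(4 * math.pi * 40**2, rel=0.02)

    def test_quarter_arc_footprint_area(self):
        img, _ = syn.generate_bead_image(
            syn.BeadTruth(bead_radius=40, coverage_deg=90, thickness_ratio=1.0)
        )
        seg = beads.segment_bead(img)
        area = beads.measure_total_area(seg, pixel_size=1.0)
        expected = math.pi * 40**2 + 0.25 * 3 * math.pi * 40**2
        assert area == pytest.approx(expected, rel=0.02)

    def test_pixel_size_must_be_positive(self):
        img, _ = syn.generate_bead_image(syn.BeadTruth(bead_radius=40))
        seg = beads.segment_bead(img)
        with pytest.raises(DomainError):
            beads.measure_total_area(seg, pixel_size=0.0)


class TestCohortPipeline:
    def test_noiseless_cohort_recovers_truth_grades_exactly(self):
        cohort = syn.generate_bead_cohort(10, seed=31, noise_sd=0.0)
        truth_df = pd.DataFrame(
            [dict(zip(("area_grade", "thickness_grade"), t.grades()))
             for _, t in cohort]
        )
        per_bead, summary = beads.analyze_bead_cohort([img for img, _ in cohort])
        gt = beads.encapsulation_index(truth_df)
        assert summary.encapsulation_index == pytest.approx(
            gt.encapsulation_index, abs=1e-12
        )

    def test_unreadable_image_becomes_flagged_row(self):
        cohort = syn.generate_bead_cohort(9, seed=4, noise_sd=0.0)
        images = [img for img, _ in cohort] + [np.full((128, 128), 10.0)]
        per_bead, summary = beads.analyze_bead_cohort(images)
        assert len(per_bead) == 10
        assert per_bead["ok"].sum() == 9
        assert summary.n_beads == 9

    def test_dominating_cohort_scores_at_least_as_high(self):
        # cohort A dominates B bead-for-bead in both coverage and thickness
        a = syn.generate_bead_cohort(8, ("degenerate", 300.0), ("degenerate", 0.9),
                                     seed=1)
        b = syn.generate_bead_cohort(8, ("degenerate", 120.0), ("degenerate", 0.3),
                                     seed=1)
        _, sa = beads.analyze_bead_cohort([img for img, _ in a])
        _, sb = beads.analyze_bead_cohort([img for img, _ in b])
        assert sa.encapsulation_index >= sb.encapsulation_index
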