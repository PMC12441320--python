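"""Landmark measurement, derived metrics, siding and record validation."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trackmorph.geometry import (
    DegenerateLandmarkError,
    IncompleteLandmarkError,
    apply_relief_siding,
    derive_metrics,
    measure_track,
    validate_record,
)
from trackmorph.synthetic import construct_landmarks, sample_metrics
from trackmorph.types import (
    DerivedMetrics,
    LandmarkSet,
    Relief,
    Side,
    TrackMetrics,
    TrackRecord,
    length_category,
    LengthCategory,
)


def _simple_set(**overrides):
    pts = {
        "tip_II": (-4.0, 10.0),
        "tip_III": (0.0, 15.0),
        "tip_IV": (4.0, 10.0),
        "hypex_II_III": (-1.5, 8.0),
        "hypex_III_IV": (1.5, 8.0),
        "heel": (0.0, 0.0),
    }
    pts.update(overrides)
    return LandmarkSet("t1", Side.LEFT, Relief.NEGATIVE, pts)


class TestMeasureTrack:
    def test_axis_aligned_anterior_triangle(self):
        # tips at (-4,0), (0,5), (4,0): the triangle height is the y-offset
        lm = _simple_set(
            tip_II=(-4.0, 0.0), tip_III=(0.0, 5.0), tip_IV=(4.0, 0.0),
            heel=(0.0, -3.0), hypex_II_III=(-1.0, -1.0), hypex_III_IV=(1.0, -1.0),
        )
        m = measure_track(lm)
        assert m.te == pytest.approx(5.0)
        assert m.W == pytest.approx(8.0)

    def test_mirror_symmetric_set_has_equal_angles_and_lateral_lengths(self):
        m = measure_track(_simple_set())
        assert m.alpha == pytest.approx(m.beta)
        assert m.L_II == pytest.approx(m.L_IV)

    def test_missing_label_raises_with_labels(self):
        pts = {k: v for k, v in _simple_set().points.items() if k != "heel"}
        with pytest.raises(IncompleteLandmarkError) as err:
            measure_track(LandmarkSet("t", Side.LEFT, Relief.NEGATIVE, pts))
        assert err.value.missing == ["heel"]

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateLandmarkError):
            measure_track(_simple_set(tip_II=(0.0, 15.0)))

    def test_collinear_tips_give_zero_te_with_warning(self):
        lm = _simple_set(tip_II=(-4.0, 15.0), tip_IV=(4.0, 15.0))
        with pytest.warns(UserWarning, match="collinear"):
            m = measure_track(lm)
        assert m.te == 0.0

    def test_hallux_points_do_not_affect_lengths(self):
        base = measure_track(_simple_set())
        with_hallux = measure_track(_simple_set(hallux_tip=(2.0, -2.0)))
        assert base == with_hallux

    @settings(max_examples=60, deadline=None)
    @given(
        sub=st.sampled_from(["HBR_B1.1", "HBR_B2.1", "HBR_B2.2", "HBR_B3.1", "HBR_B3.2", "HBR_B4"]),
        seed=st.integers(0, 10_000),
    )
    def test_inverse_construction_identity(self, sub, seed):
        """measure_track(construct_landmarks(m)) == m to 1e-6."""
        m = sample_metrics(sub, seed=seed)
        got = measure_track(construct_landmarks(m, seed=seed))
        for f in ("L", "W", "L_II", "L_III", "L_IV", "te", "alpha", "beta"):
            assert abs(getattr(m, f) - getattr(got, f)) < 1e-6

    def test_explicit_inverse_example(self):
        m = TrackMetrics(L=10, W=8, te=4, alpha=25, beta=25,
                         L_II=5.0, L_III=7.0, L_IV=5.5)
        got = measure_track(construct_landmarks(m))
        assert got.L == pytest.approx(10, abs=1e-6)
        assert got.W == pytest.approx(8, abs=1e-6)
        assert got.te == pytest.approx(4, abs=1e-6)
        assert got.alpha == pytest.approx(25, abs=1e-6)
        assert got.beta == pytest.approx(25, abs=1e-6)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), theta=st.floats(0, 2 * math.pi),
           dx=st.floats(-50, 50), dy=st.floats(-50, 50))
    def test_metrics_invariant_under_rigid_motion_and_mirroring(self, seed, theta, dx, dy):
        m = sample_metrics("HBR_B2.1", seed=seed)
        lm = construct_landmarks(m)
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        moved = LandmarkSet(
            lm.track_id, lm.side_observed, lm.relief,
            {k: tuple(R @ np.array(v) + [dx, dy]) for k, v in lm.points.items()},
        )
        mirrored = LandmarkSet(
            lm.track_id, Side.RIGHT, lm.relief,
            {k: (-v[0], v[1]) for k, v in lm.points.items()},
        )
        for other in (moved, mirrored):
            got = measure_track(other)
            for f in ("L", "W", "te", "alpha", "beta", "L_II", "L_III", "L_IV"):
                assert abs(getattr(got, f) - getattr(m, f)) < 1e-6


class TestDeriveMetrics:
    @pytest.mark.parametrize(
        "metrics, field, expected",
        [
            (TrackMetrics(L=43.88, W=33.37, te=13.81, L_III=27.56), "lw_ratio", 1.31),
            (TrackMetrics(L=43.88, W=33.37, te=13.81, L_III=27.56), "mesaxony", 0.41),
            (TrackMetrics(L=43.88, W=33.37, te=13.81, L_III=27.56), "iii_over_L", 62.81),
            (TrackMetrics(L=21.00, L_III=14.15), "iii_over_L", 67.38),
            (TrackMetrics(L=12.0, W=12.0), "lw_ratio", 1.00),
        ],
    )
    def test_printed_table_values(self, metrics, field, expected):
        assert getattr(derive_metrics(metrics), field) == pytest.approx(expected, abs=0.005)

    def test_missing_and_zero_denominators_propagate_none(self):
        d = derive_metrics(TrackMetrics(L=10.0, W=0.0))
        assert d.lw_ratio is None and d.mesaxony is None
        d2 = derive_metrics(TrackMetrics())
        assert all(
            getattr(d2, f) is None
            for f in ("lw_ratio", "r_iii_ii", "r_iii_iv", "iii_over_L", "mesaxony")
        )

    def test_total_div_is_alpha_plus_beta_exactly(self):
        m = TrackMetrics(alpha=29.03, beta=23.46)
        assert m.total_div == pytest.approx(52.49)


class TestReliefSiding:
    def _rec(self, side, relief):
        return TrackRecord(specimen_id="s", side_observed=side, relief=relief)

    def test_positive_relief_reverses_siding(self):
        out = apply_relief_siding(self._rec(Side.RIGHT, Relief.POSITIVE))
        assert out.side_catalogued is Side.LEFT
        assert out.mirrored_for_relief

    def test_negative_relief_passes_through(self):
        out = apply_relief_siding(self._rec(Side.LEFT, Relief.NEGATIVE))
        assert out.side_catalogued is Side.LEFT
        assert not out.mirrored_for_relief

    def test_indeterminate_side_warns(self):
        with pytest.warns(UserWarning, match="indeterminate"):
            out = apply_relief_siding(self._rec(Side.INDETERMINATE, Relief.POSITIVE))
        assert out.side_catalogued is Side.INDETERMINATE


class TestValidateRecord:
    def test_consistent_printed_row_has_no_findings(self):
        rec = TrackRecord(
            specimen_id="2002.004",
            metrics=TrackMetrics(L=43.88, W=33.37, te=13.81, L_III=27.56,
                                 alpha=29.03, beta=23.46),
            derived=DerivedMetrics(lw_ratio=1.31, mesaxony=0.41, iii_over_L=62.81,
                                   total_div=52.49),
        )
        assert validate_record(rec) == []

    def test_divarication_mismatch_flagged(self):
        rec = TrackRecord(
            specimen_id="bad",
            metrics=TrackMetrics(alpha=30.0, beta=30.0),
            derived=DerivedMetrics(total_div=70.0),
        )
        findings = validate_record(rec)
        assert any("divarication mismatch" in f for f in findings)

    def test_length_category_mismatch_flagged(self):
        rec = TrackRecord(
            specimen_id="cat",
            metrics=TrackMetrics(L=9.9),
            length_category_label="small",
        )
        findings = validate_record(rec)
        assert any("expected tiny" in f for f in findings)

    def test_length_bins(self):
        assert length_category(9.99) is LengthCategory.TINY
        assert length_category(10.0) is LengthCategory.SMALL
        assert length_category(29.99) is LengthCategory.MEDIUM
        assert length_category(30.0) is LengthCategory.LARGE
        assert length_category(50.0) is LengthCategory.GIANT
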