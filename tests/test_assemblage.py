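"""Assemblage aggregation: summary means, correlations, windroses, counts."""

import numpy as np
import pytest

from trackmorph.assemblage import (
    allometry_panel,
    bearing_rose,
    count_report,
    metric_correlation,
    summarize,
    _stored_values,
)
from trackmorph.geometry import derive_metrics
from trackmorph.io import fixture_path, read_measurement_table
from trackmorph.types import BearingSet, TrackMetrics, TrackRecord


def _rec(x_vals, specimen="s", subgroup="HBR_B2.1", status="characterized", **metrics):
    m = TrackMetrics(**metrics)
    return TrackRecord(
        specimen_id=specimen, metrics=m, derived=derive_metrics(m),
        published_subgroup=subgroup, published_status=status,
    )


class TestSummarize:
    def test_single_row_subgroup_mean_equals_row(self, fixture_records):
        summary = summarize(fixture_records)
        b11 = summary.per_subgroup_means["HBR_B1.1"]
        assert b11["L"] == pytest.approx(43.88)
        assert b11["mesaxony"] == pytest.approx(0.41)

    def test_printed_average_rows_reproduced(self, fixture_records):
        """Means over characterized rows match every printed average entry."""
        summary = summarize(fixture_records)
        avg_rows = [
            r for r in read_measurement_table(fixture_path(), include_averages=True)
            if r.is_summary_row
        ]
        assert len(avg_rows) == 7
        for ar in avg_rows:
            means = summary.per_subgroup_means[ar.published_subgroup]
            for col, printed in _stored_values(ar).items():
                if printed is None or col not in means:
                    continue
                # III/L is a percentage (0.05); grade averages are printed at
                # coarser precision than the metric columns (1 d.p. in places)
                tol = 0.055 if col in ("iii_over_L", "PG") else 0.0151
                assert means[col] == pytest.approx(printed, abs=tol), (
                    ar.published_subgroup, col)

    def test_eubrontes_like_subgroup_anchors(self, fixture_records):
        means = summarize(fixture_records).per_subgroup_means
        assert means["HBR_B2.1"]["lw_ratio"] == pytest.approx(1.58, abs=0.01)
        assert means["HBR_B2.1"]["total_div"] == pytest.approx(47.38, abs=0.01)
        assert means["HBR_B3.1"]["mesaxony"] == pytest.approx(0.77, abs=0.01)

    def test_counts_sum_to_total(self, fixture_records):
        summary = summarize(fixture_records)
        assert sum(summary.counts.values()) == len(fixture_records)
        assert summary.n_characterized == 85


class TestMetricCorrelation:
    def test_perfect_linearity(self):
        recs = [_rec(None, specimen=str(i), L=float(x), te=float(2 * x + 1))
                for i, x in enumerate([1, 2, 3, 4])]
        rel = metric_correlation(recs, "L", "te")
        assert rel.pearson_r == pytest.approx(1.0)

    def test_hand_computed_sigma_formula(self):
        # points (0,0),(1,2),(2,1),(3,3): Sigma (x-xbar)(y-ybar) = 4,
        # Sigma (x-xbar)^2 = Sigma (y-ybar)^2 = 5  ->  r = 4/5 = 0.8
        xs = [0.0, 1.0, 2.0, 3.0]
        ys = [0.0, 2.0, 1.0, 3.0]
        recs = [
            TrackRecord(specimen_id=str(i), metrics=TrackMetrics(alpha=x, beta=y))
            for i, (x, y) in enumerate(zip(xs, ys))
        ]
        rel = metric_correlation(recs, "alpha", "beta")
        assert rel.n == 4
        assert rel.pearson_r == pytest.approx(0.8)

    def test_small_n_and_zero_variance_undefined(self):
        recs = [_rec(None, specimen=str(i), L=1.0, te=float(i)) for i in range(3)]
        assert metric_correlation(recs[:2], "L", "te").pearson_r is None
        assert metric_correlation(recs, "L", "te").pearson_r is None  # L constant

    def test_affine_invariance_and_sign_flip(self, fixture_records):
        base = metric_correlation(fixture_records, "mesaxony", "total_div")
        pairs = [
            (r.derived.mesaxony, r.derived.total_div)
            for r in fixture_records
            if r.derived.mesaxony is not None and r.derived.total_div is not None
        ]
        x, y = map(np.array, zip(*pairs))
        r0 = float(np.corrcoef(x, y)[0, 1])
        assert float(np.corrcoef(2.5 * x + 1, y)[0, 1]) == pytest.approx(r0)
        assert float(np.corrcoef(-x, y)[0, 1]) == pytest.approx(-r0)
        assert np.sign(base.pearson_r) == np.sign(r0)

    def test_fixture_signs_match_reported_directions(self, fixture_records):
        neg = metric_correlation(fixture_records, "mesaxony", "total_div")
        pos = metric_correlation(fixture_records, "r_iii_ii", "r_iii_iv")
        assert neg.pearson_r < 0
        assert pos.pearson_r > 0
        assert neg.n >= 3 and pos.n >= 3


class TestAllometryPanel:
    def test_track_with_te_half_L_lies_on_diagonal(self):
        rec = _rec(None, L=10.0, te=5.0)
        panel = allometry_panel([rec])
        assert panel.points == ((5.0, 5.0),)
        assert panel.slope is None  # single point: no fit

    def test_printed_row_coordinates(self):
        rec = _rec(None, L=43.88, te=13.81)
        panel = allometry_panel([rec])
        assert panel.points[0] == (pytest.approx(30.07), pytest.approx(13.81))

    def test_slope_fit(self):
        recs = [_rec(None, specimen=str(x), L=float(2 * x), te=float(x)) for x in (2, 4, 6)]
        panel = allometry_panel(recs)
        assert panel.slope == pytest.approx(1.0)  # te == L - te on these


class TestBearingRose:
    def test_single_direction(self):
        res = bearing_rose(BearingSet.wrapped("s", [90.0] * 5))
        assert sum(c > 0 for c in res.counts) == 1
        assert res.rbar == pytest.approx(1.0)
        assert res.mean_direction == pytest.approx(90.0)

    @pytest.mark.parametrize("bearings", [[0.0, 180.0], [0.0, 90.0, 180.0, 270.0]])
    def test_antipodal_and_symmetric_cancellation(self, bearings):
        res = bearing_rose(BearingSet.wrapped("s", bearings))
        assert res.rbar == pytest.approx(0.0, abs=1e-12)
        assert res.mean_direction is None

    def test_counts_sum_and_bad_bin_width(self):
        rng = np.random.default_rng(1)
        bs = BearingSet.wrapped("s", rng.uniform(0, 360, 57))
        res = bearing_rose(bs, bin_width=15.0)
        assert sum(res.counts) == 57
        with pytest.raises(ValueError, match="divide"):
            bearing_rose(bs, bin_width=17.0)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(2)
        b = rng.vonmises(0.8, 4.0, 40)
        base = bearing_rose(BearingSet.wrapped("s", np.degrees(b)))
        rot = bearing_rose(BearingSet.wrapped("s", np.degrees(b) + 77.0))
        assert rot.rbar == pytest.approx(base.rbar)
        assert (rot.mean_direction - base.mean_direction) % 360 == pytest.approx(77.0, abs=1e-6)


class TestCountReport:
    def test_fixture_counts(self, fixture_records):
        rep = count_report(fixture_records)
        assert rep.n_characterized == 85
        assert rep.by_subgroup["HBR_B3.2"] == 18
        assert rep.max_divarication == pytest.approx(107.79)
        assert "2006.006-2" in rep.max_divarication_specimen

    def test_empty_input_all_zero(self):
        rep = count_report([])
        assert rep.n_characterized == 0 and rep.n_referred == 0
        assert rep.max_divarication is None
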