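"""Synthetic generator: determinism, range containment, wear, trackways."""

import numpy as np
import pytest

from trackmorph.classify import classify
from trackmorph.geometry import derive_metrics, measure_track, validate_record
from trackmorph.kinematics import estimate_trackway, trackway_geometry
from trackmorph.synthetic import (
    SUBGROUP_GENERATORS,
    AssemblageConfig,
    InfeasibleMetricsError,
    WearModel,
    apply_wear,
    construct_landmarks,
    generate_assemblage,
    generate_trackway,
    sample_metrics,
)
from trackmorph.types import TrackMetrics, TrackRecord


class TestSampleMetrics:
    def test_same_seed_identical_draws(self):
        assert sample_metrics("HBR_B2.1", seed=11) == sample_metrics("HBR_B2.1", seed=11)
        assert sample_metrics("HBR_B2.1", seed=11) != sample_metrics("HBR_B2.1", seed=12)

    def test_strict_narrow_form_draw_satisfies_its_criteria(self):
        for seed in range(10):
            m = sample_metrics("HBR_B3.1", strict=True, seed=seed)
            d = derive_metrics(m)
            assert d.lw_ratio > 1.50
            assert d.mesaxony > 0.7
            assert d.total_div < 50.0

    def test_tiniest_morphotype_draws_are_tiny(self):
        for seed in range(10):
            assert sample_metrics("HBR_B4", seed=seed).L < 10.0

    def test_unknown_subgroup(self):
        with pytest.raises(KeyError):
            sample_metrics("HBR_B9")


class TestConstructLandmarks:
    def test_symmetric_request_gives_mirror_symmetric_tips(self):
        m = TrackMetrics(L=10, W=8, te=4, alpha=25, beta=25, L_II=5, L_III=7, L_IV=5)
        lm = construct_landmarks(m)
        t2 = lm.points["tip_II"]
        t4 = lm.points["tip_IV"]
        assert t2[0] == pytest.approx(-t4[0])
        assert t2[1] == pytest.approx(t4[1])

    def test_zero_te_request_gives_collinear_tips(self):
        m = TrackMetrics(L=10, W=8, te=0.0, alpha=22, beta=22, L_II=7, L_III=6.5, L_IV=7)
        lm = construct_landmarks(m)
        t2, t3, t4 = (np.array(lm.points[k]) for k in ("tip_II", "tip_III", "tip_IV"))
        u, v = t3 - t2, t4 - t2
        cross_z = u[0] * v[1] - u[1] * v[0]
        assert abs(cross_z) < 1e-9

    def test_infeasible_te_names_constraint(self):
        m = TrackMetrics(L=10, W=8, te=12.0, alpha=25, beta=25, L_II=5, L_III=7, L_IV=5)
        with pytest.raises(InfeasibleMetricsError, match="te"):
            construct_landmarks(m)

    def test_incomplete_metrics_rejected(self):
        with pytest.raises(InfeasibleMetricsError, match="missing"):
            construct_landmarks(TrackMetrics(L=10, W=8))

    def test_bulk_round_trip_precision(self):
        """The module's central contract at scale: 1000 mixed draws at 1e-6."""
        rng = np.random.default_rng(2024)
        subs = list(SUBGROUP_GENERATORS)
        worst = 0.0
        for i in range(1000):
            sub = subs[i % len(subs)]
            m = sample_metrics(sub, seed=rng)
            got = measure_track(construct_landmarks(m, seed=rng))
            for f in ("L", "W", "L_II", "L_III", "L_IV", "te", "alpha", "beta"):
                worst = max(worst, abs(getattr(m, f) - getattr(got, f)))
        assert worst < 1e-6


class TestApplyWear:
    def _landmarks(self, seed=0):
        return construct_landmarks(sample_metrics("HBR_B3.1", strict=True, seed=seed))

    def test_severity_zero_is_identity_grade_three(self):
        lm = self._landmarks()
        worn, grade = apply_wear(lm, WearModel(0.0), seed=1)
        assert worn is lm
        assert grade == 3.0

    def test_severity_one_grade_at_most_half(self):
        _, grade = apply_wear(self._landmarks(), WearModel(1.0), seed=1)
        assert grade <= 0.5

    def test_grade_map_monotone_non_increasing(self):
        grades = [WearModel(s).grade() for s in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(grades, grades[1:]))

    def test_classification_accuracy_degrades_monotonically(self):
        """Monte-Carlo: strict narrow-form draws, increasing wear severity."""
        gen = SUBGROUP_GENERATORS["HBR_B3.1"]
        accuracies = []
        for severity in (0.0, 0.25, 0.5, 0.75):
            rng = np.random.default_rng(7)
            n_ok, n = 0, 500
            for i in range(n):
                m = sample_metrics("HBR_B3.1", strict=True, seed=rng)
                worn, grade = apply_wear(construct_landmarks(m), WearModel(severity), seed=rng)
                mm = measure_track(worn)
                rec = TrackRecord(
                    specimen_id=f"w{i}", preservation_grade=grade, flags=gen.flags,
                    metrics=mm, derived=derive_metrics(mm),
                )
                n_ok += classify(rec).subgroup == "HBR_B3.1"
            accuracies.append(n_ok / n)
        assert accuracies[0] == 1.0
        assert all(a >= b for a, b in zip(accuracies, accuracies[1:]))


class TestGenerateTrackway:
    def test_forced_length_reproduces_walking_stride(self):
        seq = generate_trackway("HBR_B1.4", 3, gait_ratio=1.54, forced_L=34.16, seed=1)
        g = trackway_geometry(seq)
        assert g.strides[0] == pytest.approx(1.54 * 4 * 0.3416, abs=1e-9)  # 2.10 m

    def test_zero_step_width_gives_straight_limit(self):
        seq = generate_trackway("HBR_B2.1", 4, gait_ratio=1.2, step_width=0.0, seed=2)
        g = trackway_geometry(seq)
        assert all(a == pytest.approx(180.0) for a in g.pace_angulations)
        assert all(w == pytest.approx(0.0) for w in g.wap)
        for i, s in enumerate(g.strides):
            assert s == pytest.approx(g.paces[i] + g.paces[i + 1])

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_gait_recovery_within_one_percent(self, seed):
        seq = generate_trackway("HBR_B3.2", 5, gait_ratio=1.7, step_width=5.0, seed=seed)
        e = estimate_trackway(seq)
        assert abs(e.gait_ratio - 1.7) / 1.7 < 0.01


class TestGenerateAssemblage:
    def test_empty_config_valid(self):
        asm = generate_assemblage(
            AssemblageConfig(mixture={"HBR_B3.1": 1.0}, n_tracks=0), seed=1
        )
        assert asm.tracks == ()

    def test_determinism_and_seed_sensitivity(self):
        cfg = AssemblageConfig(mixture={"HBR_B2.1": 0.5, "HBR_B3.2": 0.5}, n_tracks=10)
        a = generate_assemblage(cfg, seed=5)
        b = generate_assemblage(cfg, seed=5)
        c = generate_assemblage(cfg, seed=6)
        assert [t.record.metrics for t in a.tracks] == [t.record.metrics for t in b.tracks]
        assert [t.record.metrics for t in a.tracks] != [t.record.metrics for t in c.tracks]

    def test_zero_wear_records_pass_validation(self):
        asm = generate_assemblage(
            AssemblageConfig(mixture={"HBR_B2.2": 1.0}, n_tracks=12), seed=9
        )
        for rec in asm.records:
            assert validate_record(rec) == []

    def test_bearing_models_discriminate(self):
        """Directed (von Mises) vs undirected (uniform) surfaces separate on R-bar."""
        from trackmorph.assemblage import bearing_rose
        from trackmorph.types import BearingSet

        mix = {"HBR_B3.1": 1.0}
        uni = generate_assemblage(
            AssemblageConfig(mixture=mix, n_tracks=36, bearing_model="uniform"), seed=3
        )
        vm = generate_assemblage(
            AssemblageConfig(mixture=mix, n_tracks=36, bearing_model="vonmises",
                             bearing_kappa=8.0), seed=3
        )
        r_uni = bearing_rose(BearingSet.wrapped("u", uni.bearings)).rbar
        r_vm = bearing_rose(BearingSet.wrapped("v", vm.bearings)).rbar
        # null 95th percentile of R-bar for n = 36 uniform bearings
        rng = np.random.default_rng(0)
        null = sorted(
            bearing_rose(BearingSet.wrapped("n", rng.uniform(0, 360, 36))).rbar
            for _ in range(2000)
        )
        p95 = null[int(0.95 * len(null))]
        assert r_uni < p95
        assert r_vm > 0.8

    def test_bad_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AssemblageConfig(mixture={"HBR_B2.1": 0.5}, n_tracks=1)
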