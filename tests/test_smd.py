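"""Steering machinery: schedules, bias forces, classification, composites."""

import math

import numpy as np
import pytest

from cvsteer import dynamics, smd
from cvsteer.cv import wrap_angle_diff
from cvsteer.errors import ConfigurationError
from cvsteer.model import initial_condition
from cvsteer.references import CLOSED_STATE, OPEN_STATE

SCHED_I = smd.SCHEDULES["I"]
CHI_BIAS = smd.BiasTerm("chi1", 1000.0, 66.40, 176.10)
D6_BIAS = smd.BiasTerm("d6", 500.0, 0.41, 1.04)


class TestScheduleKappa:
    def test_starts_at_zero_and_free_is_zero(self):
        assert smd.schedule_kappa(SCHED_I, D6_BIAS, 0.0) == 0.0
        assert smd.schedule_kappa(SCHED_I, D6_BIAS, 80.0) == 0.0
        assert smd.schedule_kappa(SCHED_I, D6_BIAS, 100.0) == 0.0

    def test_continuous_at_stage_boundaries(self):
        for t in (25.0, 50.0, 75.0):
            lo = smd.schedule_kappa(SCHED_I, D6_BIAS, t - 1e-9)
            hi = smd.schedule_kappa(SCHED_I, D6_BIAS, t + 1e-9)
            assert lo == pytest.approx(hi, abs=1e-5)

    def test_plateau_at_kappa_max_during_steer(self):
        assert smd.schedule_kappa(SCHED_I, D6_BIAS, 37.0) == 500.0

    def test_outside_span_rejected(self):
        with pytest.raises(ValueError):
            smd.schedule_kappa(SCHED_I, D6_BIAS, -1.0)
        with pytest.raises(ValueError):
            smd.schedule_kappa(SCHED_I, D6_BIAS, 101.0)


class TestScheduleCenter:
    def test_ramp_up_holds_start_and_mid_steer_is_midpoint(self):
        assert smd.schedule_center(SCHED_I, D6_BIAS, 25.0) == 0.41
        mid = smd.schedule_center(SCHED_I, D6_BIAS, 37.5)
        assert mid == pytest.approx(0.5 * (0.41 + 1.04))

    def test_chi_steers_along_short_arc_without_crossing_180(self):
        """66.4 -> 176.1 takes the +110 deg arc; the oracle interpolates the
        wrapped difference directly."""
        arc = wrap_angle_diff(176.10, 66.40)
        assert arc == pytest.approx(109.7)
        for frac in np.linspace(0, 1, 21):
            t = 25.0 + 25.0 * frac
            got = smd.schedule_center(SCHED_I, CHI_BIAS, t)
            oracle = wrap_angle_diff(66.40 + frac * arc, 0.0)
            assert got == pytest.approx(oracle, abs=1e-9)
            assert -180 < got <= 180

    def test_ramp_down_and_free_hold_target(self):
        assert smd.schedule_center(SCHED_I, D6_BIAS, 60.0) == 1.04
        assert smd.schedule_center(SCHED_I, D6_BIAS, 90.0) == 1.04

    def test_restrain_only_center_never_moves(self):
        b = smd.BiasTerm("La3", 500.0, 2.05, 2.05, restrain_only=True)
        for t in (0.0, 30.0, 60.0, 99.0):
            assert smd.schedule_center(SCHED_I, b, t) == 2.05

    def test_restrain_only_requires_equal_endpoints(self):
        with pytest.raises(ConfigurationError):
            smd.BiasTerm("La3", 500.0, 2.0, 2.1, restrain_only=True)


class TestBiasEnergyForce:
    def test_at_center_zero(self):
        assert smd.bias_energy_force(500.0, 1.0, 1.0) == (0.0, 0.0)

    def test_distance_arithmetic(self):
        u, f = smd.bias_energy_force(500.0, 1.0, 1.1)
        assert u == pytest.approx(2.5)
        assert f == pytest.approx(500.0 * 0.1)

    def test_angle_wraps_through_180(self):
        u, _ = smd.bias_energy_force(1000.0, -179.0, 179.0, periodic=True)
        assert u == pytest.approx(0.5 * 1000.0 * math.radians(2.0) ** 2)


class TestClassifySuccess:
    def _traj(self, chi_free, d6_free=1.04, la3=2.05):
        n = 100
        times = np.arange(1, n + 1) * 0.1
        stages = ["steer"] * 40 + ["free"] * 60
        cvs = np.column_stack([
            np.full(n, 1.92), np.full(n, 1.46),
            np.concatenate([np.full(40, 1.04), np.full(60, d6_free)]),
            np.concatenate([np.full(40, 176.1), np.full(60, chi_free)]),
            np.full(n, la3)])
        return dynamics.Trajectory(times, ["d1", "d2", "d6", "chi1", "La3"],
                                   cvs, stages=stages)

    def test_pinned_at_open_means_succeeds(self):
        t = self._traj(chi_free=176.1)
        v = smd.classify_success(t, OPEN_STATE, ["d1", "d2", "d6", "chi1"])
        assert v["success"]

    def test_reverting_cv_fails(self):
        t = self._traj(chi_free=66.4)
        v = smd.classify_success(t, OPEN_STATE, ["d1", "d2", "d6", "chi1"])
        assert not v["success"]
        assert abs(v["deviations"]["chi1"]) > 2

    def test_two_sigma_boundary_is_inclusive(self):
        t = self._traj(chi_free=176.1, d6_free=1.04 + 2 * 0.18)
        v = smd.classify_success(t, OPEN_STATE, ["d6"])
        assert v["deviations"]["d6"] == pytest.approx(2.0)
        assert v["success"]

    def test_broken_helix_fails_regardless_of_cvs(self):
        t = self._traj(chi_free=176.1, la3=2.45)
        v = smd.classify_success(t, OPEN_STATE, ["d1", "d2", "d6", "chi1"])
        assert not v["success"]

    def test_no_free_stage_rejected(self):
        t = self._traj(176.1)
        t.stages = ["steer"] * len(t)
        with pytest.raises(ValueError):
            smd.classify_success(t, OPEN_STATE, ["d1"])


class TestCompositeSchedule:
    def test_quoted_desynchronized_protocol_compiles(self):
        comp = smd.desynchronized_6_12x((CLOSED_STATE, OPEN_STATE))
        assert comp.span == 100.0
        assert len(comp.segments["d6"]) == 4
        assert all(seg[1] - seg[0] == 25.0 for seg in comp.segments["d6"])
        # d6 is free after 75 units while d1/d2/chi1 are still steering
        assert comp.kappa("d6", 90.0) == 0.0
        assert comp.kappa("d1", 90.0) == 500.0

    def test_kappa_continuity_at_every_joint(self):
        comp = smd.desynchronized_6_12x((CLOSED_STATE, OPEN_STATE))
        for cvname, segs in comp.segments.items():
            for seg in segs[:-1]:
                t = seg[1]
                assert comp.kappa(cvname, t - 1e-9) == pytest.approx(
                    comp.kappa(cvname, t + 1e-9), abs=1e-4)

    def test_single_cv_composite_equals_plain_schedule(self):
        stages = [("ramp_up", 25.0, 500.0, 0.41, 0.41),
                  ("steer", 25.0, 500.0, 0.41, 1.04),
                  ("ramp_down", 25.0, 500.0, 1.04, 1.04),
                  ("free", 25.0, 0.0, 1.04, 1.04)]
        comp = smd.build_composite_schedule({"d6": stages})
        for t in np.linspace(0, 100, 41):
            assert comp.kappa("d6", t) == pytest.approx(
                smd.schedule_kappa(SCHED_I, D6_BIAS, t))
            assert comp.center("d6", t) == pytest.approx(
                smd.schedule_center(SCHED_I, D6_BIAS, t))

    def test_overlapping_stages_rejected(self):
        with pytest.raises(ConfigurationError):
            smd.build_composite_schedule({"d6": [
                ("ramp_up", 10.0, 500.0, 0.4, 0.4),
                ("steer", 10.0, 400.0, 0.4, 1.0)]})  # kappa jump 500 -> 400


class TestRunSmd:
    def test_zero_kappa_reduces_to_unbiased_run(self, model):
        spec = smd.SMDRunSpec(
            "custom0", [smd.BiasTerm("d1", 0.0, 0.93, 1.92)],
            smd.StageSchedule("short", (1, 1, 1, 1)), n_replicas=1, base_seed=3)
        trajs, report = smd.run_smd(model, spec, steps_per_unit=200)
        x0 = initial_condition(model, "closed", 3)
        ref = dynamics.run(model, x0, 800,
                           dynamics.LangevinParams(seed=3), record_stride=20)
        assert np.allclose(trajs[0].cvs, ref.cvs)
        assert report.n_success == 0  # unbiased run does not transition

    def test_bias_energy_bookkeeping_exact(self, model):
        """Recorded bias energy equals 0.5 Σ κ(t) Δ(t)² recomputed from the
        recorded CVs at every frame."""
        spec = smd.make_run_spec("126a3x-d", model.refs, n_replicas=1,
                                 base_seed=1)
        trajs, _ = smd.run_smd(model, spec, steps_per_unit=100)
        t = trajs[0]
        unit_time = 100 * dynamics.LangevinParams().dt
        for i in range(len(t)):
            tu = min(t.times[i] / unit_time, spec.schedule.total)
            expect = 0.0
            for b in spec.biases:
                kap = smd.schedule_kappa(spec.schedule, b, tu)
                cen = smd.schedule_center(spec.schedule, b, tu)
                theta = t.series(b.cv)[i]
                u, _ = smd.bias_energy_force(kap, cen, theta,
                                             periodic=b.cv == "chi1")
                expect += u
            assert t.bias_energy[i] == pytest.approx(expect, abs=1e-9)

    def test_schedule_reversal_mirrors_centers(self):
        fwd = smd.BiasTerm("d6", 500.0, 0.41, 1.04)
        rev = smd.BiasTerm("d6", 500.0, 1.04, 0.41)
        for t in np.linspace(0, 100, 51):
            c_f = smd.schedule_center(SCHED_I, fwd, t)
            c_r = smd.schedule_center(SCHED_I, rev, t)
            assert c_f + c_r == pytest.approx(0.41 + 1.04)

    def test_unknown_set_and_cv_mismatch_rejected(self, refs):
        with pytest.raises(ConfigurationError):
            smd.make_run_spec("nope", refs)
        with pytest.raises(ConfigurationError):
            smd.SMDRunSpec("126", [smd.BiasTerm("d1", 500.0, 0.93, 1.92)],
                           SCHED_I)

    def test_registry_covers_all_table_rows(self):
        assert len(smd.SMD_SETS) == 19
        assert smd.SMD_SETS["126a3x-d"]["restrain"] == {"La3": 500.0}
        assert smd.SMD_SETS["6-12x"]["schedule"] == "*"
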