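"""Stability+: velocity, centre of mass, classification, thermal latency,
tags, halo and pre-ablation indication."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cathstab import (
    MovementEvent,
    RespirationConfig,
    SessionConfig,
    StabilityPlusParams,
    analyze_session,
    apply_thermal_latency,
    classify_stability,
    instantaneous_velocity,
    running_center_of_mass,
    simulate_session,
    splus_tags,
)
from tests.conftest import stationary_config, synthetic_session

FS = 60.0


def _t(n):
    return np.arange(n) / FS


class TestVelocity:
    def test_constant_position_zero_speed(self):
        v = instantaneous_velocity(np.ones((100, 3)), FS)
        assert np.allclose(v, 0.0)

    def test_unit_conversion_at_30_mm_per_s(self):
        t = _t(300)
        pos = np.outer(t * 30.0, [1, 0, 0])        # 30 mm/s along x
        v = instantaneous_velocity(pos, FS)
        assert np.allclose(v[20:-20], 3.0, atol=1e-6)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            instantaneous_velocity(np.zeros((2, 3)), FS)

    def test_compensated_respiration_speed_stays_low(self):
        """Stationary catheter + respiration: after compensation, speed is
        below 0.5 cm/s for at least 95% of samples."""
        res = analyze_session(simulate_session(stationary_config(seed=1)))
        m = res.respiration.valid
        frac = np.mean(res.splus.speed_cm_s[m] < 0.5)
        assert frac >= 0.95


class TestRunningCenter:
    def test_constant_input_is_identity(self):
        p = np.tile([1.0, 2.0, 3.0], (50, 1))
        assert np.allclose(running_center_of_mass(p), p)

    def test_reset_isolates_second_cluster(self):
        p = np.vstack([np.zeros((40, 3)), np.full((40, 3), 10.0)])
        c = running_center_of_mass(p, breaks=[40])
        assert np.allclose(c[40:], 10.0)

    def test_jittered_center_converges(self):
        rng = np.random.default_rng(0)
        p = np.array([3.0, -1.0, 2.0]) + rng.normal(0, 0.5, (600, 3))
        c = running_center_of_mass(p)
        assert np.linalg.norm(c[-1] - [3.0, -1.0, 2.0]) < 0.1

    def test_stable_mask_freezes_center(self):
        p = np.zeros((60, 3))
        p[30:, 0] = 8.0
        mask = np.ones(60, bool)
        mask[30:] = False
        c = running_center_of_mass(p, stable_mask=mask)
        assert np.allclose(c[30:], 0.0)


class TestClassification:
    def test_stationary_all_stable(self):
        n = 300
        comp = np.zeros((n, 3))
        flags = classify_stability(comp, np.zeros(n), _t(n))
        assert flags.all()

    def test_strict_threshold_semantics(self):
        """2.9 mm displacement at 2.4 cm/s is stable; the printed thresholds
        are strict upper bounds."""
        n = 240
        comp = np.zeros((n, 3))
        comp[120:, 0] = 2.9
        ok = classify_stability(comp, np.full(n, 2.4), _t(n))
        assert ok.all()
        too_fast = classify_stability(comp, np.full(n, 2.5), _t(n))
        assert not too_fast.any()

    def test_sustained_step_unstable_until_site_break(self):
        n = int(15 * FS)
        comp = np.zeros((n, 3))
        step = int(5 * FS)
        comp[step:, 0] = 5.0
        flags = classify_stability(comp, np.zeros(n), _t(n))
        assert flags[:step].all()
        grace_end = step + int(3 * FS)
        assert not flags[step:grace_end].any()       # away, centre frozen
        assert flags[grace_end + 2:].all()           # new site after break

    def test_monotone_in_thresholds_without_site_breaks(self):
        """Enlarging d_max or v_max never shrinks the stable set when the
        trajectory contains no site break."""
        for seed in range(4):
            mv = MovementEvent(t_start=16.0, duration=2.0,
                               displacement_mm=(6, -4, 3))
            cfg = stationary_config(seed=seed, rf_duration_s=12, movements=[mv])
            res = analyze_session(simulate_session(cfg))
            comp, speed = res.splus.compensated, res.splus.speed_cm_s
            t = res.session.trajectory.t
            assert res.splus.break_runs == []
            base = classify_stability(comp, speed, t)
            for p in (StabilityPlusParams(d_max_mm=5.0),
                      StabilityPlusParams(v_max_cm_s=4.0)):
                assert np.all(classify_stability(comp, speed, t, p)[base])


class TestThermalLatency:
    def _flags_with_run(self, n, a, b):
        f = np.ones(n, bool)
        f[a:b] = False
        return f

    def test_no_unstable_runs_is_identity(self):
        n = 200
        comp = np.zeros((n, 3))
        flags = np.ones(n, bool)
        out, runs = apply_thermal_latency(flags, comp, _t(n))
        assert np.array_equal(out, flags) and runs == []

    def test_short_returning_run_forgiven(self):
        n = 600
        comp = np.zeros((n, 3))
        comp[200:300, 0] = 6.0                      # 1.7 s away, returns
        flags = self._flags_with_run(n, 200, 300)
        out, runs = apply_thermal_latency(flags, comp, _t(n))
        assert out.all() and runs == []

    def test_long_run_breaks_site(self):
        n = 900
        comp = np.zeros((n, 3))
        comp[200:500, 0] = 6.0                      # 5 s away
        flags = self._flags_with_run(n, 200, 500)
        out, runs = apply_thermal_latency(flags, comp, _t(n))
        assert not out[200:500].any()
        assert runs == [(200, 500)]

    def test_non_returning_short_run_breaks_site(self):
        n = 600
        comp = np.zeros((n, 3))
        comp[200:, 0] = 6.0                         # settles 6 mm away
        flags = self._flags_with_run(n, 200, 290)   # run ends away from origin
        out, runs = apply_thermal_latency(flags, comp, _t(n))
        assert not out[200:290].any()
        assert runs == [(200, 290)]

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        comp = np.cumsum(rng.normal(0, 0.3, (n, 3)), axis=0)
        flags = rng.random(n) > 0.2
        once, runs1 = apply_thermal_latency(flags, comp, _t(n))
        twice, runs2 = apply_thermal_latency(once, comp, _t(n))
        assert np.array_equal(once, twice)
        assert runs1 == runs2


class TestTagsAndSites:
    def test_stable_from_onset_tags_at_min_dwell(self, stable_analysis):
        res = stable_analysis
        assert res.record.ttt_splus_s == pytest.approx(2.0, abs=1 / FS)
        tags = res.splus.tags
        assert len(tags) == 1 and tags[0].first_site and not tags[0].halo
        assert res.splus.pre_ablation_stable

    def test_initial_instability_postpones_tag(self):
        """A 1 s out-and-back excursion at RF onset is forgiven (session
        stays stable) but restarts the dwell clock: tag at ~3 s."""
        mv = MovementEvent(t_start=14.0, duration=1.0,
                           displacement_mm=(15, 0, 0))
        cfg = stationary_config(seed=3, movements=[mv])
        res = analyze_session(simulate_session(cfg))
        assert res.splus.break_runs == []
        assert not res.splus.unstable_during_rf
        assert res.record.ttt_splus_s == pytest.approx(3.0, abs=0.3)

    def test_never_stable_yields_no_tags(self):
        n = int(20 * FS)
        rng = np.random.default_rng(1)
        # fast large-amplitude wandering: both gates fail almost everywhere
        pos = np.cumsum(rng.normal(0, 1.5, (n, 3)), axis=0)
        ses, est = synthetic_session(pos, 10.0, 20.0)
        out = splus_tags(ses, est)
        assert out.tags == []
        assert not out.pre_ablation_stable

    def test_session_without_rf_rejected(self):
        n = int(5 * FS)
        ses, est = synthetic_session(np.zeros((n, 3)), 10.0, 20.0)
        ses.trajectory.rf_on[:] = False
        with pytest.raises(ValueError):
            splus_tags(ses, est)

    def test_halo_marks_site_broken_during_rf(self):
        mv = MovementEvent(t_start=17.0, duration=3.0,
                           displacement_mm=(8, 0, 0), return_to_origin=False)
        cfg = stationary_config(seed=5, rf_duration_s=14, movements=[mv])
        res = analyze_session(simulate_session(cfg))
        sp = res.splus
        assert sp.unstable_during_rf
        assert len(sp.tags) == 2
        assert sp.tags[0].halo and not sp.tags[1].halo
        assert sp.tags[0].first_site and not sp.tags[1].first_site

    def test_pre_ablation_instability_clears_flag(self):
        mv = MovementEvent(t_start=12.5, duration=1.0,
                           displacement_mm=(15, 0, 0))
        cfg = stationary_config(seed=6, movements=[mv])   # RF starts at 14 s
        res = analyze_session(simulate_session(cfg))
        assert not res.splus.pre_ablation_stable

    def test_tag_position_near_true_site(self, stable_analysis):
        """Tag centre lands near the true contact point; residual respiration
        leaves a sub-threshold bias."""
        tag = stable_analysis.splus.tags[0]
        assert np.linalg.norm(np.asarray(tag.position_mm)) < 2.0


class TestTableOneContrasts:
    @pytest.mark.parametrize("bpm", [8, 10, 12, 16])
    def test_latency_independent_of_respiratory_rate(self, bpm):
        cfg = stationary_config(rate_bpm=bpm, seed=4)
        res = analyze_session(simulate_session(cfg))
        assert res.record.ttt_splus_s == pytest.approx(2.0, abs=1 / FS)

    def test_short_duration_fit(self):
        """A 3.5 s very-high-power application tags under Stability+ and not
        under Gated at a 6 s respiratory period."""
        cfg = SessionConfig(mode="QMODE_PLUS", seed=2)
        res = analyze_session(simulate_session(cfg))
        assert res.record.ttt_splus_s is not None
        assert res.record.ttt_splus_s <= 2.0 + 1 / FS
        assert res.record.ttt_gated_s is None

    def test_zero_respiration_limit_neither_reports_instability(self):
        cfg = SessionConfig(
            rf_duration_s=10, seed=6, jitter_sd_mm=0.0,
            respiration=RespirationConfig(amplitude_mm=(0, 0, 0)),
        )
        res = analyze_session(simulate_session(cfg))
        assert res.record.ttt_splus_s == pytest.approx(2.0, abs=1 / FS)
        assert not res.splus.unstable_during_rf
        assert all(tg.stable for tg in res.gated_tags)
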