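import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trutta as T
from trutta.behavior import SensoryOvoid, _fatigue_kernel, _motivation_kernel

from conftest import make_uniform_field



def assert_angle(actual, expected, abs=1e-9):
    d = (actual - expected + np.pi) % (2 * np.pi) - np.pi
    assert d == pytest.approx(0.0, abs=abs)

class ZeroRng:
    """Stand-in rng whose draws are all zero (no random deviation)."""

    def random(self, n=None):
        return np.zeros(n) if n else 0.0


def make_state(pos=(8.0, 1.25, 0.07), **kw):
    return T.FishState(position=np.array(pos, dtype=float), **kw)


def make_ovoid(u=0.5, v=0.0, tke7=None, um7=None, amag7=None,
               wall_left=1.25, wall_right=1.25):
    n = 7
    um = np.full(n, np.hypot(u, v)) if um7 is None else np.asarray(um7, float)
    s = {
        "u": np.full(n, u), "v": np.full(n, v), "w": np.zeros(n),
        "U_m": um,
        "tke": np.zeros(n) if tke7 is None else np.asarray(tke7, float),
        "a_mag": np.zeros(n) if amag7 is None else np.asarray(amag7, float),
        "alpha": np.ones(n),
    }
    return SensoryOvoid(points=np.zeros((7, 3)), samples=s,
                        wall_front=5.0, wall_left=wall_left,
                        wall_right=wall_right)


class TestMotivation:
    def test_fast_fish_saturates_after_20_seconds(self):
        st_ = make_state(M=0.0, M_bar=0.0, category="fast")
        p = T.ParameterSet()
        for _ in range(40):                      # 40 * 0.5 s = 20 s stuck
            T.update_motivation(st_, made_progress=False, dt=0.5, params=p)
        assert st_.M == pytest.approx(1.0)

    def test_slow_fish_linear_accumulation(self):
        st_ = make_state(M=0.0, M_bar=0.0, category="slow")
        p = T.ParameterSet()
        for _ in range(130):                     # 65 s of 130 s denominator
            T.update_motivation(st_, made_progress=False, dt=0.5, params=p)
        assert st_.M == pytest.approx(65.0 / 130.0)

    def test_clamped_at_one(self):
        st_ = make_state(M=1.0, category="fast")
        T.update_motivation(st_, made_progress=False, dt=0.5,
                            params=T.ParameterSet())
        assert st_.M == 1.0

    def test_progress_decays_towards_initial(self):
        p = T.ParameterSet()
        st_ = make_state(M=0.9, M_bar=0.9)
        for _ in range(400):
            T.update_motivation(st_, made_progress=True, dt=0.5, params=p)
        assert st_.M == pytest.approx(p.motivation_initial, abs=1e-6)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            T.update_motivation(make_state(), True, 0.0, T.ParameterSet())


class TestFatigue:
    def test_burst_speed_drives_to_one(self):
        st_ = make_state(F=0.0)
        p = T.ParameterSet()
        for _ in range(400):
            T.update_fatigue(st_, U_rel=25.0, dt=0.5, params=p)
        assert st_.F > 0.99

    def test_rest_recovers_to_zero(self):
        st_ = make_state(F=0.8)
        for _ in range(600):
            T.update_fatigue(st_, U_rel=0.0, dt=0.5, params=T.ParameterSet())
        assert st_.F < 0.01

    def test_constant_load_fixed_point(self):
        # EWMA fixed point equals the load for any memory coefficients
        st_ = make_state(F=0.0)
        p = T.ParameterSet(fatigue_increasing_memory_coeff=0.3,
                           fatigue_decreasing_memory_coeff=0.07)
        for _ in range(500):
            T.update_fatigue(st_, U_rel=12.5, dt=0.5, params=p)
        assert st_.F == pytest.approx(0.5, abs=1e-6)

    def test_rejects_negative_speed(self):
        with pytest.raises(ValueError):
            T.update_fatigue(make_state(), -1.0, 0.5, T.ParameterSet())


class TestInternalStateBounds:
    @given(st.lists(st.tuples(st.booleans(), st.floats(0, 50)),
                    min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_m_and_f_stay_in_unit_interval(self, seq):
        p = T.ParameterSet()
        M, F = 0.5, 0.5
        for progress, u_rel in seq:
            M = float(_motivation_kernel(M, progress, 0.5, p.k_M_fast,
                                         p.motivation_memory_coeff,
                                         p.motivation_initial))
            F = float(_fatigue_kernel(F, min(1.0, u_rel / p.k_F),
                                      p.fatigue_increasing_memory_coeff,
                                      p.fatigue_decreasing_memory_coeff))
            assert 0.0 <= M <= 1.0
            assert 0.0 <= F <= 1.0


class TestBehaviorSelection:
    @pytest.mark.parametrize("m,f,h,expected", [
        (1.0, 0.0, 0.3, "migrating"),
        (0.0, 1.0, 0.3, "drifting"),
        (0.5, 0.5, 0.1, "holding"),
        (0.56, 0.5, 0.1, "holding"),     # inside the dead band
        (0.61, 0.5, 0.1, "migrating"),
    ])
    def test_dead_band(self, m, f, h, expected):
        p = T.ParameterSet(holding_extent=h)
        assert T.select_behavior(m, f, p) == expected


class TestMigratingAngle:
    def test_baseline_pure_rheotaxis(self):
        # flow due +x, no random draw: heading exactly -x
        ov = make_ovoid(u=0.5)
        ang = T.migrating_angle(ov, "baseline", T.ParameterSet(), ZeroRng())
        assert np.cos(ang) == pytest.approx(-1.0)

    def test_walldist_steers_towards_nearer_wall(self):
        p = T.ParameterSet()
        ov = make_ovoid(u=0.5, wall_left=0.1, wall_right=2.4)
        ang = T.migrating_angle(ov, "walldist", p, ZeroRng())
        assert_angle(ang, np.pi + p.migrating_wall_distance_angle)
        ov = make_ovoid(u=0.5, wall_left=2.4, wall_right=0.1)
        ang = T.migrating_angle(ov, "walldist", p, ZeroRng())
        assert_angle(ang, np.pi - p.migrating_wall_distance_angle)

    @pytest.mark.parametrize("left,right,sign", [
        (0.5, 0.8, +1),     # lower velocity on the left: steer left
        (0.8, 0.5, -1),
    ])
    def test_velocity_side_rule(self, left, right, sign):
        cfg = T.SimulationConfig()
        um = np.array([0.6, 0.6, 0.6, left, right, 0.6, 0.6])
        ov = make_ovoid(u=0.6, um7=um)
        ang = T.migrating_angle(ov, "velocity", T.ParameterSet(), ZeroRng(),
                                config=cfg)
        assert_angle(ang, np.pi + sign * cfg.default_swim_angle)

    def test_velocity_threshold_gates_small_differences(self):
        um = np.array([0.6, 0.6, 0.6, 0.60, 0.61, 0.6, 0.6])
        ov = make_ovoid(u=0.6, um7=um)
        p = T.ParameterSet(stimulus_threshold_factor=0.1)
        ang = T.migrating_angle(ov, "velocity", p, ZeroRng())
        assert np.cos(ang) == pytest.approx(-1.0)    # falls back to baseline

    @pytest.mark.parametrize("left,right,sign", [
        (0.9, 0.1, +1),     # higher acceleration on the left: steer left
        (0.1, 0.9, -1),
    ])
    def test_acceleration_side_rule(self, left, right, sign):
        cfg = T.SimulationConfig()
        am = np.array([0.5, 0.5, 0.5, left, right, 0.5, 0.5])
        ov = make_ovoid(u=0.6, amag7=am)
        ang = T.migrating_angle(ov, "acceleration", T.ParameterSet(),
                                ZeroRng(), config=cfg)
        assert_angle(ang, np.pi + sign * cfg.default_swim_angle)

    def test_tke_seeks_constant_turbulence(self):
        cfg = T.SimulationConfig()
        # center tke 0.05; front 0.2, left 0.06 (closest), right 0.5
        tke = np.array([0.05, 0.2, 0.05, 0.06, 0.5, 0.05, 0.05])
        ov = make_ovoid(u=0.6, tke7=tke)
        ang = T.migrating_angle(ov, "tke", T.ParameterSet(), ZeroRng(),
                                config=cfg)
        assert_angle(ang, np.pi + cfg.default_swim_angle)
        # front closest: no side steer
        tke = np.array([0.05, 0.051, 0.05, 0.2, 0.5, 0.05, 0.05])
        ov = make_ovoid(u=0.6, tke7=tke)
        ang = T.migrating_angle(ov, "tke", T.ParameterSet(), ZeroRng(),
                                config=cfg)
        assert np.cos(ang) == pytest.approx(-1.0)

    def test_tied_stimuli_fair_coin(self):
        p = T.ParameterSet()
        ov = make_ovoid(u=0.5, wall_left=0.3, wall_right=0.3)

        class SideRng:
            def __init__(self, u2):
                self.u2 = u2

            def random(self, n):
                return np.array([0.0, 0.0, self.u2])

        a_left = T.migrating_angle(ov, "walldist", p, SideRng(0.2))
        a_right = T.migrating_angle(ov, "walldist", p, SideRng(0.8))
        assert_angle(a_left, np.pi + p.migrating_wall_distance_angle)
        assert_angle(a_right, np.pi - p.migrating_wall_distance_angle)


class TestVerticalRule:
    def test_zero_at_reference(self):
        st_ = make_state(pos=(8.0, 1.25, 0.07))
        assert T.vertical_angle(st_, make_ovoid(), T.ParameterSet()) == 0.0

    def test_downward_correction_when_high(self):
        p = T.ParameterSet(vertical_elevation_threshold=0.1)
        st_ = make_state(pos=(8.0, 1.25, 0.37))
        assert T.vertical_angle(st_, make_ovoid(), p) == pytest.approx(
            -p.vertical_correction_angle)

    def test_degenerate_zero_angle(self):
        p = T.ParameterSet(vertical_correction_angle=0.0)
        st_ = make_state(pos=(8.0, 1.25, 0.5))
        assert T.vertical_angle(st_, make_ovoid(), p) == 0.0


class TestHoldingAndDrifting:
    def test_holding_opposes_flow(self):
        s = T.HydraulicSample(u=0.6, v=0.0, w=0.0, U_m=0.6, gamma_m=0.0,
                              beta_m=0.0, tke=0.01, a_mag=0.0, alpha=1.0)
        d = T.holding_vector(s, BL=0.27)
        assert d.speed == pytest.approx(0.6 / 0.27)
        assert np.cos(d.horizontal_angle) == pytest.approx(-1.0)

    def test_holding_still_water(self):
        s = T.HydraulicSample(u=0.0, v=0.0, w=0.0, U_m=0.0, gamma_m=0.0,
                              beta_m=0.0, tke=0.0, a_mag=0.0, alpha=1.0)
        assert T.holding_vector(s, BL=0.27).speed == 0.0

    def test_holding_capped_at_burst_speed(self):
        p = T.ParameterSet()
        s = T.HydraulicSample(u=10.0, v=0.0, w=0.0, U_m=10.0, gamma_m=0.0,
                              beta_m=0.0, tke=0.0, a_mag=0.0, alpha=1.0)
        assert T.holding_vector(s, BL=0.27, params=p).speed == p.k_F

    def test_straight_drift_is_passive(self):
        p = T.ParameterSet(drift_straight_prob=1.0)
        s = T.HydraulicSample(u=0.6, v=0.0, w=0.0, U_m=0.6, gamma_m=0.0,
                              beta_m=0.0, tke=0.0, a_mag=0.0, alpha=1.0)
        d = T.drifting_vector(s, p, ZeroRng())
        assert d.speed == 0.0

    def test_counter_swim_halves_downstream_speed(self):
        p = T.ParameterSet(drift_straight_prob=0.0)
        cfg = T.SimulationConfig(drift_counter_fraction=0.5)
        s = T.HydraulicSample(u=0.6, v=0.0, w=0.0, U_m=0.6, gamma_m=0.0,
                              beta_m=0.0, tke=0.0, a_mag=0.0, alpha=1.0)
        d = T.drifting_vector(s, p, ZeroRng(), config=cfg)
        net = 0.6 + np.cos(d.horizontal_angle) * d.speed * 0.27
        assert net == pytest.approx(0.3)


class TestOvoid:
    def test_uniform_field_identical_samples(self, uniform_field):
        ov = T.build_ovoid(make_state(), uniform_field)
        assert np.allclose(ov.samples["u"], 0.5, atol=1e-12)
        assert ov.points.shape == (7, 3)

    def test_wall_distances_near_right_wall(self, uniform_field):
        # y small = near the right wall; fish faces upstream
        ov = T.build_ovoid(make_state(pos=(8.0, 0.2, 0.07)), uniform_field)
        assert ov.wall_left < ov.wall_right

    def test_heading_reversal_swaps_front_back(self, uniform_field):
        a = T.build_ovoid(make_state(heading=np.pi), uniform_field)
        b = T.build_ovoid(make_state(heading=0.0), uniform_field)
        assert np.allclose(a.points[1], b.points[2])
        assert np.allclose(a.points[2], b.points[1])


class TestStep:
    def test_holding_cancels_uniform_flow(self, uniform_field):
        st_ = make_state()
        start = st_.position.copy()
        for _ in range(200):
            T.step(st_, uniform_field, T.ParameterSet(),
                   rng=np.random.default_rng(0), force_rule="holding")
        assert np.linalg.norm(st_.position - start) < 1e-9

    def test_passive_transport_kinematics(self):
        field = make_uniform_field(velocity=(0.67, 0.0, 0.0))
        p = T.ParameterSet(drift_straight_prob=1.0)
        st_ = make_state(pos=(8.0, 1.25, 0.07))
        T.step(st_, field, p, dt=0.5, rng=np.random.default_rng(0),
               force_rule="drifting")
        assert st_.position[0] == pytest.approx(8.0 + 0.335)

    def test_migrating_monotone_upstream_in_mild_flow(self):
        field = make_uniform_field(velocity=(0.3, 0.0, 0.0))
        st_ = make_state(pos=(14.0, 1.25, 0.07))
        rng = np.random.default_rng(2)
        xs = [st_.position[0]]
        for _ in range(50):
            T.step(st_, field, T.ParameterSet(), rng=rng,
                   force_rule="migrating")
            xs.append(st_.position[0])
            if st_.position[0] <= field.geometry.line_D_x:
                break
        assert np.all(np.diff(xs) < 0)

    def test_rejects_bad_dt(self, uniform_field):
        with pytest.raises(ValueError):
            T.step(make_state(), uniform_field, T.ParameterSet(), dt=-0.5)


class TestRunSimulation:
    def test_identical_seed_identical_tracks(self, field_nojet):
        kw = dict(n_fish=10, seed=656, version="walldist", max_minutes=10.0)
        a = T.run_simulation(field_nojet, **kw)
        b = T.run_simulation(field_nojet, **kw)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.t, tb.t)
            assert np.array_equal(ta.x, tb.x)
            assert np.array_equal(ta.y, tb.y)
            assert np.array_equal(ta.z, tb.z)

    def test_forced_migrating_reaches_line_d(self, geom_nojet):
        field = make_uniform_field(geom_nojet, velocity=(0.3, 0.0, 0.0))
        tracks = T.run_simulation(field, n_fish=1, seed=1, version="baseline",
                                  max_minutes=10.0, force_rule="migrating")
        assert tracks[0].x[-1] <= geom_nojet.line_D_x

    def test_all_fish_start_right_when_left_share_zero(self, field_nojet):
        p = T.ParameterSet(init_left_frac=0.0)
        tracks = T.run_simulation(field_nojet, params=p, n_fish=20, seed=3,
                                  max_minutes=0.1)
        g = field_nojet.geometry
        for tr in tracks:
            assert tr.y[0] <= g.dy

    def test_drifting_monotone_downstream(self, field_nojet):
        tracks = T.run_simulation(field_nojet, n_fish=5, seed=4,
                                  version="baseline", max_minutes=5.0,
                                  force_rule="drifting")
        for tr in tracks:
            assert np.all(np.diff(tr.x) >= -1e-12)

    def test_zero_side_angles_collapse_to_baseline(self, field_nojet):
        p = T.ParameterSet(migrating_wall_distance_angle=0.0)
        cfg = T.SimulationConfig(default_swim_angle=0.0)
        ref = T.run_simulation(field_nojet, params=p, n_fish=6, seed=9,
                               version="baseline", max_minutes=8.0, config=cfg)
        for version in ("velocity", "tke", "acceleration", "walldist"):
            out = T.run_simulation(field_nojet, params=p, n_fish=6, seed=9,
                                   version=version, max_minutes=8.0,
                                   config=cfg)
            for ta, tb in zip(ref, out):
                assert np.array_equal(ta.x, tb.x)
                assert np.array_equal(ta.y, tb.y)
                assert np.array_equal(ta.z, tb.z)

    def test_positions_stay_inside_domain(self, field_jet):
        g = field_jet.geometry
        tracks = T.run_simulation(field_jet, n_fish=10, seed=5,
                                  max_minutes=10.0)
        for tr in tracks:
            assert np.all((tr.y >= 0) & (tr.y <= g.width))
            assert np.all((tr.z >= 0) & (tr.z <= g.water_depth))
            assert np.all(tr.x >= 0)

    def test_slower_motivation_never_helps_arrival(self, field_nojet):
        # raising the motivation denominators must not raise the arrival rate
        g = field_nojet.geometry
        rates = []
        for scale in (1.0, 2.5):
            p = T.ParameterSet(k_M_fast=20.0 * scale, k_M_slow=130.0 * scale)
            p5 = []
            for seed in range(10):
                tracks = T.run_simulation(field_nojet, params=p, n_fish=20,
                                          seed=seed, version="walldist",
                                          max_minutes=15.0)
                valid = T.filter_valid_tracks(tracks, g)
                if valid:
                    p5.append(T.arrival_rate(valid, g)[0])
            rates.append(np.mean(p5))
        assert rates[1] <= rates[0] + 5.0     # sampling-error tolerance
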