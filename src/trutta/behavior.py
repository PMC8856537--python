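"""Behavioral rules and the agent loop for upstream-orienting fish.

Each fish is a point agent with two bounded internal states — motivation to
move upstream (M) and fatigue (F), both in [0, 1] — whose time-averaged
balance selects one of three horizontal rules every time step:

* migrating: swim upstream against the local flow direction (positive
  rheotaxis) with a limited random angle, optionally biased by one of five
  stimulus versions (baseline, velocity, tke, acceleration, walldist);
* holding:   oppose the local flow vector exactly so net displacement is ~0;
* drifting:  move downstream with the flow, swimming against it at a fraction
  of the flow speed, with a limited random deviation.

An independent vertical rule steers fish back towards a preferred
near-bottom elevation. Perception happens through a sensory ovoid of seven
points (center + front/back/left/right/up/down at the skin/water interface)
where hydraulic variables are interpolated, plus capped wall distances
towards the front and both sides.

The kinematic position update per time step dt is::

    x_new = x_old + (swim_vector * BL + flow_vector) * dt

The module exposes scalar per-fish operations for inspection and testing and
a vectorised cohort engine (:func:`run_simulation`) used for production runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, fields as dc_fields
from typing import Optional, Sequence

import numpy as np

from .flowfield import FlowField, sample_many, wall_distances, HydraulicSample
from .patterns import Track

VERSIONS = ("baseline", "velocity", "tke", "acceleration", "walldist")
RULES = ("migrating", "holding", "drifting")

# status codes of a fish during a run
_ACTIVE, _ARRIVED, _EXITED, _TIMEOUT = 0, 1, 2, 3


@dataclass
class ParameterSet:
    """The 20 variable parameters of the behavioral model.

    Probabilities and memory coefficients live in [0, 1]; angles are radians
    in (0, pi/2]; denominators are strictly positive. The motivation
    denominators are the times after which motivation saturates for fast
    (20 s) and slow (130 s) fish when no upstream progress is made; the
    fatigue denominator is the burst swim speed (25 BL/s) at which the
    instantaneous fatigue load saturates.
    """

    motivation_initial: float = 0.12
    motivation_memory_coeff: float = 0.05
    k_M_fast: float = 20.0
    k_M_slow: float = 130.0
    spot_memory_coeff: float = 0.01
    fatigue_increasing_memory_coeff: float = 0.1
    fatigue_decreasing_memory_coeff: float = 0.02
    k_F: float = 25.0
    holding_extent: float = 0.05
    drift_straight_prob: float = 0.5
    vertical_elevation_threshold: float = 0.10
    vertical_correction_angle: float = 0.3
    stuck_time_threshold: float = 30.0
    migrating_max_random_angle: float = 0.5
    wall_detection_range: float = 1.0
    migrating_wall_distance_angle: float = 0.175
    stimulus_threshold_factor: float = 0.1
    init_left_frac: float = 0.33
    init_slow_left_frac: float = 0.5
    init_slow_right_frac: float = 0.5

    def __post_init__(self) -> None:
        for name in ("motivation_initial", "motivation_memory_coeff",
                     "spot_memory_coeff", "fatigue_increasing_memory_coeff",
                     "fatigue_decreasing_memory_coeff", "drift_straight_prob",
                     "init_left_frac", "init_slow_left_frac",
                     "init_slow_right_frac", "holding_extent",
                     "stimulus_threshold_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("migrating_max_random_angle", "vertical_correction_angle",
                     "migrating_wall_distance_angle"):
            v = getattr(self, name)
            if not 0.0 <= v <= np.pi / 2:
                raise ValueError(f"{name}={v} must lie in [0, pi/2]")
        for name in ("k_M_fast", "k_M_slow", "k_F", "stuck_time_threshold",
                     "wall_detection_range", "vertical_elevation_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def names(cls) -> list:
        return [f.name for f in dc_fields(cls)]


@dataclass
class SimulationConfig:
    """Fixed model configuration (not part of the varied parameter space)."""

    body_length: float = 0.27        # m
    dt: float = 0.5                  # s
    migrating_swim_speed: float = 4.5   # BL/s, sustained speed while migrating
    default_swim_angle: float = 0.35    # rad, side-steer for velocity/tke/accel
    drift_counter_fraction: float = 0.5  # swim-against fraction of U_m
    drift_max_angle: float = 0.3     # rad, random deviation while drifting
    reference_elevation: float = 0.07   # m, preferred height above bottom
    progress_eps: float = 0.01       # m, minimum upstream gain counted
    ovoid_front_frac: float = 0.5    # ovoid offsets, fractions of BL
    ovoid_lateral_frac: float = 0.15
    ovoid_vertical_frac: float = 0.1
    idw_k: int = 8

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")


@dataclass
class FishState:
    """One agent: position, traits, internal states and memories."""

    position: np.ndarray
    body_length: float = 0.27
    category: str = "fast"           # "fast" | "slow"
    M: float = 0.12
    F: float = 0.0
    M_bar: float = 0.12
    best_x: float = np.inf           # spot memory: best upstream x reached
    t_since_progress: float = 0.0
    heading: float = np.pi           # facing upstream initially
    rule: str = "migrating"
    last_load: float = 0.0
    status: int = _ACTIVE

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.category not in ("fast", "slow"):
            raise ValueError("category must be 'fast' or 'slow'")
        if not np.isfinite(self.best_x):
            self.best_x = float(self.position[0])


@dataclass
class SensoryOvoid:
    """Seven perception points with interpolated samples and wall distances.

    Point order: 0 center, 1 front, 2 back, 3 left, 4 right, 5 up, 6 down
    (body frame, offsets scaled by body length).
    """

    points: np.ndarray          # (7, 3)
    samples: dict               # arrays of length 7: u, v, w, U_m, tke, a_mag
    wall_front: float
    wall_left: float
    wall_right: float
    clamped: np.ndarray = dc_field(default_factory=lambda: np.zeros(7, bool))


@dataclass
class SwimDecision:
    """The outcome of one behavioral decision."""

    horizontal_angle: float     # rad, world frame
    vertical_angle: float       # rad
    speed: float                # BL/s
    rule: str
    version: str = "baseline"


# ---------------------------------------------------------------------------
# Internal-state kernels (elementwise; used both scalar and vectorised)
# ---------------------------------------------------------------------------

def _motivation_kernel(M, made_progress, dt, k_M, c_mem, M_init):
    grown = np.minimum(1.0, M + dt / k_M)
    decayed = M + c_mem * (M_init - M)
    return np.clip(np.where(made_progress, decayed, grown), 0.0, 1.0)


def _fatigue_kernel(F, load, c_up, c_down):
    c = np.where(load > F, c_up, c_down)
    return np.clip(F + c * (load - F), 0.0, 1.0)


def update_motivation(state: FishState, made_progress: bool, dt: float,
                      params: ParameterSet) -> float:
    """Advance motivation: linear growth towards 1 while stuck (saturating
    after k_M seconds), exponential decay towards its initial value while
    progressing. The time-averaged memory M_bar follows with the same
    memory coefficient."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    k_M = params.k_M_fast if state.category == "fast" else params.k_M_slow
    state.M = float(_motivation_kernel(state.M, made_progress, dt, k_M,
                                       params.motivation_memory_coeff,
                                       params.motivation_initial))
    c = params.motivation_memory_coeff
    state.M_bar = float(np.clip(state.M_bar + c * (state.M - state.M_bar),
                                0.0, 1.0))
    return state.M


def update_fatigue(state: FishState, U_rel: float, dt: float,
                   params: ParameterSet) -> float:
    """Advance fatigue as an EWMA of the instantaneous load min(1, U_rel/k_F)
    with separate rising and falling memory coefficients. ``U_rel`` is the
    water-relative swim speed in BL/s; the load saturates at burst speed."""
    if U_rel < 0:
        raise ValueError("relative speed must be non-negative")
    load = min(1.0, U_rel / params.k_F)
    state.F = float(_fatigue_kernel(state.F, load,
                                    params.fatigue_increasing_memory_coeff,
                                    params.fatigue_decreasing_memory_coeff))
    return state.F


def select_behavior(M_bar: float, F_bar: float, params: ParameterSet) -> str:
    """Dead-band selection on the motivation-fatigue balance: migrating when
    M_bar - F_bar exceeds the holding extent, drifting when it falls below
    its negative, holding inside the band."""
    h = params.holding_extent
    d = M_bar - F_bar
    if d > h:
        return "migrating"
    if d < -h:
        return "drifting"
    return "holding"


# ---------------------------------------------------------------------------
# Perception
# ---------------------------------------------------------------------------

def _ovoid_points(pos: np.ndarray, heading: np.ndarray, BL: float,
                  cfg: SimulationConfig) -> np.ndarray:
    """(n, 7, 3) ovoid points in the world frame, aligned with the heading."""
    n = pos.shape[0]
    c, s = np.cos(heading), np.sin(heading)
    fwd = np.stack([c, s, np.zeros(n)], axis=1)
    left = np.stack([-s, c, np.zeros(n)], axis=1)
    up = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    pts = np.empty((n, 7, 3))
    pts[:, 0] = pos
    pts[:, 1] = pos + cfg.ovoid_front_frac * BL * fwd
    pts[:, 2] = pos - cfg.ovoid_front_frac * BL * fwd
    pts[:, 3] = pos + cfg.ovoid_lateral_frac * BL * left
    pts[:, 4] = pos - cfg.ovoid_lateral_frac * BL * left
    pts[:, 5] = pos + cfg.ovoid_vertical_frac * BL * up
    pts[:, 6] = pos - cfg.ovoid_vertical_frac * BL * up
    return pts


def _clamp_to_domain(pts: np.ndarray, field: FlowField) -> np.ndarray:
    lo, hi = field.geometry.bounds
    eps = 1e-6
    clamped = (pts < lo + eps) | (pts > hi - eps)
    np.clip(pts, lo + eps, hi - eps, out=pts)
    return np.any(clamped, axis=-1)


def build_ovoid(state: FishState, field: FlowField,
                params: Optional[ParameterSet] = None,
                config: Optional[SimulationConfig] = None) -> SensoryOvoid:
    """Perceive the local environment: interpolate hydraulic variables at the
    seven ovoid points (clamped to the wetted domain and flagged when so) and
    cast capped wall-distance rays front/left/right."""
    params = params or ParameterSet()
    cfg = config or SimulationConfig()
    pts = _ovoid_points(state.position[None, :], np.array([state.heading]),
                        state.body_length, cfg)[0]
    clamped = _clamp_to_domain(pts, field)
    s = sample_many(field, pts, k=cfg.idw_k)
    f, l, r = wall_distances(field.geometry, state.position[0],
                             state.position[1], state.heading,
                             cap=params.wall_detection_range)
    return SensoryOvoid(points=pts, samples=s, wall_front=float(f[0]),
                        wall_left=float(l[0]), wall_right=float(r[0]),
                        clamped=clamped)


# ---------------------------------------------------------------------------
# Steering
# ---------------------------------------------------------------------------

def _side_delta(version: str, s: dict, wall_l, wall_r,
                params: ParameterSet, cfg: SimulationConfig, u_tie):
    """Signed stimulus steering angle; +1 steers towards body-left.

    Vectorised over fish; ``s`` holds (n, 7) sample arrays in ovoid order.
    """
    n = s["U_m"].shape[0]
    coin = np.where(u_tie < 0.5, 1.0, -1.0)
    if version == "baseline":
        return np.zeros(n)
    if version == "walldist":
        side = np.where(wall_l < wall_r, 1.0,
                        np.where(wall_r < wall_l, -1.0, coin))
        return side * params.migrating_wall_distance_angle
    if version in ("velocity", "acceleration"):
        key = "U_m" if version == "velocity" else "a_mag"
        L, R = s[key][:, 3], s[key][:, 4]
        hi = np.maximum(np.maximum(L, R), 1e-12)
        fire = np.abs(L - R) / hi > params.stimulus_threshold_factor
        if version == "velocity":      # towards lower velocity magnitude
            side = np.where(L < R, 1.0, np.where(R < L, -1.0, coin))
        else:                          # towards higher acceleration
            side = np.where(L > R, 1.0, np.where(R > L, -1.0, coin))
        return np.where(fire, side * cfg.default_swim_angle, 0.0)
    if version == "tke":
        # towards front/left/right point with smallest TKE difference to the
        # fish center (constant-turbulence seeking); front wins exact ties,
        # lateral ties are broken by a fair coin
        dif = np.abs(s["tke"][:, (1, 3, 4)] - s["tke"][:, 0:1])
        front_best = (dif[:, 0] <= dif[:, 1]) & (dif[:, 0] <= dif[:, 2])
        side = np.where(dif[:, 1] < dif[:, 2], 1.0,
                        np.where(dif[:, 2] < dif[:, 1], -1.0, coin))
        return np.where(front_best, 0.0, side * cfg.default_swim_angle)
    raise ValueError(f"unknown stimulus version '{version}'")


def migrating_angle(ovoid: SensoryOvoid, version: str, params: ParameterSet,
                    rng, config: Optional[SimulationConfig] = None) -> float:
    """Horizontal swim angle for the migrating rule.

    Base direction opposes the interpolated flow at the fish center; a random
    angle of up to the migrating max random angle is added towards a random
    side; non-baseline versions add their stimulus steer on top.
    """
    cfg = config or SimulationConfig()
    u = np.asarray(rng.random(3), dtype=float)
    s1 = {k: np.asarray(v)[None, :] for k, v in ovoid.samples.items()}
    base = float(np.arctan2(-ovoid.samples["v"][0], -ovoid.samples["u"][0]))
    rand = float(u[0]) * params.migrating_max_random_angle * (
        1.0 if u[1] < 0.5 else -1.0)
    side = float(_side_delta(version, s1, np.array([ovoid.wall_left]),
                             np.array([ovoid.wall_right]), params, cfg,
                             np.array([u[2]]))[0])
    return base + rand + side


def vertical_angle(state: FishState, ovoid: SensoryOvoid,
                   params: ParameterSet,
                   config: Optional[SimulationConfig] = None) -> float:
    """Vertical correction: steer back towards the reference elevation by the
    vertical correction angle once the elevation difference exceeds the
    threshold; zero otherwise."""
    cfg = config or SimulationConfig()
    dz = state.position[2] - cfg.reference_elevation
    if dz > params.vertical_elevation_threshold:
        return -params.vertical_correction_angle
    if dz < -params.vertical_elevation_threshold:
        return params.vertical_correction_angle
    return 0.0


def holding_vector(sample: HydraulicSample, BL: float,
                   params: Optional[ParameterSet] = None) -> SwimDecision:
    """Swim vector that exactly opposes the local flow (capped at burst
    speed, in which case holding fails and the fish loses ground)."""
    params = params or ParameterSet()
    speed = min(sample.U_m / BL, params.k_F)
    ang_h = np.arctan2(-sample.v, -sample.u)
    hyp = np.hypot(sample.u, sample.v)
    ang_v = np.arctan2(-sample.w, hyp) if sample.U_m > 0 else 0.0
    return SwimDecision(horizontal_angle=float(ang_h),
                        vertical_angle=float(ang_v),
                        speed=float(speed), rule="holding")


def drifting_vector(sample: HydraulicSample, params: ParameterSet, rng,
                    config: Optional[SimulationConfig] = None,
                    BL: float = 0.27) -> SwimDecision:
    """Downstream transport: with the straight-drift probability the fish is
    carried passively along the flow vector; otherwise it swims against the
    flow at a fraction of U_m with a limited random deviation."""
    cfg = config or SimulationConfig()
    u = np.asarray(rng.random(3), dtype=float)
    against = np.arctan2(-sample.v, -sample.u)
    if u[2] < params.drift_straight_prob:
        return SwimDecision(horizontal_angle=float(against), vertical_angle=0.0,
                            speed=0.0, rule="drifting")
    dev = float(u[0]) * cfg.drift_max_angle * (1.0 if u[1] < 0.5 else -1.0)
    speed = min(cfg.drift_counter_fraction * sample.U_m / BL, params.k_F)
    return SwimDecision(horizontal_angle=float(against + dev),
                        vertical_angle=0.0, speed=float(speed),
                        rule="drifting")


# ---------------------------------------------------------------------------
# Cohort engine
# ---------------------------------------------------------------------------

class _Cohort:
    """Vectorised state of n fish advanced one time step at a time."""

    def __init__(self, field: FlowField, params: ParameterSet,
                 cfg: SimulationConfig, version: str,
                 force_rule: Optional[str] = None):
        if version not in VERSIONS:
            raise ValueError(f"unknown stimulus version '{version}'")
        if force_rule is not None and force_rule not in RULES:
            raise ValueError(f"unknown rule '{force_rule}'")
        self.field = field
        self.params = params
        self.cfg = cfg
        self.version = version
        self.force_rule = force_rule
        g = field.geometry
        self._lineD = g.line_D_x
        self._xmax = g.length

    def init_arrays(self, pos, category, heading=None):
        p = self.params
        n = pos.shape[0]
        self.n = n
        self.pos = np.array(pos, dtype=float)
        self.heading = (np.full(n, np.pi) if heading is None
                        else np.array(heading, dtype=float))
        self.category = np.asarray(category)
        self.k_M = np.where(self.category == "fast", p.k_M_fast, p.k_M_slow)
        self.M = np.full(n, p.motivation_initial)
        self.M_bar = np.full(n, p.motivation_initial)
        self.F = np.zeros(n)
        self.last_load = np.zeros(n)
        self.best_x = self.pos[:, 0].copy()
        self.t_since = np.zeros(n)
        self.status = np.full(n, _ACTIVE, dtype=np.int64)
        self.rule_code = np.zeros(n, dtype=np.int64)

    def advance(self, draws: np.ndarray) -> None:
        """One time step for all active fish. ``draws`` is (n, 4) uniforms in
        [0, 1); inactive rows are ignored."""
        p, cfg = self.params, self.cfg
        act = np.flatnonzero(self.status == _ACTIVE)
        if act.size == 0:
            return
        BL = cfg.body_length
        dt = cfg.dt
        pos = self.pos[act]
        psi = self.heading[act]
        u0, u1, u2, u3 = (draws[act, i] for i in range(4))

        # --- perception -----------------------------------------------------
        pts = _ovoid_points(pos, psi, BL, cfg)
        _clamp_to_domain(pts, self.field)
        raw = sample_many(self.field, pts.reshape(-1, 3), k=cfg.idw_k)
        s = {k: v.reshape(act.size, 7) for k, v in raw.items()}
        if np.any(~np.isfinite(s["u"])):
            bad = int(act[np.argmax(~np.isfinite(s["u"]).all(axis=1))])
            raise RuntimeError(f"NaN in field sample for fish {bad}")
        wf, wl, wr = wall_distances(self.field.geometry, pos[:, 0], pos[:, 1],
                                    psi, cap=p.wall_detection_range)

        # --- internal states ------------------------------------------------
        progressing = self.t_since[act] <= p.stuck_time_threshold
        self.M[act] = _motivation_kernel(
            self.M[act], progressing, dt, self.k_M[act],
            p.motivation_memory_coeff, p.motivation_initial)
        self.M_bar[act] = np.clip(
            self.M_bar[act] + p.motivation_memory_coeff
            * (self.M[act] - self.M_bar[act]), 0.0, 1.0)
        self.F[act] = _fatigue_kernel(
            self.F[act], self.last_load[act],
            p.fatigue_increasing_memory_coeff,
            p.fatigue_decreasing_memory_coeff)

        # --- behavior selection --------------------------------------------
        if self.force_rule is not None:
            rule = np.full(act.size, RULES.index(self.force_rule))
        else:
            d = self.M_bar[act] - self.F[act]
            rule = np.where(d > p.holding_extent, 0,
                            np.where(d < -p.holding_extent, 2, 1))
        self.rule_code[act] = rule

        # --- steering -------------------------------------------------------
        uc, vc, wc = s["u"][:, 0], s["v"][:, 0], s["w"][:, 0]
        Um_c = s["U_m"][:, 0]
        against = np.arctan2(-vc, -uc)
        z = pos[:, 2]
        dz = z - cfg.reference_elevation
        beta = np.where(dz > p.vertical_elevation_threshold,
                        -p.vertical_correction_angle,
                        np.where(dz < -p.vertical_elevation_threshold,
                                 p.vertical_correction_angle, 0.0))

        # migrating
        rand = u0 * p.migrating_max_random_angle * np.where(u1 < 0.5, 1., -1.)
        side = _side_delta(self.version, s, wl, wr, p, cfg, u2)
        psi_mig = against + rand + side
        sp_mig = min(cfg.migrating_swim_speed, p.k_F)
        swim_mig = sp_mig * np.stack(
            [np.cos(beta) * np.cos(psi_mig), np.cos(beta) * np.sin(psi_mig),
             np.sin(beta)], axis=1)

        # holding: oppose the full 3D flow vector, capped at burst speed
        cap = np.minimum(1.0, p.k_F * BL / np.maximum(Um_c, 1e-12))
        swim_hold = -np.stack([uc, vc, wc], axis=1) / BL * cap[:, None]

        # drifting
        straight = u3 < p.drift_straight_prob
        dev = u0 * cfg.drift_max_angle * np.where(u1 < 0.5, 1.0, -1.0)
        psi_drift = against + dev
        sp_drift = np.where(straight, 0.0, np.minimum(
            cfg.drift_counter_fraction * Um_c / BL, p.k_F))
        swim_drift = sp_drift[:, None] * np.stack(
            [np.cos(beta) * np.cos(psi_drift),
             np.cos(beta) * np.sin(psi_drift), np.sin(beta)], axis=1)

        swim = np.where(rule[:, None] == 0, swim_mig,
                        np.where(rule[:, None] == 1, swim_hold, swim_drift))
        psi_new = np.where(rule == 0, psi_mig, against)

        # --- kinematics and boundaries -------------------------------------
        flow = np.stack([uc, vc, wc], axis=1)
        newp = pos + (swim * BL + flow) * dt
        g = self.field.geometry
        # reflect off side walls, bottom, surface and the upstream screen
        newp[:, 1] = np.abs(newp[:, 1])
        newp[:, 1] = g.width - np.abs(g.width - newp[:, 1])
        newp[:, 2] = np.abs(newp[:, 2])
        newp[:, 2] = g.water_depth - np.abs(g.water_depth - newp[:, 2])
        newp[:, 0] = np.abs(newp[:, 0])
        if g.slot_present:
            blocked = ((pos[:, 0] > g.slot_x) & (newp[:, 0] < g.slot_x)
                       & (newp[:, 1] > g.slot_opening))
            newp[blocked, 0] = 2.0 * g.slot_x - newp[blocked, 0]
        np.clip(newp[:, 1], 1e-6, g.width - 1e-6, out=newp[:, 1])
        np.clip(newp[:, 2], 1e-6, g.water_depth - 1e-6, out=newp[:, 2])

        # --- bookkeeping ----------------------------------------------------
        self.pos[act] = newp
        self.heading[act] = np.mod(psi_new, 2 * np.pi)
        # fatigue load grows with local flow velocity plus swim speed and
        # saturates at burst speed
        u_rel = Um_c / BL + np.linalg.norm(swim, axis=1)
        self.last_load[act] = np.minimum(1.0, u_rel / p.k_F)
        prog = newp[:, 0] < self.best_x[act] - cfg.progress_eps
        self.t_since[act] = np.where(prog, 0.0, self.t_since[act] + dt)
        relax = (newp[:, 0] > self.best_x[act]) & ~prog
        self.best_x[act] = np.where(
            prog, newp[:, 0],
            np.where(relax, self.best_x[act] + p.spot_memory_coeff
                     * (newp[:, 0] - self.best_x[act]), self.best_x[act]))
        arrived = newp[:, 0] <= self._lineD
        exited = newp[:, 0] >= self._xmax
        self.status[act] = np.where(arrived, _ARRIVED,
                                    np.where(exited, _EXITED, _ACTIVE))


def step(state: FishState, field: FlowField, params: ParameterSet,
         dt: Optional[float] = None, rng=None, version: str = "baseline",
         config: Optional[SimulationConfig] = None,
         force_rule: Optional[str] = None) -> FishState:
    """Advance a single fish one time step (perception, internal states,
    behavior selection, steering, kinematic move with wall reflection).
    Mutates and returns ``state``."""
    cfg = config or SimulationConfig()
    if dt is not None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        cfg = SimulationConfig(**{**cfg.__dict__, "dt": dt})
    cfg = SimulationConfig(**{**cfg.__dict__, "body_length": state.body_length})
    if state.status != _ACTIVE:
        return state
    rng = rng if rng is not None else np.random.default_rng(0)
    coh = _Cohort(field, params, cfg, version, force_rule=force_rule)
    coh.init_arrays(state.position[None, :], np.array([state.category]),
                    heading=np.array([state.heading]))
    coh.M[0], coh.M_bar[0], coh.F[0] = state.M, state.M_bar, state.F
    coh.best_x[0] = state.best_x
    coh.t_since[0] = state.t_since_progress
    coh.last_load[0] = state.last_load
    coh.advance(np.asarray(rng.random(4))[None, :])
    state.position = coh.pos[0]
    state.heading = float(coh.heading[0])
    state.M, state.M_bar = float(coh.M[0]), float(coh.M_bar[0])
    state.F = float(coh.F[0])
    state.best_x = float(coh.best_x[0])
    state.t_since_progress = float(coh.t_since[0])
    state.last_load = float(coh.last_load[0])
    state.rule = RULES[int(coh.rule_code[0])]
    state.status = int(coh.status[0])
    return state


def run_simulation(field: FlowField, params: Optional[ParameterSet] = None,
                   n_fish: int = 100, seed: int = 0,
                   version: str = "walldist",
                   max_minutes: float = 60.0,
                   config: Optional[SimulationConfig] = None,
                   force_rule: Optional[str] = None) -> list:
    """Run a cohort of fish through the field and return one Track per fish.

    Fish are initialised in the left/right lateral zones of the staging area
    at the downstream end according to the three initialisation fractions
    (left/total share, slow share per side) and stepped until they cross
    line D (arrival), leave the flume downstream, or the clock runs out.
    Randomness comes from one stream per fish derived deterministically from
    the run seed, so identical seeds give bit-identical output regardless of
    how other fish fare.
    """
    params = params or ParameterSet()
    cfg = config or SimulationConfig()
    g = field.geometry
    ss = np.random.SeedSequence(seed)
    gens = [np.random.default_rng(c) for c in ss.spawn(n_fish)]

    pos = np.empty((n_fish, 3))
    category = np.empty(n_fish, dtype=object)
    for i, rg in enumerate(gens):
        u = rg.random(5)
        left = u[0] < params.init_left_frac
        slow_frac = (params.init_slow_left_frac if left
                     else params.init_slow_right_frac)
        category[i] = "slow" if u[1] < slow_frac else "fast"
        pos[i, 0] = g.length - g.staging_extent * u[2]
        pos[i, 1] = (g.width - g.dy * u[3]) if left else g.dy * u[3]
        pos[i, 2] = 0.02 + 0.1 * u[4]
    coh = _Cohort(field, params, cfg, version, force_rule=force_rule)
    coh.init_arrays(pos, category)

    n_steps = int(np.round(max_minutes * 60.0 / cfg.dt))
    times = [0.0]
    snaps = [coh.pos.copy()]
    recorded = [np.ones(n_fish, dtype=bool)]
    for k in range(n_steps):
        act = coh.status == _ACTIVE
        if not act.any():
            break
        draws = np.zeros((n_fish, 4))
        for i in np.flatnonzero(act):
            draws[i] = gens[i].random(4)
        coh.advance(draws)
        times.append((k + 1) * cfg.dt)
        snaps.append(coh.pos.copy())
        recorded.append(act.copy())
    coh.status[coh.status == _ACTIVE] = _TIMEOUT

    t_arr = np.asarray(times)
    P = np.stack(snaps)              # (steps+1, n, 3)
    R = np.stack(recorded)           # (steps+1, n)
    tracks = []
    for i in range(n_fish):
        m = R[:, i]
        tracks.append(Track(fish_id=i, body_length=cfg.body_length,
                            t=t_arr[m], x=P[m, i, 0], y=P[m, i, 1],
                            z=P[m, i, 2], source="simulated"))
    return tracks
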