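"""Steady 3D hydraulic fields and flume geometry.

This module holds the hydraulic side of the fish-movement model: the flume
geometry (walls, screen, control lines, optional vertical slot), steady flow
fields stored as point clouds with k-NN inverse-distance interpolation, field
post-processing (turbulence kinetic energy from velocity variances, convective
spatial acceleration), a synthetic flume-field generator that stands in for a
CFD solve, and geometric queries (wall distances via ray casting).

Coordinate convention: ``x`` increases in the flow direction with the origin at
the upstream screen, so upstream migration *decreases* ``x``. ``y`` spans the
flume width; facing downstream (+x, z up) body-left points to +y, so
``y = width`` is the left wall and ``y = 0`` the right wall (the slot/jet
side). ``z = 0`` is the flume bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


class DomainError(ValueError):
    """A physically invalid input (non-positive extent, negative variance...)."""


class OutOfDomainError(ValueError):
    """A query point lies outside the wetted flume domain."""


class FieldFormatError(ValueError):
    """A field table is missing columns or contains non-numeric cells."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass
class FlumeGeometry:
    """Rectangular laboratory flume with control lines and an optional slot.

    Defaults describe a 16.38 m x 2.50 m flume with 0.60 m water depth.
    Line D (upstream) and line A (downstream) are the control lines used for
    track filtering and the arrival-rate pattern; the region between them is
    the experimental area. The staging (release) area occupies the most
    downstream ``staging_extent`` metres. When ``slot_present`` a solid wall
    spans the cross-section at ``slot_x`` except for an opening of width
    ``slot_opening`` adjacent to the right wall (``y = 0``), producing a
    jet downstream of the slot on the right-hand flume side.
    """

    length: float = 16.38
    width: float = 2.50
    water_depth: float = 0.60
    line_A_x: float = 11.75
    line_D_x: float = 1.50
    staging_extent: float = 2.38
    dy: float = 0.25          # lateral wall-zone width for pattern P1
    dz: float = 0.15          # vertical wall-zone height for pattern P2
    slot_present: bool = False
    slot_x: float = 2.00
    slot_opening: float = 0.35

    def __post_init__(self) -> None:
        for name in ("length", "width", "water_depth", "staging_extent",
                     "dy", "dz", "slot_x", "slot_opening"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if not (0.0 <= self.line_D_x < self.line_A_x <= self.length):
            raise DomainError(
                "control lines must satisfy 0 <= line_D_x < line_A_x <= length")
        if 2.0 * self.dy >= self.width:
            raise DomainError("lateral zones must fit inside the width")
        if 2.0 * self.dz >= self.water_depth:
            raise DomainError("vertical zones must fit inside the water depth")

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of lower/upper corner of the wetted box."""
        return np.array([[0.0, 0.0, 0.0],
                         [self.length, self.width, self.water_depth]])

    def contains(self, point: Sequence[float]) -> bool:
        p = np.asarray(point, dtype=float)
        lo, hi = self.bounds
        return bool(np.all(p >= lo - 1e-12) and np.all(p <= hi + 1e-12))


def bulk_velocity(Q: float, width: float, depth: float) -> float:
    """Section-averaged streamwise velocity U_bulk = Q / (width * depth)."""
    if Q <= 0 or width <= 0 or depth <= 0:
        raise DomainError("discharge, width and depth must be positive")
    return Q / (width * depth)


def tke_from_variances(var_u: float, var_v: float, var_w: float) -> float:
    """Turbulence kinetic energy: half the sum of velocity-component variances."""
    if var_u < 0 or var_v < 0 or var_w < 0:
        raise DomainError("velocity variances must be non-negative")
    return 0.5 * (var_u + var_v + var_w)


# ---------------------------------------------------------------------------
# Field container and sampling
# ---------------------------------------------------------------------------

@dataclass
class HydraulicSample:
    """Interpolated hydraulic state at one point."""

    u: float
    v: float
    w: float
    U_m: float
    gamma_m: float   # horizontal flow angle, atan2(v, u), rad
    beta_m: float    # vertical flow angle, rad
    tke: float       # J/kg
    a_mag: float     # |convective acceleration|, m/s^2
    alpha: float     # water fraction


@dataclass
class FlowField:
    """Steady hydraulic field on a 3D point cloud.

    ``grid_axes`` is set when the points form a structured rectilinear grid
    (the synthetic generator always produces one); gradients are then computed
    directly on the grid, otherwise the field is resampled first.
    """

    points: np.ndarray               # (N, 3)
    velocity: np.ndarray             # (N, 3)
    tke: np.ndarray                  # (N,)
    alpha: np.ndarray                # (N,)
    geometry: FlumeGeometry
    accel: Optional[np.ndarray] = None   # (N, 3)
    grid_axes: Optional[tuple] = None    # (xs, ys, zs)
    _tree: Optional[cKDTree] = dc_field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.velocity = np.atleast_2d(np.asarray(self.velocity, dtype=float))
        self.tke = np.asarray(self.tke, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.tke < 0):
            raise DomainError("TKE must be non-negative everywhere")
        if np.any((self.alpha < 0) | (self.alpha > 1)):
            raise DomainError("water fraction must lie in [0, 1]")

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _idw(field: FlowField, pts: np.ndarray, k: int = 8):
    """k-NN inverse-distance weights; exact on nodes.

    Returns (idx, weights) with weights rows summing to 1.
    """
    k = min(k, field.n_points)
    dist, idx = field.tree.query(pts, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(dist, 1e-300) ** 2
    on_node = dist[:, 0] < 1e-9
    if np.any(on_node):
        w[on_node] = 0.0
        w[on_node, 0] = 1.0
    w /= w.sum(axis=1, keepdims=True)
    return idx, w


def sample_many(field: FlowField, pts: np.ndarray, k: int = 8) -> dict:
    """Interpolate (u, v, w, tke, |a|, alpha) at many points at once.

    Points are assumed inside the wetted domain (the agent engine clamps
    sensory points to the walls before sampling).
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    idx, w = _idw(field, pts, k=k)
    uvw = np.einsum("nk,nkc->nc", w, field.velocity[idx])
    tke = np.einsum("nk,nk->n", w, field.tke[idx])
    alpha = np.einsum("nk,nk->n", w, field.alpha[idx])
    if field.accel is not None:
        amag = np.einsum(
            "nk,nk->n", w, np.linalg.norm(field.accel, axis=1)[idx])
    else:
        amag = np.zeros(pts.shape[0])
    return {
        "u": uvw[:, 0], "v": uvw[:, 1], "w": uvw[:, 2],
        "U_m": np.linalg.norm(uvw, axis=1),
        "tke": tke, "a_mag": amag, "alpha": alpha,
    }


def sample_at(field: FlowField, point: Sequence[float], k: int = 8) -> HydraulicSample:
    """Interpolate the hydraulic state at one point (IDW over k nearest nodes)."""
    p = np.asarray(point, dtype=float)
    if not field.geometry.contains(p):
        raise OutOfDomainError(f"point {p.tolist()} outside the wetted domain")
    s = sample_many(field, p[None, :], k=k)
    u, v, w = float(s["u"][0]), float(s["v"][0]), float(s["w"][0])
    return HydraulicSample(
        u=u, v=v, w=w,
        U_m=float(s["U_m"][0]),
        gamma_m=float(np.arctan2(v, u)),
        beta_m=float(np.arctan2(w, np.hypot(u, v))),
        tke=float(s["tke"][0]),
        a_mag=float(s["a_mag"][0]),
        alpha=float(s["alpha"][0]),
    )


# ---------------------------------------------------------------------------
# Field post-processing
# ---------------------------------------------------------------------------

def acceleration_field(field: FlowField) -> FlowField:
    """Fill the convective (spatial) acceleration a = (U^T grad U)^T.

    Computed with central finite differences on the structured grid (one-sided
    at the boundaries). An unstructured point cloud is first resampled onto a
    regular grid, differentiated there, and the result interpolated back to
    the original points.
    """
    if field.grid_axes is not None:
        xs, ys, zs = field.grid_axes
        shape = (len(xs), len(ys), len(zs))
        if any(n < 2 for n in shape):
            raise DomainError("need at least 2 points along every axis")
        a = _grid_acceleration(field.velocity.reshape(shape + (3,)), xs, ys, zs)
        field.accel = a.reshape(-1, 3)
        return field
    # resample onto an auto grid at the median nearest-neighbour spacing
    lo = field.points.min(axis=0)
    hi = field.points.max(axis=0)
    d, _ = field.tree.query(field.points, k=2)
    h = max(float(np.median(d[:, 1])), 1e-6)
    axes = []
    for i in range(3):
        n = max(2, int(np.round((hi[i] - lo[i]) / h)) + 1)
        axes.append(np.linspace(lo[i], hi[i], n))
    xs, ys, zs = axes
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    gpts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    s = sample_many(field, gpts)
    vel = np.column_stack([s["u"], s["v"], s["w"]])
    a = _grid_acceleration(
        vel.reshape(len(xs), len(ys), len(zs), 3), xs, ys, zs).reshape(-1, 3)
    gfield = FlowField(points=gpts, velocity=vel,
                       tke=np.zeros(len(gpts)), alpha=np.ones(len(gpts)),
                       geometry=field.geometry, accel=a)
    idx, w = _idw(gfield, field.points)
    field.accel = np.einsum("nk,nkc->nc", w, a[idx])
    return field


def _grid_acceleration(vel: np.ndarray, xs, ys, zs) -> np.ndarray:
    """Convective acceleration on a rectilinear grid, a_i = U_j dU_i/dx_j."""
    grads = []
    for c in range(3):
        gx, gy, gz = np.gradient(vel[..., c], xs, ys, zs, edge_order=1)
        grads.append((gx, gy, gz))
    a = np.empty_like(vel)
    u, v, w = vel[..., 0], vel[..., 1], vel[..., 2]
    for c in range(3):
        gx, gy, gz = grads[c]
        a[..., c] = u * gx + v * gy + w * gz
    return a


# ---------------------------------------------------------------------------
# Synthetic flume field (analytic stand-in for the CFD solve)
# ---------------------------------------------------------------------------

def synth_flume_field(
    geometry: FlumeGeometry,
    Q: float = 1.00,
    jet: bool = False,
    resolution: float = 0.15,
    seed: int = 0,
    bl_thickness: float = 0.05,
    jet_peak: float = 1.5,
    jet_width: float = 0.30,
    jet_decay_length: float = 3.2,
    lateral_asymmetry: float = 0.15,
    tke_base: float = 0.003,
) -> FlowField:
    """Generate an analytic steady flume field on a regular grid.

    The field emulates the qualitative structure of a solved flume flow:
    a streamwise plug flow with thin near-wall boundary layers (thickness
    ``bl_thickness``), a mild lateral asymmetry, and — when ``jet`` is set —
    a laterally offset high-velocity core issuing from the slot opening near
    the right wall (peak ``jet_peak`` m/s at the slot, decaying downstream
    over ``jet_decay_length``) with elevated TKE and acceleration on that
    side. Every cross-section is rescaled so its section-averaged streamwise
    velocity equals Q/(width*depth) exactly (continuity by construction).
    TKE is kept within the 0.001-0.1 J/kg range typical of such flumes.
    Identical arguments and seed produce identical fields.
    """
    g = geometry
    ub = bulk_velocity(Q, g.width, g.water_depth)
    nx = max(5, int(np.round(g.length / resolution)))
    ny = max(5, int(np.round(g.width / resolution)))
    nz = max(5, int(np.round(g.water_depth / resolution)))
    # cell centres: no node exactly on a wall, velocity decays towards walls
    xs = np.linspace(g.length / (2 * nx), g.length * (1 - 0.5 / nx), nx)
    ys = np.linspace(g.width / (2 * ny), g.width * (1 - 0.5 / ny), ny)
    zs = np.linspace(g.water_depth / (2 * nz),
                     g.water_depth * (1 - 0.5 / nz), nz)
    rng = np.random.default_rng(seed)

    def blayer(d):
        return 1.0 - np.exp(-np.maximum(d, 0.0) / bl_thickness)

    Y, Z = np.meshgrid(ys, zs, indexing="ij")           # (ny, nz)
    shape_yz = (blayer(Y) * blayer(g.width - Y) * blayer(Z)
                * (1.0 + lateral_asymmetry * (2 * Y / g.width - 1.0)))
    base = ub * shape_yz / shape_yz.mean()              # section mean = ub

    u = np.broadcast_to(base, (nx, ny, nz)).copy()
    if jet:
        y_jet = g.slot_opening / 2.0
        for i, x in enumerate(xs):
            if x < g.slot_x:
                continue
            s = x - g.slot_x
            # jet amplitude is the excess over bulk so the core velocity
            # stays near the configured peak after superposition
            amp = max(jet_peak * np.exp(-s / jet_decay_length) - ub, 0.0)
            sigma = jet_width * (1.0 + 0.15 * s)
            j = amp * np.exp(-0.5 * ((Y - y_jet) / sigma) ** 2) * blayer(Z)
            mj = j.mean()
            if mj >= 0.9 * ub:      # jet cannot carry more than the discharge
                j *= 0.9 * ub / mj
                mj = 0.9 * ub
            # background yields the flow share carried by the jet; slice mean
            # stays exactly ub while the jet core keeps its peak velocity
            u[i] = base * (ub - mj) / ub + j
    # smooth seeded modulation (2 %) that respects continuity per slice
    mod = 1.0 + 0.02 * np.sin(
        2 * np.pi * (np.add.outer(ys / g.width, zs / g.water_depth))
        + rng.uniform(0, 2 * np.pi))
    u *= mod[None, :, :]
    u *= ub / u.mean(axis=(1, 2), keepdims=True)

    # TKE: base level + wall-shear + jet-shear contributions, clipped to the
    # observed 0.001-0.1 J/kg range
    du_dy = np.gradient(u, ys, axis=1)
    tke = tke_base + 0.003 * np.abs(du_dy) / max(ub / bl_thickness * 0.05, 1e-9)
    wall_d = np.minimum(np.minimum(Y, g.width - Y), Z)
    tke = tke + 0.01 * np.exp(-wall_d / 0.08)[None, :, :]
    tke = np.clip(tke, 0.001, 0.1)

    X, Yg, Zg = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Yg.ravel(), Zg.ravel()])
    vel = np.zeros((pts.shape[0], 3))
    vel[:, 0] = u.ravel()
    field = FlowField(points=pts, velocity=vel, tke=tke.ravel(),
                      alpha=np.ones(pts.shape[0]), geometry=g,
                      grid_axes=(xs, ys, zs))
    return acceleration_field(field)


# ---------------------------------------------------------------------------
# Field tables
# ---------------------------------------------------------------------------

_CANONICAL_COLS = ("x", "y", "z", "u", "v", "w")
_OPTIONAL_COLS = ("tke", "alpha")


def read_field_table(path, column_map: Optional[Mapping[str, str]] = None,
                     geometry: Optional[FlumeGeometry] = None) -> FlowField:
    """Read a hydraulic field from a CSV point table.

    Requires columns x, y, z, u, v, w (SI units); tke and alpha are optional
    (defaults 0 and 1). ``column_map`` maps canonical names to the file's
    header names, e.g. ``{"u": "Vx"}``. Without an explicit geometry, flume
    extents are inferred from the point-cloud bounding box.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cmap = dict(column_map or {})
    cols = {}
    for name in _CANONICAL_COLS + _OPTIONAL_COLS:
        src = cmap.get(name, name)
        if src in df.columns:
            cols[name] = src
        elif name in _CANONICAL_COLS:
            raise FieldFormatError(
                f"field table {path} is missing required column '{src}'")
    data = {}
    for name, src in cols.items():
        vals = pd.to_numeric(df[src], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(np.isnan(vals) & ~df[src].isna().to_numpy())
        if bad.size:
            raise FieldFormatError(
                f"non-numeric value in column '{src}' at row {int(bad[0])}")
        data[name] = vals
    n = len(df)
    pts = np.column_stack([data["x"], data["y"], data["z"]])
    vel = np.column_stack([data["u"], data["v"], data["w"]])
    tke = data.get("tke", np.zeros(n))
    alpha = data.get("alpha", np.ones(n))
    if geometry is None:
        hi = pts.max(axis=0)
        geometry = FlumeGeometry(
            length=max(hi[0], 1e-3) or 1.0,
            width=max(hi[1], 1e-3),
            water_depth=max(hi[2], 1e-3),
            line_A_x=max(hi[0], 1e-3) * 0.75,
            line_D_x=max(hi[0], 1e-3) * 0.1,
            staging_extent=max(hi[0], 1e-3) * 0.15,
            dy=min(0.25, max(hi[1], 1e-3) / 4),
            dz=min(0.15, max(hi[2], 1e-3) / 4),
        )
    return FlowField(points=pts, velocity=vel, tke=tke, alpha=alpha,
                     geometry=geometry)


def write_field_table(field: FlowField, path) -> None:
    """Write a field as the canonical CSV dialect (x,y,z,u,v,w,tke,alpha)."""
    df = pd.DataFrame({
        "x": field.points[:, 0], "y": field.points[:, 1],
        "z": field.points[:, 2],
        "u": field.velocity[:, 0], "v": field.velocity[:, 1],
        "w": field.velocity[:, 2],
        "tke": field.tke, "alpha": field.alpha,
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Wall distances
# ---------------------------------------------------------------------------

def wall_distances(geometry: FlumeGeometry, x, y, bearing, cap: float = np.inf):
    """Ray-cast distances to solid boundaries for front/left/right directions.

    Vectorised over fish. ``bearing`` is the horizontal heading (rad, world
    frame). Solid boundaries are the two side walls, the upstream screen at
    x = 0, and — when present — the slot wall at ``slot_x`` (solid except for
    the opening adjacent to the right wall). The downstream end is open.
    Returns (front, left, right) arrays capped at ``cap``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    bearing = np.atleast_1d(np.asarray(bearing, dtype=float))
    out = []
    for rot in (0.0, np.pi / 2.0, -np.pi / 2.0):     # front, left, right
        ang = bearing + rot
        out.append(_ray_distance(geometry, x, y, np.cos(ang), np.sin(ang), cap))
    return tuple(out)


def _ray_distance(g: FlumeGeometry, x, y, dx, dy, cap):
    t = np.full_like(x, np.inf)

    def hit_plane_x(px, y_lo=None, y_hi=None):
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = (px - x) / dx
        ok = (np.abs(dx) > 1e-12) & (tt > 1e-9)
        if y_lo is not None:
            yy = y + tt * dy
            ok &= (yy >= y_lo) & (yy <= y_hi)
        return np.where(ok, tt, np.inf)

    def hit_plane_y(py):
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = (py - y) / dy
        ok = (np.abs(dy) > 1e-12) & (tt > 1e-9)
        xx = x + tt * dx
        ok &= (xx >= -1e-9) & (xx <= g.length + 1e-9)
        return np.where(ok, tt, np.inf)

    t = np.minimum(t, hit_plane_x(0.0))              # upstream screen
    t = np.minimum(t, hit_plane_y(0.0))              # left wall
    t = np.minimum(t, hit_plane_y(g.width))          # right wall
    if g.slot_present:
        t = np.minimum(
            t, hit_plane_x(g.slot_x, g.slot_opening, g.width))
    return np.minimum(t, cap)


def wall_distance(geometry: FlumeGeometry, point: Sequence[float],
                  bearing: float, side: str, cap: float = np.inf) -> float:
    """Distance from a point to the nearest solid boundary along one body-
    relative direction (``front``, ``left`` or ``right``), capped at ``cap``."""
    p = np.asarray(point, dtype=float)
    if not geometry.contains(p):
        raise OutOfDomainError(f"point {p.tolist()} outside the flume")
    f, l, r = wall_distances(geometry, p[0], p[1], bearing, cap=cap)
    return float({"front": f, "left": l, "right": r}[side][0])
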