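"""Movement patterns and the weighted-RMSE evaluation metric.

Observed or simulated fish tracks are condensed into five system-level
patterns used for pattern-oriented validation of the behavioral model:

* P1 — lateral occupancy: mean time share in a left / middle / right zone
  (wall zones 0.25 m wide);
* P2 — vertical occupancy: surface / middle / bottom (wall zones 0.15 m);
* P3 — turn locations: mean share of turns in three equal-length
  longitudinal zones of the experimental area, over fish with > 4 turns;
* P4 — percentage of few-/no-turning fish (<= 4 turns);
* P5 — arrival rate: fish crossing the upstream control line D as a
  percentage of fish that entered over the downstream control line A.

A turn is a change of longitudinal movement direction followed by a
displacement of at least two body lengths before the next direction change.
Zone occupancy uses Eq-style per-fish time fractions (piecewise-constant
position between records, each fraction normalised by that fish's track
duration) averaged over fish. Model and laboratory pattern sets are compared
with a weighted root-mean-square error: triple patterns contribute the RMS
of their three component differences, scalar patterns the absolute
difference, combined with weights (0.3, 0.1, 0.2, 0.2, 0.2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

DEFAULT_WEIGHTS = (0.3, 0.1, 0.2, 0.2, 0.2)


@dataclass
class Track:
    """Timestamped 3D positions of one fish."""

    fish_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    body_length: float = 0.27
    source: str = "observed"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("t, x, y, z must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("record times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def slice(self, mask) -> "Track":
        return Track(fish_id=self.fish_id, t=self.t[mask], x=self.x[mask],
                     y=self.y[mask], z=self.z[mask],
                     body_length=self.body_length, source=self.source)


@dataclass
class PatternSet:
    """The ten pattern values of one cohort, with cohort bookkeeping.

    Triples are (left, middle, right), (surface, middle, bottom) and
    (upstream, middle, downstream); all values are percentages. ``p3`` is
    None when the cohort contains no turning fish.
    """

    p1: tuple
    p2: tuple
    p3: Optional[tuple]
    p4: float
    p5: float
    p1_sd: Optional[tuple] = None
    p2_sd: Optional[tuple] = None
    p3_sd: Optional[tuple] = None
    n: int = 0
    n_turns: int = 0
    n_few_turns: int = 0
    n_D: int = 0

    def to_dict(self) -> dict:
        return {
            "p1": list(self.p1), "p2": list(self.p2),
            "p3": None if self.p3 is None else list(self.p3),
            "p4": self.p4, "p5": self.p5,
            "n": self.n, "n_turns": self.n_turns,
            "n_few_turns": self.n_few_turns, "n_D": self.n_D,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatternSet":
        return cls(p1=tuple(d["p1"]), p2=tuple(d["p2"]),
                   p3=None if d.get("p3") is None else tuple(d["p3"]),
                   p4=float(d["p4"]), p5=float(d["p5"]),
                   n=int(d.get("n", 0)), n_turns=int(d.get("n_turns", 0)),
                   n_few_turns=int(d.get("n_few_turns", 0)),
                   n_D=int(d.get("n_D", 0)))


# Laboratory reference pattern values for the two flume setups (jet / no
# jet), used as the calibration target of the behavioral model.
LAB_SETUP1 = PatternSet(
    p1=(33.0, 10.0, 57.0), p1_sd=(37.0, 12.0, 38.0),
    p2=(1.0, 1.0, 99.0), p2_sd=(2.0, 2.0, 3.0),
    p3=(24.0, 29.0, 47.0), p3_sd=(19.0, 17.0, 16.0),
    p4=60.0, p5=84.0, n=25, n_turns=9, n_few_turns=15, n_D=21)
LAB_SETUP2 = PatternSet(
    p1=(38.0, 6.0, 56.0), p1_sd=(39.0, 10.0, 40.0),
    p2=(4.0, 0.0, 96.0), p2_sd=(17.0, 1.0, 17.0),
    p3=(27.0, 40.0, 33.0), p3_sd=(17.0, 16.0, 26.0),
    p4=50.0, p5=79.0, n=24, n_turns=12, n_few_turns=12, n_D=19)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def first_crossing_index(track: Track, line_x: float) -> Optional[int]:
    """Index of the first record at or upstream of a control line."""
    hits = np.flatnonzero(track.x <= line_x)
    return int(hits[0]) if hits.size else None


def filter_valid_tracks(tracks: Sequence[Track], geometry,
                        window_A: float = 1800.0,
                        cap: float = 3600.0) -> list:
    """Apply the validity filters to a cohort of tracks.

    Fish that never cross the downstream control line A within ``window_A``
    seconds of their release are dropped. Records after a fish's line-D
    crossing are excluded (the crossing record is kept), and the trial is
    capped ``cap`` seconds after the cohort's first line-A crossing.
    """
    crossings = {}
    for tr in tracks:
        i = first_crossing_index(tr, geometry.line_A_x)
        if i is not None and tr.t[i] - tr.t[0] <= window_A:
            crossings[tr.fish_id] = tr.t[i]
    if not crossings:
        return []
    t_stop = min(crossings.values()) + cap
    out = []
    for tr in tracks:
        if tr.fish_id not in crossings:
            continue
        tr = tr.slice(tr.t <= t_stop)
        iD = first_crossing_index(tr, geometry.line_D_x)
        if iD is not None:
            tr = tr.slice(np.arange(len(tr)) <= iD)
        if len(tr):
            out.append(tr)
    return out


# ---------------------------------------------------------------------------
# Zone occupancy (Eq-1 style time fractions)
# ---------------------------------------------------------------------------

def lateral_zone(y: np.ndarray, geometry) -> np.ndarray:
    """0 = left (y >= width - dy), 1 = middle, 2 = right (y <= dy).

    Facing downstream the left wall is at y = width. Boundaries belong to the
    wall-side zone.
    """
    y = np.asarray(y, dtype=float)
    return np.where(y >= geometry.width - geometry.dy, 0,
                    np.where(y <= geometry.dy, 2, 1))


def vertical_zone(z: np.ndarray, geometry) -> np.ndarray:
    """0 = surface, 1 = middle, 2 = bottom; boundaries to the wall side."""
    z = np.asarray(z, dtype=float)
    return np.where(z >= geometry.water_depth - geometry.dz, 0,
                    np.where(z <= geometry.dz, 2, 1))


def _per_fish_fractions(track: Track, zone_of) -> Optional[np.ndarray]:
    if len(track) < 2 or track.duration <= 0:
        warnings.warn(f"fish {track.fish_id}: zero-duration track excluded "
                      "from zone occupancy")
        return None
    dt = np.diff(track.t)
    zones = zone_of(track)[:-1]          # position held until the next record
    frac = np.zeros(3)
    for k in range(3):
        frac[k] = dt[zones == k].sum()
    return frac / track.duration


def zone_fractions(tracks: Sequence[Track], zone_of) -> tuple:
    """Cohort mean and SD (in %) of per-fish time fractions over 3 zones.

    Per fish, the time spent in each zone (position held piecewise-constant
    between records) is divided by that fish's track duration; fractions are
    then averaged over fish.
    """
    rows = [f for tr in tracks
            if (f := _per_fish_fractions(tr, zone_of)) is not None]
    if not rows:
        raise ValueError("no usable tracks for zone occupancy")
    arr = 100.0 * np.asarray(rows)
    sd = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(3)
    return tuple(arr.mean(axis=0)), tuple(sd)


def lateral_fractions(tracks, geometry):
    """Pattern P1: (left, middle, right) mean and SD percentages."""
    return zone_fractions(tracks, lambda tr: lateral_zone(tr.y, geometry))


def vertical_fractions(tracks, geometry):
    """Pattern P2: (surface, middle, bottom) mean and SD percentages."""
    return zone_fractions(tracks, lambda tr: vertical_zone(tr.z, geometry))


# ---------------------------------------------------------------------------
# Turns
# ---------------------------------------------------------------------------

def detect_turns(track: Track, min_excursion_bl: float = 2.0) -> np.ndarray:
    """x positions of turns: direction changes of longitudinal movement whose
    following excursion reaches at least ``min_excursion_bl`` body lengths
    before the next direction change."""
    x = track.x
    thresh = min_excursion_bl * track.body_length
    nz = np.flatnonzero(np.diff(x) != 0.0)   # indices of nonzero moves
    if nz.size < 2:
        return np.empty(0)
    moves = x[nz + 1] - x[nz]
    signs = np.sign(moves)
    run_starts = np.concatenate(
        [[0], np.flatnonzero(np.diff(signs) != 0) + 1])
    run_disp = np.add.reduceat(moves, run_starts)
    turns = [x[nz[run_starts[j]]]
             for j in range(1, len(run_starts))
             if np.abs(run_disp[j]) >= thresh]
    return np.asarray(turns)


def longitudinal_turn_zone(x: np.ndarray, geometry) -> np.ndarray:
    """0 = upstream, 1 = middle, 2 = downstream third of the experimental
    area (between lines D and A); turns outside are clipped into it."""
    lo, hi = geometry.line_D_x, geometry.line_A_x
    xx = np.clip(np.asarray(x, dtype=float), lo, hi - 1e-9)
    return np.minimum(2, ((xx - lo) / ((hi - lo) / 3.0)).astype(int))


def turn_patterns(tracks: Sequence[Track], geometry,
                  few_turn_max: int = 4) -> tuple:
    """Patterns P3 and P4.

    Fish are split into turning (> ``few_turn_max`` turns) and few-/no-
    turning fish. P3 averages, over turning fish, each fish's share of turns
    in three equal-length longitudinal zones; P4 is the percentage of
    few-turning fish. Returns (p3, p3_sd, p4, n_turning, n_few); ``p3`` is
    None (flagged) when no fish turns more than ``few_turn_max`` times.
    """
    n = len(tracks)
    if n == 0:
        raise ValueError("empty cohort")
    shares = []
    n_few = 0
    for tr in tracks:
        tx = detect_turns(tr)
        if tx.size > few_turn_max:
            zones = longitudinal_turn_zone(tx, geometry)
            s = np.bincount(zones, minlength=3) / tx.size
            shares.append(s)
        else:
            n_few += 1
    p4 = 100.0 * n_few / n
    if not shares:
        return None, None, p4, 0, n_few
    arr = 100.0 * np.asarray(shares)
    sd = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(3)
    return tuple(arr.mean(axis=0)), tuple(sd), p4, len(shares), n_few


def arrival_rate(tracks: Sequence[Track], geometry) -> tuple:
    """Pattern P5: percentage of (valid) fish that crossed line D."""
    n = len(tracks)
    if n == 0:
        raise ValueError("empty cohort")
    n_D = sum(1 for tr in tracks
              if first_crossing_index(tr, geometry.line_D_x) is not None)
    return 100.0 * n_D / n, n_D


def start_distribution(tracks: Sequence[Track], geometry) -> tuple:
    """(left, middle, right) percentages of the tracks' first records."""
    zones = np.array([lateral_zone(tr.y[:1], geometry)[0] for tr in tracks])
    n = len(zones)
    if n == 0:
        raise ValueError("empty cohort")
    return tuple(100.0 * np.bincount(zones, minlength=3) / n)


def alone_fraction(tracks: Sequence[Track], radius: float = 0.5,
                   dt: float = 0.5) -> float:
    """Descriptive statistic: mean fraction of track time a fish spends with
    no other fish within ``radius`` (positions held between records)."""
    if len(tracks) < 2:
        return 100.0
    t_lo = min(tr.t[0] for tr in tracks)
    t_hi = max(tr.t[-1] for tr in tracks)
    grid = np.arange(t_lo, t_hi + dt, dt)
    P = np.full((len(tracks), grid.size, 3), np.nan)
    for i, tr in enumerate(tracks):
        idx = np.searchsorted(tr.t, grid, side="right") - 1
        ok = (idx >= 0) & (grid <= tr.t[-1])
        P[i, ok] = np.column_stack([tr.x[idx[ok]], tr.y[idx[ok]],
                                    tr.z[idx[ok]]])
    fracs = []
    for i in range(len(tracks)):
        valid = ~np.isnan(P[i, :, 0])
        if not valid.any():
            continue
        d = np.linalg.norm(P[:, valid] - P[i, valid][None], axis=2)
        d[i] = np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            near = np.nanmin(d, axis=0) < radius
        fracs.append(100.0 * (1.0 - near.mean()))
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# Pattern sets and the evaluation metric
# ---------------------------------------------------------------------------

def compute_patterns(tracks: Sequence[Track], geometry) -> PatternSet:
    """All five patterns of a (already filtered) cohort."""
    p1, p1_sd = lateral_fractions(tracks, geometry)
    p2, p2_sd = vertical_fractions(tracks, geometry)
    p3, p3_sd, p4, n_turning, n_few = turn_patterns(tracks, geometry)
    p5, n_D = arrival_rate(tracks, geometry)
    return PatternSet(p1=p1, p2=p2, p3=p3, p4=p4, p5=p5,
                      p1_sd=p1_sd, p2_sd=p2_sd, p3_sd=p3_sd,
                      n=len(tracks), n_turns=n_turning,
                      n_few_turns=n_few, n_D=n_D)


def weighted_rmse(model: PatternSet, lab: PatternSet,
                  weights: Sequence[float] = DEFAULT_WEIGHTS,
                  incomplete: str = "raise") -> float:
    """Weighted RMSE between model and laboratory pattern means.

    Triple patterns (P1-P3) contribute the root of the mean squared
    component difference, scalar patterns (P4-P5) the absolute difference;
    contributions are combined linearly with ``weights``. With
    ``incomplete="drop"`` an undefined P3 on either side is dropped and the
    remaining weights renormalised to sum to the original total.
    """
    if len(weights) != 5:
        raise ValueError("need five pattern weights")
    terms = {}
    for key, a in zip(("p1", "p2", "p3"), weights[:3]):
        m, l = getattr(model, key), getattr(lab, key)
        if m is None or l is None:
            if incomplete == "drop":
                continue
            raise ValueError(f"pattern {key} undefined; cannot compute RMSE")
        m, l = np.asarray(m, float), np.asarray(l, float)
        if m.shape != (3,) or l.shape != (3,):
            raise ValueError(f"pattern {key} must have three components")
        terms[key] = (a, float(np.sqrt(np.mean((m - l) ** 2))))
    for key, a in zip(("p4", "p5"), weights[3:]):
        terms[key] = (a, abs(float(getattr(model, key))
                             - float(getattr(lab, key))))
    total_w = sum(a for a, _ in terms.values())
    scale = sum(weights) / total_w if total_w > 0 else 1.0
    return scale * sum(a * d for a, d in terms.values())
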