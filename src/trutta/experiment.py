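"""Experiment harness: parameter-space sampling, seed replication, Morris
elementary-effects screening, and stimulus-version ranking.

The parameter space discretises each variable model parameter to ``p``
equally spaced levels around its default. It is sampled with the revised
Morris method: many random one-step-at-a-time trajectories are generated on
the level grid and a maximally dispersed subset is selected (greedy
max-dispersion, since the exact combinatorial selection is infeasible),
yielding (D+1)*T parameter sets per T selected trajectories. Elementary
effects of the model error (weighted RMSE) along those trajectories give the
influence measure mu* (mean absolute effect) and the interaction measure
sigma_M (SD of signed effects) per parameter, normalised by their maxima and
classed high/middle/low.

Stimulus versions are ranked by the 10th percentile of their RMSE samples;
significance of pairwise differences against the best version is assessed
with a Kruskal-Wallis group test and post-hoc Nemenyi tests on the values
below the percentile, and versions are rated good/moderate/poor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .behavior import ParameterSet

#: random-seed replication list used throughout the study protocol
DEFAULT_SEEDS = (656, 36, 849, 934, 679, 758, 743, 392, 655, 171)


# ---------------------------------------------------------------------------
# Parameter space
# ---------------------------------------------------------------------------

@dataclass
class ParameterSpace:
    """Discrete level grid per parameter, with optional frozen parameters.

    ``levels`` maps each parameter name to its strictly increasing level
    values (all the same length p >= 2). Frozen parameters keep a fixed
    value and are excluded from sampling.
    """

    levels: dict
    frozen: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, lv in self.levels.items():
            lv = np.asarray(lv, dtype=float)
            if lv.size < 2 or np.any(np.diff(lv) <= 0):
                raise ValueError(
                    f"levels of '{name}' must be >= 2 strictly ordered values")
            self.levels[name] = lv
        ps = {lv.size for lv in self.levels.values()}
        if len(ps) != 1:
            raise ValueError("all parameters must share the same level count")

    @property
    def names(self) -> list:
        return list(self.levels)

    @property
    def D(self) -> int:
        return len(self.levels)

    @property
    def p(self) -> int:
        return next(iter(self.levels.values())).size

    def freeze(self, name: str, value: Optional[float] = None) -> "ParameterSpace":
        """Return a copy with one parameter removed from sampling."""
        if name not in self.levels:
            raise KeyError(name)
        lv = dict(self.levels)
        levels = lv.pop(name)
        frozen = dict(self.frozen)
        frozen[name] = float(levels[len(levels) // 2] if value is None
                             else value)
        return ParameterSpace(levels=lv, frozen=frozen)

    @classmethod
    def default(cls, params: Optional[ParameterSet] = None, p: int = 6,
                rel_step: float = 0.2, default_level: int = 2) -> "ParameterSpace":
        """Level grid around the behavioral-model defaults: p equally spaced
        values with spacing ``rel_step`` times the default, the default value
        sitting at the (default_level+1)-th place."""
        params = params or ParameterSet()
        levels = {}
        for name in ParameterSet.names():
            d = getattr(params, name)
            step = rel_step * d
            lv = d + step * (np.arange(p) - default_level)
            levels[name] = lv
        return cls(levels=levels)


# ---------------------------------------------------------------------------
# Revised Morris sampling
# ---------------------------------------------------------------------------

def _random_trajectory(D: int, p: int, rng) -> np.ndarray:
    """One Morris trajectory on the normalised level grid: (D+1, D) points in
    {0, 1/(p-1), ..., 1}, consecutive points differing in one coordinate by
    the step delta = p / (2 (p - 1))."""
    grid = np.arange(p) / (p - 1)
    delta = p / (2.0 * (p - 1))
    lo = grid[grid <= 1.0 - delta + 1e-12]
    x = rng.choice(lo, size=D) if lo.size else np.zeros(D)
    # random starting orthant: start high for a random half of the moves
    up = rng.random(D) < 0.5
    x = np.where(up, x, x + delta)
    pts = np.empty((D + 1, D))
    pts[0] = x
    order = rng.permutation(D)
    for k, dim in enumerate(order):
        x = x.copy()
        x[dim] += delta if up[dim] else -delta
        pts[k + 1] = x
    return np.clip(pts, 0.0, 1.0)


def _trajectory_distances(trajs: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Campolongo spread: d(m, l) = sum over point pairs of their Euclidean
    distance. Vectorised in chunks to bound memory."""
    r, npts, D = trajs.shape
    flat = trajs.reshape(r * npts, D)
    dmat = np.zeros((r, r))
    for a in range(0, r, chunk):
        b = min(a + chunk, r)
        block = cdist(flat[a * npts:b * npts], flat)   # (nb*npts, r*npts)
        block = block.reshape(b - a, npts, r, npts).sum(axis=(1, 3))
        dmat[a:b] = block
    np.fill_diagonal(dmat, 0.0)
    return dmat


def _select_spread(dmat: np.ndarray, T: int) -> np.ndarray:
    """Greedy max-dispersion subset: seed with the farthest pair, then add
    the trajectory maximising the summed squared distance to the selection."""
    r = dmat.shape[0]
    if T >= r:
        return np.arange(r)
    d2 = dmat ** 2
    sel = list(np.unravel_index(np.argmax(d2), d2.shape))
    rest = set(range(r)) - set(sel)
    score = d2[sel].sum(axis=0)
    while len(sel) < T:
        cand = max(rest, key=lambda j: (score[j], -j))
        sel.append(cand)
        rest.remove(cand)
        score = score + d2[cand]
    return np.asarray(sorted(sel))


def morris_sample(space: ParameterSpace, r: int = 1000, T: int = 50,
                  seed: int = 0) -> list:
    """Generate (D+1)*T parameter sets via the revised Morris method.

    ``r`` random trajectories are drawn on the level grid and the ``T`` most
    dispersed are kept (greedy heuristic) and flattened; consecutive sets
    within a trajectory differ in exactly one parameter by one grid jump.
    Returns a list of dicts mapping parameter names to values (frozen
    parameters included at their fixed value).
    """
    if not (r >= T >= 1):
        raise ValueError("need r >= T >= 1")
    rng = np.random.default_rng(seed)
    D, p = space.D, space.p
    trajs = np.stack([_random_trajectory(D, p, rng) for _ in range(r)])
    keep = _select_spread(_trajectory_distances(trajs), T)
    names = space.names
    level_arr = np.stack([space.levels[n] for n in names])   # (D, p)
    sets = []
    for ti in keep:
        for pt in trajs[ti]:
            idx = np.rint(pt * (p - 1)).astype(int)
            values = {n: float(level_arr[i, idx[i]])
                      for i, n in enumerate(names)}
            values.update(space.frozen)
            sets.append(values)
    return sets


def drop_parameter_sets(sets: Sequence[Mapping], space: ParameterSpace,
                        name: str) -> list:
    """Remove, per trajectory, the step that varies one parameter (used when
    a stimulus version does not need it); the set count shrinks by T."""
    D = space.D
    block = D + 1
    out = []
    for start in range(0, len(sets), block):
        traj = list(sets[start:start + block])
        kept = [traj[0]]
        for prev, cur in zip(traj, traj[1:]):
            changed = [n for n in space.names if prev[n] != cur[n]]
            if changed == [name]:
                continue
            kept.append(cur)
        out.extend(kept)
    return out


# ---------------------------------------------------------------------------
# Seed replication
# ---------------------------------------------------------------------------

@dataclass
class SeedReplicate:
    """Mean RMSE over replicate seeds with its coefficient of variation."""

    mean: float
    cv: float
    values: np.ndarray


def seed_replicate(run: Callable[[Mapping, int], float], params: Mapping,
                   seeds: Sequence[int] = DEFAULT_SEEDS) -> SeedReplicate:
    """Evaluate ``run(params, seed)`` for every replicate seed and average."""
    vals = np.array([float(run(params, s)) for s in seeds])
    mean = float(vals.mean())
    cv = float(vals.std(ddof=0) / mean) if mean != 0 else 0.0
    return SeedReplicate(mean=mean, cv=cv, values=vals)


# ---------------------------------------------------------------------------
# Elementary-effects screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    """Per-parameter influence (mu*) and interaction (sigma_M) measures."""

    table: pd.DataFrame      # index: parameter; mu_star, sigma_M, normalised,
                             # rank, influence class

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


def elementary_effects(sets: Sequence[Mapping], rmse_values: Sequence[float],
                       space: ParameterSpace,
                       high: float = 0.6, low: float = 0.1) -> ScreeningResult:
    """Morris screening of RMSE values aligned to the trajectory structure.

    For every one-parameter step within a trajectory the elementary effect is
    the RMSE difference divided by the step size on the normalised [0, 1]
    scale of that parameter. mu* is the mean absolute effect, sigma_M the
    sample SD of signed effects; both are normalised by their maxima and
    classed high (mu*_norm > ``high``), low (<= ``low``) or middle.
    Trajectories whose steps cannot be paired to single-parameter changes
    are skipped with a warning.
    """
    y = np.asarray(rmse_values, dtype=float)
    if len(sets) != y.size:
        raise ValueError("rmse_values must align with the parameter sets")
    D = space.D
    block = D + 1
    span = {n: space.levels[n][-1] - space.levels[n][0] for n in space.names}
    effects = {n: [] for n in space.names}
    for start in range(0, len(sets), block):
        traj = sets[start:start + block]
        if len(traj) < 2:
            continue
        steps = []
        ok = True
        for k, (prev, cur) in enumerate(zip(traj, traj[1:])):
            changed = [n for n in space.names if prev[n] != cur[n]]
            if len(changed) != 1:
                ok = False
                break
            n = changed[0]
            dnorm = (cur[n] - prev[n]) / span[n]
            steps.append((n, (y[start + k + 1] - y[start + k]) / dnorm))
        if not ok:
            warnings.warn(f"trajectory at set {start} is not a valid Morris "
                          "trajectory; skipped")
            continue
        for n, ee in steps:
            effects[n].append(ee)
    mu_star = np.array([np.mean(np.abs(effects[n])) if effects[n] else 0.0
                        for n in space.names])
    sigma = np.array([np.std(effects[n], ddof=1) if len(effects[n]) > 1
                      else 0.0 for n in space.names])
    mu_max = mu_star.max() if mu_star.max() > 0 else 1.0
    s_max = sigma.max() if sigma.max() > 0 else 1.0
    mu_n = mu_star / mu_max
    s_n = sigma / s_max
    order = np.argsort(-mu_star, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    cls = np.where(mu_n > high, "high", np.where(mu_n <= low, "low", "middle"))
    table = pd.DataFrame({
        "mu_star": mu_star, "sigma_M": sigma,
        "mu_star_norm": mu_n, "sigma_M_norm": s_n,
        "rank": rank, "influence": cls,
    }, index=pd.Index(space.names, name="parameter"))
    return ScreeningResult(table=table)


# ---------------------------------------------------------------------------
# Version ranking
# ---------------------------------------------------------------------------

def nemenyi_pairwise(samples: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Post-hoc Nemenyi test p-values for all pairs of groups.

    Rank-based: groups are ranked jointly (with tie correction) and the
    studentized-range distribution gives two-sided p-values for the pairwise
    differences of mean ranks.
    """
    names = list(samples)
    groups = [np.asarray(samples[n], dtype=float) for n in names]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    allv = np.concatenate(groups)
    N = allv.size
    ranks = stats.rankdata(allv)
    sizes = np.array([g.size for g in groups])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rmeans = np.array([ranks[bounds[i]:bounds[i + 1]].mean()
                       for i in range(k)])
    _, tie_counts = np.unique(allv, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (N - 1))
    out = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i]
                                                     + 1.0 / sizes[j])
            q = abs(rmeans[i] - rmeans[j]) / np.sqrt(var) * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, np.inf))
            out.iat[i, j] = out.iat[j, i] = min(1.0, p)
    return out


def rate_version(q10: float, best_q10: float, p_value: Optional[float],
                 alpha: float = 0.01, rule: str = "absolute",
                 poor_threshold: float = 25.0,
                 gap_threshold: float = 5.0) -> str:
    """Qualitative rating of one version against the best version.

    The best version (p_value None) and versions not significantly different
    from it are "good". Significantly different versions are "moderate" or
    "poor" depending on the configured percentile rule: ``absolute`` rates
    poor when the 10th percentile reaches ``poor_threshold`` RMSE units,
    ``gap`` when it exceeds the best version's by more than ``gap_threshold``.
    """
    if p_value is None or p_value >= alpha:
        return "good"
    if rule == "absolute":
        return "poor" if q10 >= poor_threshold else "moderate"
    if rule == "gap":
        return "poor" if q10 - best_q10 > gap_threshold else "moderate"
    raise ValueError(f"unknown rating rule '{rule}'")


@dataclass
class VersionRanking:
    """Stimulus versions ranked by RMSE percentile with significance tests."""

    table: pd.DataFrame        # index: version; q10, p_value, rating, rank
    kruskal_p: float
    percentile_q: float

    @property
    def best(self) -> str:
        return self.table.index[0]

    def to_dict(self) -> dict:
        return {"kruskal_p": self.kruskal_p,
                "percentile_q": self.percentile_q,
                "versions": self.table.reset_index().to_dict("records")}


def rank_versions(rmse_by_version: Mapping[str, Sequence[float]],
                  alpha: float = 0.01, percentile_q: float = 10.0,
                  rating_rule: str = "absolute",
                  poor_threshold: float = 25.0,
                  gap_threshold: float = 5.0,
                  min_tail: int = 5) -> VersionRanking:
    """Rank stimulus versions by the q-th percentile of their RMSE samples.

    Only values strictly below each version's percentile enter the
    statistical comparison (they represent the attainable optimum; the bulk
    of the sample stems from deliberately spread-out parameter sets). A
    Kruskal-Wallis test across versions is followed by post-hoc Nemenyi
    tests of each version against the best one, and versions are rated
    good/moderate/poor (see :func:`rate_version`). Results do not depend on
    the input ordering of versions.
    """
    if len(rmse_by_version) < 2:
        raise ValueError("need at least two versions to rank")
    names = sorted(rmse_by_version)
    q10 = {}
    tails = {}
    for n in names:
        v = np.asarray(rmse_by_version[n], dtype=float)
        if v.size == 0:
            raise ValueError(f"empty RMSE sample for version '{n}'")
        q10[n] = float(np.percentile(v, percentile_q))
        tails[n] = v[v < q10[n]]
        if tails[n].size < min_tail:
            raise ValueError(
                f"version '{n}' has fewer than {min_tail} sub-percentile "
                "values; enlarge the sample")
    order = sorted(names, key=lambda n: (q10[n], n))
    best = order[0]
    kw_p = float(stats.kruskal(*[tails[n] for n in order]).pvalue)
    nem = nemenyi_pairwise({n: tails[n] for n in order})
    rows = []
    for rk, n in enumerate(order, start=1):
        p = None if n == best else float(nem.loc[best, n])
        rows.append({
            "version": n, "rank": rk, "q10": q10[n],
            "n_tail": int(tails[n].size), "p_value": p,
            "rating": rate_version(q10[n], q10[best], p, alpha=alpha,
                                   rule=rating_rule,
                                   poor_threshold=poor_threshold,
                                   gap_threshold=gap_threshold),
        })
    table = pd.DataFrame(rows).set_index("version")
    return VersionRanking(table=table, kruskal_p=kw_p,
                          percentile_q=percentile_q)
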