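# Model and methods

## Scope and coordinates

The package simulates upstream-orienting brown trout in a rectangular
indoor flume (16.38 m × 2.50 m, water depth 0.60 m, discharge 1.00 m³/s,
bulk velocity Q/(w·d) ≈ 0.67 m/s). `x` increases in flow direction with the
origin at the upstream screen, so migrating fish decrease `x`; `z = 0` is
the bottom. Facing downstream, body-left points to +y, so the left wall is
at y = width and the right wall (the slot side in setup 1) at y = 0. Two
control lines cross the flume: line A (x = 11.75 m) marks the entry of the
experimental area from the downstream staging area and line D (x = 1.50 m)
the upstream target. In setup 1 a solid wall at x = 2.0 m blocks the
cross-section except for a 0.35 m opening at the right wall; its jet is the
dominant hydraulic feature. Setup 2 has no slot.

## Synthetic hydraulic fields

The generator replaces a CFD solve and emulates only the features the
behavioral model consumes:

* streamwise plug flow shaped by thin exponential boundary layers
  (default thickness 0.05 m) at both walls and the bottom — wall influence
  in the real flume was likewise limited to a few centimetres;
* a mild lateral asymmetry (±15 % linear tilt, right side slower without
  the jet);
* with the slot: a Gaussian jet core at the opening (width 0.30 m,
  spreading downstream) whose centreline velocity starts at the configured
  peak (default 1.5 m/s) and decays over 3.2 m; the jet's excess discharge
  is removed from the background so that **every cross-section averages to
  the bulk velocity exactly** (continuity by construction);
* TKE built from a base level, a near-wall term and a jet-shear term,
  clipped to the observed 0.001–0.1 J/kg range; the water fraction is 1
  everywhere below the fixed water level;
* convective acceleration a = (Uᵀ∇U)ᵀ computed by central finite
  differences on the grid (one-sided at boundaries).

Cross-stream velocity components are zero: the stand-in carries lateral
structure in magnitudes, not in secondary currents, so behaviors that react
to v/w (none of the implemented rules do beyond flow opposition) are not
exercised. A 2 % smooth seeded modulation adds texture without breaking
per-slice continuity. Fields are stored as point clouds; queries use
inverse-distance weighting over the k = 8 nearest nodes (exact on nodes,
convex between them), which is adequate at behavioral-data accuracy and
independent of any mesh format.

## Agent model

Perception: a sensory ovoid of 7 points (center; front/back at ±0.5 BL,
lateral at ±0.15 BL, vertical at ±0.1 BL, aligned with the heading) sampled
from the field, plus ray-cast wall distances front/left/right capped at the
wall detection range. Solid boundaries are the side walls, the upstream
screen, and the slot wall when present; the downstream end is open.

Internal states (per time step Δt = 0.5 s):

* Motivation M grows linearly by Δt/k_M while the fish makes no upstream
  progress (k_M = 20 s for "fast", 130 s for "slow" fish — saturation after
  exactly those times) and relaxes exponentially toward its resting value
  while progressing. Progress is tracked by a spot memory (best upstream x
  reached, slowly forgetting via the spot memory coefficient) and a stuck
  time threshold: a fish counts as progressing until it has failed to
  improve its best x for that long.
* Fatigue F is an exponentially weighted average of the instantaneous load
  min(1, U_rel/k_F) with separate rising/falling coefficients, where
  U_rel = U_m/BL + |swim| combines local flow velocity and swim speed and
  k_F = 25 BL/s is the burst speed. Coupling the load to the flow (not only
  to the swim speed) is what lets fatigue overtake motivation in fast water
  and trigger drifting; with a flow-independent load the drifting rule
  would be unreachable under the constant migrating swim speed.
* Rule selection is a symmetric dead band on M̄ − F: migrating above the
  holding extent h, drifting below −h, holding inside.

Steering: the migrating base direction opposes the interpolated flow at the
center (positive rheotaxis); a uniform random angle up to the migrating max
random angle is added toward a random side. The stimulus versions add their
side steer on top — velocity/acceleration use the default swim angle gated
by a relative side-difference threshold, the TKE version steers toward the
front/left/right point closest in TKE to the center, and the wall-distance
version adds its (half-sized) angle toward the nearer wall. Exact ties are
broken by a fair coin from the fish's own random stream. An independent
vertical rule pitches the fish back by the vertical correction angle once
it strays more than the elevation threshold from the preferred near-bottom
height (0.07 m). Holding opposes the full 3D flow vector (capped at burst
speed, beyond which holding fails); drifting is passive transport with the
straight-drift probability, otherwise a counter-swim at half the flow speed
with a bounded random deviation.

Kinematics: new position = old + (swim·BL + flow)·Δt. Wall crossings are
reflected back inside (preserving heading) to avoid wall-sticking artifacts
in P1; crossing line D freezes the fish as arrived, leaving the flume
downstream freezes it as exited.

Reproducibility: one `SeedSequence` per run spawns an independent substream
per fish; every active fish draws a fixed four uniforms per step, so a
fish's trajectory depends only on the run seed and its index, and identical
seeds give bit-identical runs. The cohort engine is vectorised over fish;
the per-operation scalar functions delegate to the same kernels.

## Default parameters

The 20 variable parameters carry defaults chosen once for plausible trout
behavior in this flume (units: rad for angles, s for times, BL/s for
speeds): motivation initial value 0.12, motivation memory 0.05, k_M
20/130 s, spot memory 0.01, fatigue memories 0.1 (rising) / 0.02 (falling),
k_F 25 BL/s, holding extent 0.05, straight-drift probability 0.5, vertical
threshold 0.10 m and correction angle 0.3, stuck time threshold 30 s, max
random angle 0.5, wall detection range 1.0 m, wall-distance angle 0.175
(half the 0.35 default swim angle of the other stimulus versions),
stimulus threshold factor 0.1, initialisation fractions 0.33 (left share)
and 0.5/0.5 (slow shares). The internal-state values were calibrated by a
coarse scan on the synthetic fields until the migrate–hold–drift cycle is
alive: fish mostly migrate, hold briefly at the balance edge, and drift
downstream ≥ 2 BL often enough to produce a non-degenerate turning split
(P4 ≈ 60 % in setup 1) while most of the cohort stays valid. Fixed model
configuration (not part of the screened space): BL = 0.27 m, Δt = 0.5 s,
migrating swim speed 4.5 BL/s (a sustained-speed literature value for
rheophilic species), drift counter-swim fraction 0.5.

## Patterns and evaluation

Track filtering mirrors the laboratory protocol: fish that never cross
line A within 30 min of release are dropped, records after the line-D
crossing are discarded, and the trial is capped 60 min after the cohort's
first line-A crossing (interpreted per cohort, as a batch). Zone occupancy
holds positions piecewise-constant between records, normalises each fish's
zone times by its own track duration, and averages over fish; boundaries
belong to the wall-side zone. Turns are direction changes of longitudinal
movement followed by an excursion of ≥ 2 BL before the next change; fish
with > 4 turns form the P3 cohort (turn shares over three equal-length
thirds of the experimental area, turns outside clipped in), the rest define
P4. P5 is the share of valid fish that reach line D. The weighted RMSE sums
a_i·ΔP_i with ΔP = RMS of the component differences (triples) or the
absolute difference (scalars); the default weights (0.3, 0.1, 0.2, 0.2,
0.2) sum to one, so a uniform offset of every component by c gives RMSE = c
exactly. SDs are reported but never enter the RMSE. When a cohort has no
turning fish P3 is undefined; the metric then either raises or (in harness
contexts) drops P3 and renormalises the weights.

## Experiment harness

The parameter space discretises each parameter to p = 6 levels spaced at
20 % of its default, with the default at the 3rd level. Revised Morris
sampling draws r random one-at-a-time trajectories on the normalised grid
(step δ = p/(2(p−1)) = 0.6) and keeps the T most dispersed by a greedy
max-dispersion heuristic seeded with the farthest pair — the exact
combinatorial subset selection is infeasible at r = 1000. Elementary
effects are RMSE differences per normalised step; μ* (mean |effect|) ranks
influence, σ_M (SD of signed effects) measures interaction; both are
normalised by their maxima with classes high (> 0.6) / low (≤ 0.1) /
middle. Seed replication averages RMSE over the fixed list
656, 36, 849, 934, 679, 758, 743, 392, 655, 171 and reports the coefficient
of variation.

Version ranking uses the 10th percentile of each version's RMSE sample
(the bulk of the sample reflects deliberately spread-out parameter sets and
is uninformative about the attainable optimum); values strictly below the
percentile enter a Kruskal–Wallis test and pairwise post-hoc Nemenyi tests
(rank-based, tie-corrected, studentized-range reference distribution)
against the best version. Ratings: the best version and versions not
significantly different from it (α = 0.01) are "good"; significantly worse
versions are "moderate" or "poor". The moderate/poor boundary is a
configurable heuristic with two modes: the default rates "poor" when the
10th percentile reaches 25 RMSE units, the alternative when the gap to the
best version exceeds 5 units.

## Problem sizes and limitations

Tests and the acceptance script run the simulator at desk scale: synthetic
fields at 0.15 m resolution (~9000 nodes), cohorts of 100 fish for up to
60 simulated minutes, and replicate counts of 3–10 seeds; the screening
demonstration uses D = 6, r = 50, T = 10 on analytic test functions. These
sizes exercise every code path of the full protocol while keeping a
complete run in minutes on one CPU.

What passing tests show — and what they do not: the synthetic generator
reproduces the coarse structure of the solved fields (bulk flow, boundary
layers, jet core and lateral asymmetry) but not their fine shear, secondary
currents, or vertical velocities at the slot head drop. Pattern values
computed on it therefore demonstrate the machinery and directional effects
(e.g. wall-distance steering raises wall-zone occupancy over the baseline),
not calibrated agreement with the laboratory cohort; the published best-fit
error levels are only reachable with the original solved fields and a
parameter search. Further limitations: steady fields only; no shoaling or
fish–fish interaction (the alone-fraction statistic is descriptive only);
kinematic coupling (fish do not alter the flow); the minute-resolution
observation converter assumes the documented workbook layout and spreads
same-minute events evenly over seconds.
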