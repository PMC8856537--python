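# trutta

Individual-based simulation of upstream-orienting brown trout (*Salmo
trutta fario*) in a confined laboratory flume, for testing which external
stimulus best explains upstream orientation near hydraulic structures such
as fishways.

Each model fish is a point agent in a steady 3D hydraulic field. Two bounded
internal states — motivation to move upstream, M, and fatigue, F (both in
[0, 1]) — are balanced every time step to select one of three horizontal
rules: **migrating** (swim upstream against the flow), **holding** (cancel
the local flow vector), or **drifting** (move downstream with limited
deviation). The migrating rule exists in five stimulus versions that differ
in how the horizontal swim angle is chosen:

| version | added steer |
|---|---|
| baseline | positive rheotaxis + limited random angle |
| velocity | toward the side of lower velocity magnitude \|U\| |
| tke | toward the point of smallest TKE difference to the fish center |
| acceleration | toward the side of higher convective acceleration \|a\| |
| walldist | toward the side of shorter wall distance |

Simulated cohorts are condensed into five movement patterns — lateral
occupancy P1, vertical occupancy P2, turn locations P3, few-turning share
P4, and arrival rate P5 — and compared with laboratory reference values
through a weighted root-mean-square error

    RMSE = Σᵢ aᵢ·ΔPᵢ ,   a = (0.3, 0.1, 0.2, 0.2, 0.2),

where ΔPᵢ is the RMS of the three component differences for the triple
patterns P1–P3 and the absolute difference for P4–P5. The experiment
harness samples the 20-parameter space with the revised Morris method
(elementary-effects screening with influence measure μ\* and interaction
measure σ_M) and ranks stimulus versions by the 10th percentile of their
RMSE samples with Kruskal–Wallis / post-hoc Nemenyi significance tests.

Because the original CFD solve is out of scope, a synthetic flow-field
generator produces analytically constructed flume fields (plug flow with
thin wall boundary layers, lateral asymmetry, and an optional slot jet with
a ~1.5 m/s core) that satisfy continuity exactly; real solved fields can be
read from CSV point tables instead.

## Worked example

```python
import trutta as T

geom  = T.FlumeGeometry(slot_present=True)            # setup 1: with jet
field = T.synth_flume_field(geom, Q=1.0, jet=True, resolution=0.15, seed=1)

tracks = T.run_simulation(field, n_fish=100, seed=656, version="walldist")
valid  = T.filter_valid_tracks(tracks, geom)          # line-A / line-D filters
ps     = T.compute_patterns(valid, geom)

print("P1 (left, middle, right) =", [round(v) for v in ps.p1])
print("P5 arrival rate          =", round(ps.p5, 1), "%")
print("RMSE vs lab              =",
      round(T.weighted_rmse(ps, T.LAB_SETUP1, incomplete="drop"), 1))
```

prints

```
P1 (left, middle, right) = [18, 32, 50]
P5 arrival rate          = 48.3 %
RMSE vs lab              = 21.5
```

P1 says the cohort spent 18 % / 32 % / 50 % of its track time in the
left / middle / right lateral zones (wall zones are 0.25 m wide): the
wall-distance stimulus concentrates fish near the walls, as observed in the
laboratory. P5 is the share of valid fish that crossed the upstream control
line D within the hour. The RMSE aggregates the mismatch of all pattern
means against the laboratory reference (`T.LAB_SETUP1`); smaller is better,
and the wall-distance version scores distinctly better than the plain
rheotaxis baseline on the same field.

The same pipeline is scriptable from the shell:

```sh
trutta synthflow --setup jet --out field.csv --seed 1
trutta simulate  --field field.csv --version walldist --seed 656 --out tracks.csv
trutta patterns  --tracks tracks.csv --setup jet --out patterns.json
trutta rmse      --model patterns.json --setup 1
```

plus `trutta sensitivity` (desk-scale Morris screening) and `trutta rank`
(stimulus-version ranking from an RMSE table). File formats are described
in `docs/formats.md`, the model itself in `docs/methods.md`.

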