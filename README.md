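# ziphius

Behavioural-response analysis for satellite-tagged Cuvier's beaked whales
(*Ziphius cavirostris*) exposed to two types of military mid-frequency active
sonar (MFAS) on an instrumented Navy range. The package contains the full
pipeline — and a synthetic-data generator with known planted effects, so every
stage is testable end to end without access to restricted tag or range data.

## What it does

1. **Synthetic scenario generation** (`ziphius.simulate`) — whale movement as a
   continuous-time correlated random walk (CTCRW), Argos-noised fixes,
   Behaviour-Log dive/surfacing grammars with diel structure and planted
   exposure responses, ship-type (long) and helicopter-type (short, clustered)
   sonar schedules, hydrophone detection reports with whistle clutter, and a
   corrupted SPORTS-style report table.
2. **Behaviour log processing** (`ziphius.behaviour`) — dive qualification,
   per-whale 2-means deep/shallow classification, dive-cycle metrics (IDDI).
3. **Movement modelling** (`ziphius.movement`) — Argos speed filtering, CTCRW
   fitting by exact-discretization Kalman maximum likelihood, smoothed 30-min
   track prediction with 95% CIs, geographic annotation, solar-elevation diel
   classes.
4. **Sonar detection** (`ziphius.detection`) — adaptive-threshold ping
   detection on hard-limited FFT reports, false-positive screening by
   inter-detection-interval regularity, 3-min bout segmentation,
   closest-hydrophone tracking, multi-source splitting, first-arrival
   localization, false-negative auditing.
5. **Dataset fusion** (`ziphius.fusion`) — SPORTS QC, the 15-min/10-km
   archive/SPORTS duplicate rule, combined-record assembly with conservation
   audits.
6. **Exposure summarization** (`ziphius.exposure`) — per-event overlap
   fraction (OL), distance to nearest transmission, land-blocking test, IDDI
   exposure windows, SOAR and Complete model tables.
7. **Response models** (`ziphius.gamm`) — Gaussian GAMMs with shrinkage cubic
   regression splines (k = 5, by-gated per sonar type, 500-km placeholder for
   unexposed events), whale and nested time-block random intercepts, marginal
   ML fitting, all-subsets AIC selection with AIC weights, prediction curves.
8. **Pipeline + CLI** (`ziphius.pipeline`, `ziphius.cli`) — staged runs
   (simulate → detect → fuse → integrate → fit → report) with deterministic
   derived seeds and sha256 manifests.

## Worked example

Simulate a 6-whale, 10-day scenario with the default planted responses
(deep dives extend up to +30 min when a mid-type bout overlaps within 5 km;
inter-deep-dive intervals stretch ×2 within 20 km), build the ground-truth
deep-dive-duration model table, and run AIC selection between the no-MFAS
models and the distance-smooth models:

```python
from ziphius.simulate import ScenarioConfig, simulate_scenario, truth_model_table
from ziphius.gamm import all_subsets_selection

scenario = simulate_scenario(ScenarioConfig(n_whales=6, days=10.0), seed=7)
table = truth_model_table(scenario, "deep_duration")
print(f"{len(table)} deep dives from {table['whale_id'].nunique()} whales")

sel = all_subsets_selection(table, "deep_duration", "Complete",
                            terms=("diel",), mfas_options=("none", "distance"))
print(sel.table[["label", "aic", "delta_aic", "aic_weight"]].round(3).to_string(index=False))
print(sel.best.summary())
```

Output:

```text
456 deep dives from 6 whales
             label      aic  delta_aic  aic_weight
mfas=distance+diel 3365.929      0.000         1.0
    mfas=none+diel 3392.217     26.288         0.0
     mfas=distance 3400.802     34.874         0.0
         mfas=none 3419.962     54.033         0.0

Gaussian exposure-response GAMM: deep_duration [Complete]
  model: mfas=distance+diel
  n obs: 456   log-likelihood (ML): -1674.964
  AIC: 3365.929   edf: 8
  residual SD: 9.4363   lag-1 resid ACF: -0.026
  fixed effects (estimate, SE):
    Intercept                         60.4175     0.6536
    diel[Day]                          5.8682     0.9633
    diel[Dawn]                         0.1460     1.8149
    diel[Dusk]                        -1.0095     1.8418
  random intercept whale: SD 0.0000
  smooth s(dist_high): lambda 4.172e+10 (trace edf 0.00)
  smooth s(dist_mid): lambda 7.82e+04 (trace edf 2.99)
```

The selection recovers the planted structure exactly: the distance model wins
decisively, the diel day effect is estimated at +5.87 min against a planted
+6 min, the smooth for the sonar type with no planted effect (`dist_high`)
shrinks to zero, and the mid-type smooth carries the response.

## Command-line pipeline

```sh
ziphius all --config config.yml --seed 11 --outdir out/
# or stage by stage:
ziphius simulate --config config.yml --seed 11 --outdir out/
ziphius detect   --config config.yml --seed 11 --outdir out/
...
```

Each stage writes its artefacts plus a `manifest.json` with sha256 hashes of
inputs, outputs and the configuration, so reruns are verifiably reproducible.

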