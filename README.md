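# beartrack

Analysis pipeline for satellite-tag telemetry from polar bears (*Ursus
maritimus*) during the Hudson Bay ice-free season — built for studies that
track subadult and adult male bears with short-term fur- and ear-mounted
Argos/GPS tags rather than collars.

The package takes irregular, error-prone satellite fixes and turns them into
behavioural inferences:

1. **Preprocessing** — post-capture truncation (3 days), a McConnell-style
   iterative RMS **speed filter** (≥ 40 km h⁻¹ removed), terrestrial
   selection with bounded marine *forays* (< 50 consecutive marine fixes
   retained when the bear returns to land), and segmentation at temporal
   gaps > 24 h (segments < 100 fixes dropped).
2. **Regularization** — a continuous-time correlated random walk (CTCRW;
   integrated Ornstein–Uhlenbeck velocity, `dv = −βv dt + σ dW`) fitted per
   segment by Kalman-filter maximum likelihood with measurement SDs fixed by
   Argos location class (3, 2, 1, 0, A, B) or GPS error, then smoothed onto
   an exact 4-h grid (interpolating Argos, rarefying 2-h GPS).
3. **Behavioural HMM** — a two-state hidden Markov model on the 4-h grid:
   step lengths `ℓ_t ~ Gamma(mean_s, sd_s)`, turn angles
   `φ_t ~ vonMises(μ_s, κ_s)`, and transition probabilities
   `logit P(i→j | x) = β₀ᵢⱼ + β₁ᵢⱼ·temp (+ β₂ᵢⱼ·temp²)` driven by hourly
   station temperature. Candidate formulations (intercept-only, linear,
   quadratic; K = 11, 13, 15 parameters) are fitted from random restarts,
   compared by AICc, and decoded with the Viterbi algorithm to yield
   resting/traveling time budgets and stationary occupancy curves
   `π(temp)` solving `π Γ(temp) = π`.
4. **Tag performance** — functional duration per tag design (detachment is a
   run of > 3 consecutive inactivity-flagged fixes; otherwise last
   transmission) and Argos error-class composition tables.
5. **Synthetic studies** — because the original telemetry is not publicly
   deposited, `beartrack.simulate` generates complete stand-in studies
   (latent two-state movement with temperature-dependent switching,
   class-structured Argos error, duty cycles, missed fixes, tag failure)
   with full ground truth, so every stage is tested closed-loop.

## Worked example

```python
from beartrack.simulate import SimConfig, simulate_study
from beartrack.pipeline import run_study_pipeline

study = simulate_study(SimConfig(n_bears=6, n_steps=400, seed=42))
report = run_study_pipeline(study.fixes, study.deployments, study.temperature,
                            {"n_restarts": 10}, seed=42)
for s in report.stages:
    print(f"{s.stage:22s} in={s.n_in:5d} removed={s.n_removed:4d} retained={s.n_out:5d}")
print(report.model_table.to_string(index=False))
print("time budget (resting, traveling):", report.time_budget.round(3))
```

prints

```
truncate_post_capture  in= 2700 removed= 189 retained= 2511
speed_filter           in= 2511 removed=   0 retained= 2511
terrestrial_filter     in= 2511 removed=   0 retained= 2511
segment_tracks         in= 2511 removed=  39 retained= 2472
         model  K      loglik        AICc  delta_AICc
          temp 13 -524.523247 1075.317327    0.000000
         temp2 15 -524.064851 1078.487378    3.170051
intercept_only 11 -531.215811 1084.627760    9.310433
time budget (resting, traveling): [0.689 0.311]
```

Reading this: counts are conserved at every stage (nothing is silently
dropped); the linear-temperature transition model wins model selection
(ΔAICc 9.3 over intercept-only), its fitted traveling step mean is 0.74 km
per 4 h (~0.19 km h⁻¹) with a negative temperature coefficient on the
resting→traveling transition — the bears of this synthetic study travel more
as temperatures cool — and the decoded time budget is ~69% resting / 31%
traveling.

The same run is available from a shell:

```bash
beartrack all --out-dir work --seed 42        # simulate + pipeline + report
beartrack simulate --out-dir work --seed 1    # or stage by stage:
beartrack preprocess --out-dir work
beartrack regularize --out-dir work
beartrack fit --out-dir work
beartrack decode --out-dir work
```

## Layout

```
src/beartrack/
  geo.py              spherical distances, bearings, local AEQD projection
  core.py             data model, CSV IO, temperature covariate matching
  preprocess.py       truncation, speed filter, foray rule, segmentation
  regularize.py       CTCRW Kalman filter/smoother, 4-h grid
  hmm.py              gamma–von Mises HMM, AICc selection, Viterbi, budgets
  tag_performance.py  functional durations, error-class tables
  simulate.py         synthetic-study generator with ground truth
  pipeline.py         orchestration + report bundle
  cli.py              typer CLI (`beartrack`)
docs/methods.md       model and design notes
```
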