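# facelearn

Simulation and hierarchical Bayesian modelling of a dyadic facial-expression
avoidance-learning experiment. Two on-screen interactants present smile/frown
clips; the participant avoids a mild shock by responding with the congruent
expression to one interactant and the incongruent expression to the other,
with the contingencies silently reversed halfway through (96 trials: 4 clips
× 12 repetitions × 2 blocks).

The package provides:

- **`facelearn.task`** — expressions, contingency maps, reversal, and
  randomized trial schedules (no clip more than twice in a row, exact
  per-block clip counts via constrained sequential sampling with restarts).
- **`facelearn.preprocess`** — scoring and exclusion rules (RT < 626 ms
  non-compliance, RT > 5 s outliers, no-response trials), per-condition
  summaries, learning curves, and early/late reversal comparisons with
  paired t-tests.
- **`facelearn.rl`** — the Q-learning model family over copy/not-copy
  actions per interactant: SoftMax choice with a static copy bias ζ,
  Rescorla–Wagner updates with reinforcement ±1, four alternative variants
  (no bias, learnable prior bias, expression-dependent α or ζ), vectorized
  likelihoods, hierarchical Bayesian fitting, PSIS-LOO model comparison, and
  posterior-predictive learning curves per CI/IC condition.
- **`facelearn.ddm`** — response-coded Wiener diffusion model (upper
  boundary = smile): adaptive small/large-time first-passage density,
  Euler–Maruyama and inverse-CDF simulators, condition-indexed likelihood
  (drift and boundary per target-expression × required-response cell, bias
  per target expression, per-subject non-decision time), hierarchical
  fitting, and posterior contrasts (absolute-drift congruency contrast in
  both the sum and per-condition-mean variants, expression contrasts on
  |v|, a and z) reported as mean, 95% CrI, and fraction of posterior mass
  positive.
- **`facelearn.synth`** — ground-truthed synthetic cohorts (default 58 × 96
  = 5568 trials) in two modes (`rl_choices`, `ddm_joint`), with injected
  fast-non-compliance and no-response artifacts and exact exclusion-reason
  labels for scoring the filters.
- **`facelearn.pipeline` / CLI** — staged runs with manifests (config hash,
  substream seeds, artifact checksums).

No participant data ship with this package: all fitting is validated by
parameter- and model-recovery experiments on the synthetic cohorts, whose
ground truth is stored alongside the generated records.

MCMC is a self-contained blocked adaptive Metropolis-within-Gibbs sampler
(subjects updated in parallel, conjugate population-location draws, and a
non-centred scale move that removes the location-scale funnel); convergence
diagnostics (split R-hat, bulk ESS) and PSIS-LOO come from `arviz`.

## CLI

```bash
facelearn run --seed 1 --out results/run1 --fast        # all stages, reduced samplers
facelearn simulate --seed 1 --out results/run1
facelearn preprocess --out results/run1
facelearn fit-rl --out results/run1 --config my_config.yaml
facelearn fit-ddm --out results/run1 --fast
facelearn compare --out results/run1 --fast
facelearn contrasts --out results/run1
facelearn report --out results/run1
```

Configuration is a YAML/JSON serialization of `facelearn.pipeline.RunConfig`;
every random stage derives its stream from the single top-level `--seed`.
Default sampler settings are 4 chains × 2000 iterations for the RL models and
6 chains × 10 000 iterations (1000 warm-up) for the DDM; `--fast` switches
both to desk-scale settings.

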