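# kinpref

Kin-directed sexual and social preference analysis for dichotomous-choice
and free-swimming fish trials.

Behavioural ecologists testing for inbreeding avoidance ask whether animals
direct sexual and affiliative behaviour away from relatives.  `kinpref`
implements the full analysis chain for the two standard designs in small
fish (guppies and similar poeciliids):

* **Dichotomous mate choice** — a focal fish in the main compartment of a
  three-compartment tank chooses between a related and an unrelated
  opposite-sex stimulus; preference is read from time spent in the
  24 x 5 cm association zones.
* **Free-swimming groups** — 8 fish in a 36 cm arena, tracked frame by
  frame; social structure is read from pairwise proximity (two individuals
  are associated when their centroids are within 2 mean body lengths,
  2 x 1.76 cm = 3.52 cm) and from observer-scored sexual behaviours
  (orienting, approaching, gliding; pursuing, sigmoid displays, matings and
  forced mating attempts).

The core index is the **strength of preference**

    SOP = (T_R − T_UR) / (T_R + T_UR)   ∈ [−1, 1]

with `T_R` / `T_UR` the time associated with the related / unrelated
option: −1 is exclusive avoidance of kin, +1 exclusive kin preference, 0 no
bias.  SOP scores feed one-sample t tests and linear mixed models (sex,
mating status and stimulus trait differences as fixed effects, family
origin random); behaviour and association counts feed negative-binomial
GLMMs (relatedness, mating status, sex fixed; arena and behaviour type
random) with likelihood-ratio ANOVA, Tukey post-hoc contrasts and
Benjamini–Hochberg FDR within declared test families; per-individual SOPs
are compared across designs with Spearman rank correlations.

A synthetic-data module generates trials with the statistical structure the
analysis assumes — a three-state Markov chain for zone occupancy, a biased
correlated random walk with tunable pairwise social attraction for arena
trajectories, and overdispersed behaviour counts with arena random effects
— so the whole pipeline is testable without any recordings.  See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from kinpref.pipeline import RunConfig, Scenario, run_experiment1

res = run_experiment1(RunConfig(scenario=Scenario(), master_seed=1))
t = res.ttest_total
print(f"trials: {res.n_total} -> {res.n_analyzed} (breach) -> {res.n_ic_analyzed} (informed choice)")
print(f"mean SOP = {t.mean:.3f}, t({t.df}) = {t.t:.2f}, P = {t.p:.3f}")
print(res.models["overall"].summary())
```

prints

```
trials: 96 -> 89 (breach) -> 88 (informed choice)
mean SOP = -0.035, t(88) = -1.47, P = 0.146
Mixed model results
==================================================================
Response:   sop_total                Family: gaussian
N obs:      89                       Log-likelihood: 12.587
Random:     family                   Converged: True
------------------------------------------------------------------
term                                   est     se      z       p
Intercept                            0.021  0.039   0.53  0.5986
sex[T.male]                         -0.053  0.044  -1.19  0.2348
mating_status[T.virgin]             -0.061  0.044  -1.39  0.1655
body_length_diff_mm                  0.035  0.010   3.39  0.0007
Dropped interactions: body_length_diff_mm:sex:mating_status, body_length_diff_mm:sex, sex:mating_status, body_length_diff_mm:mating_status
==================================================================
```

Reading it: of 96 simulated choice trials, 7 acclimation-breach flags leave
89 for analysis and the informed-choice window drops 1 more (88).  Under
the default scenario there is no kin preference (mean SOP ≈ 0, t test not
significant), sex and mating status have no effect, and the positive
body-length-difference slope — larger related stimuli are preferred —
recovers the size effect built into the generator (0.05 SOP units/mm,
estimate 0.035 ± 0.010).  All interactions were pruned as non-significant,
leaving main effects only.

The same objects drive the arena experiments and the cross-design
consistency stage (`run_experiment2`, `run_experiment3`,
`run_cross_experiment`, or `run_all`), and a thin CLI wraps them:

```sh
kinpref all --seed 1 --outdir out/          # all three experiments + cross
kinpref exp1 --scenario my_scenario.yaml    # scenario file overrides defaults
```

Every output table carries the master seed and a config hash; identical
config + seed reproduce outputs byte for byte.

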