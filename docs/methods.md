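# Methods

`kinpref` quantifies kin-directed sexual and social preference in small
freshwater fish from two kinds of raw material: zone occupancy of a focal
individual in a three-compartment dichotomous-choice tank, and
multi-animal centroid trajectories plus observer-scored behavioural events
from free-swimming arenas.  This note records the models, the synthetic
data generators, the numerical choices, and the limitations a user should
know about.

## The preference index

All preference statements reduce to the strength of preference

    SOP = (T_R - T_UR) / (T_R + T_UR)

where `T_R` is time associated with the related option and `T_UR` with the
unrelated option.  SOP lies in [-1, 1]: -1 is exclusive preference for the
unrelated partner (inbreeding avoidance), +1 exclusive kin preference, 0 no
bias.  When `T_R + T_UR = 0` the score is undefined; it is flagged and
excluded listwise from every downstream test, never coerced to zero.

Three bases are implemented:

* **Dichotomous zones** — occupancy of the two 24 x 5 cm association zones
  of the choice tank, attributed to related/unrelated via the trial's
  stimulus-side assignment.  Zone membership is centroid-in-rectangle,
  inclusive on the outer (stimulus-side) wall and half-open against the
  neutral region, so the zones and the neutral area partition the main
  compartment.  An *informed choice* (IC) variant restricts scoring to
  frames after the focal has visited both zones; trials where a zone is
  never visited, or where fewer than `min_window_s` (default 60 s) remain
  after the later first entry, are flagged and excluded (the study's own
  ledger drops one trial this way).  Interval SOPs default to successive
  thirds of the trial; the edges are a config parameter because no
  canonical definition exists.
* **Mixed-sex arenas** — `T_R` is the summed association duration with the
  2 related opposite-sex arena mates, `T_UR` with the 2 unrelated ones.
* **Same-sex arenas** — 1 related (the sibling) versus 6 unrelated
  partners, raw sums.  The raw-sum definition makes a partner-indifferent
  individual score (t - 6t)/(t + 6t) = -5/7, not 0.  This asymmetry is
  preserved deliberately because it is how the arena scores are defined in
  the source analyses; a per-capita variant (`per_capita=True`) divides by
  the set sizes and restores 0 as the indifference point, but is off by
  default.

## Association detection

Two individuals are associated at a frame when their centroid distance is
at most the threshold radius — two mean body lengths, 2 x 1.76 cm =
3.52 cm, by default; the multiplier is configurable (e.g. 4 body lengths
for shoal-scale proximity).  The boundary is inclusive (`<=`): the
difference to a strict inequality has measure zero in continuous data and
the inclusive rule keeps exact-geometry tests clean.  Frames where either
member of a dyad is missing are removed from that dyad's numerator *and*
denominator, so tracking loss does not bias association fractions.  Every
qualifying frame counts independently; no bout merging or minimum bout
length is applied by default (total time, not bout structure, feeds the
models), though a bout extractor with both knobs exists.

Tracking gaps can be repaired before detection: runs of at most
`max_interp_frames` (default 5) missing frames are filled by per-coordinate
linear interpolation; longer runs stay missing and are reported.  Repair is
idempotent and never invents endpoints (gaps touching the recording edges
are left alone).

## Statistical layer

Gaussian responses (SOP) are fitted as linear mixed models (statsmodels
`MixedLM`, maximum likelihood) with family origin as a random intercept;
overdispersed behaviour and association counts as negative-binomial GLMMs
(log link, NB2 mean-dispersion parameterization) fitted by `glmmTMB`
through a batched R subprocess worker.  The surrounding logic — design
construction, the stepwise interaction-pruning loop, likelihood-ratio
ANOVA, Tukey contrasts, FDR — is implemented in the package and is backend
agnostic.

*Interaction pruning.*  All 2- and 3-way interactions among the fixed
effects enter initially; the least significant droppable interaction
(highest Wald p at or above alpha = 0.05, never a term marginal to a
retained higher-order interaction) is removed and the model refitted, one
term per iteration, until only significant interactions or main effects
remain.  The alpha and one-at-a-time order are package choices; only
"stepwise removal of non-significant interactions" is externally fixed.

*Per-predictor tests.*  Predictors with more than two levels are tested by
likelihood-ratio model comparison (refit without the predictor and every
interaction containing it; chi-square on the parameter-count difference).
Significant multi-level effects get all pairwise Tukey contrasts on the
link scale, adjusted with the studentized-range distribution on the Wald z
statistics (the standard asymptotic single-step correction for mixed
models).

*Multiplicity.*  Benjamini–Hochberg adjustment is implemented from the
step-up definition (sort ascending, `adj_i = min_{j>=i} m p_(j) / j`,
capped at 1, original order restored) and applied within declared families:
one family per predictor across the per-behaviour and pooled models of each
sex, and one family per predictor across the three association-duration
models (female–male pairs, all mixed-sex pairs, same-sex pairs).  This
family structure is the one that reproduces the published adjusted values
exactly from the published raw p values; adjustment is applied to
unrounded p values.

*Simple tests.*  One-sample t (SOP against 0), Wilcoxon rank-sum with
mid-ranks (trait differences; W is the Mann–Whitney U of the first sample,
exact for small tie-free samples), and Spearman rank correlations with
pairwise deletion for the cross-design consistency of individual SOPs.

## Synthetic data generators

The generators produce data with the statistical structure the analysis
assumes, at the study design: 24 full-sib families x 4 focals (one per
sex x mating status), 96 choice trials (7 flagged acclimation breaches and
1 trial that never enters one zone, reproducing the 96 -> 89 -> 88 filter
ledger), 12 mixed-sex arenas (two families of 4) and 12 same-sex arenas
(4 families x 2, six arenas per sex) of 8 fish each.

**Zone occupancy** is a three-state discrete-time Markov chain (related
zone / unrelated zone / neutral) sampled at frame resolution, not a
mechanistic swim model: only occupancy totals and visit order feed the
analysis.  The chain redraws its state from the stationary distribution
`(p_zone * b, p_zone * (1-b), 1 - p_zone)` with a per-frame probability
calibrated to an expected `switch_rate` (default 2 switches/min), so
stationarity holds exactly at every frame and the expected SOP of a trial
is `2b - 1` by construction.  Defaults: `p_zone` 0.68 for females and 0.58
for males (the observed occupancy levels), `b = 0.5` (no kin preference,
the study's headline finding), 30-min trials at 10 frames/s (frame rate is
a package default; none is externally specified).  Per-trial bias can be
shifted by a body-length-difference slope (default 0.05 SOP units/mm, the
magnitude the choice models report), a family random effect (SD 0.05) and
an optional latent per-individual kin preference shared across experiments
(SD 0 by default).

**Arena trajectories** are biased correlated random walks in a circular
arena (radius 18 cm): each step the direction is the normalized sum of the
persistence-weighted previous heading (persistence 0.8), a social pull, and
a uniform random unit vector weighted by 1 - persistence; speed is
truncated-normal (5 +/- 1.5 cm/s) and the wall reflects specularly.  The
social pull points along the normalized attraction-weighted resultant of
unit vectors toward the other fish and has magnitude `attraction_gain`
(default 0.1) times the individual's mean absolute attraction weight —
relative weights steer which partners are approached, the overall weight
level sets group cohesion, and speed/turning distributions stay decoupled
from the social term.  Default weights: base 1.0, virgin–virgin pairs
-0.5, male–male pairs -0.6, relatedness 0 — i.e. the status and sex
association contrasts the arena models detect, and no kin structure.
These movement statistics are generic small-fish placeholders: no speed or
turning-angle distributions are externally specified, and the simulated
kinematics are not claimed to match real guppies.  At the default gain the
mean dyadic association fraction is ~0.1–0.15 of frames, a realistic
shoaling level for a 2-body-length threshold.

**Behaviour counts** are negative-binomial draws per
arena x mating-status x relatedness cell with log-linear effects and an
arena random intercept (log-scale SD 0.3, dispersion 2).  Default
per-trial base rates (orienting 20, approaching 15, gliding 2, pursuing
30, sigmoid 10, mating 2, forced mating 1 events per cell) are plausible
half-hour magnitudes chosen once; the status effects default to the
published estimates (gliding +1.33 for virgins, pursuing -0.22, mating
-0.61) and all relatedness effects to 0.  An event-level wrapper scatters
cell counts into observer-style logs (actor, recipient, onset) so the
aggregation stage is exercised end to end; aggregating the log recovers
the cell counts exactly.

All generators take explicit integer seeds; a master seed spawns
per-component streams through `numpy.random.SeedSequence`, and identical
config + seed reproduce every output table byte for byte.

## What passing tests do and do not show

The generators match the analysis assumptions by construction (NB counts
fitted by NB models, Markov occupancy scored by occupancy totals).  Passing
recovery and calibration suites therefore validates the *machinery* — the
estimators recover what was injected and the pipeline is deterministic —
not the adequacy of these models for real recordings.  Real data deviate in
ways the generators do not emulate: tracker identity swaps, non-stationary
arousal, wall-following, bout-structured courtship, zero-inflated dyads,
and kinematics unlike the placeholder walk.

## Problem sizes and observed calibration

Unit suites run reduced problem sizes (e.g. 4–10 min recordings at 5–10
frames/s, 100–300 replicates); the acceptance script runs the full study
design for the single-pass stages and 100–200 replicates for the
calibration suites.

One calibration result deserves a flag: at the study's count-model design
size (48 cells, 12 arenas, dispersion 2) the NB-GLMM relatedness term
rejects a true null at about 8–9% rather than the nominal 5% (observed
18/200 by Wald z and 16/200 by likelihood ratio over seeded null
replicates).  The same machinery is well calibrated at larger designs, so
this is the familiar small-sample anti-conservatism of asymptotic z and
chi-square references with few grouping levels — a property of the
analysis design itself (and of any analysis using these tests at this
size), not of the implementation.  The acceptance suite reports this check
against the nominal envelope and it can fail; the parallel estimate-scale
check (estimate within 3 SE of zero) holds comfortably.

## Known limitations

* Negative-binomial GLMMs require the R `glmmTMB` stack at run time; the
  bridge batches fits (R startup dominates) and surfaces non-convergence
  as a flag on the result, never silently.
* Gaussian mixed models support a single random intercept (family origin);
  crossed Gaussian designs are out of scope.
* Tukey contrasts assume the factor is not involved in a retained
  interaction (contrasts are otherwise not constant across covariates).
* The same-sex arena SOP inherits the -5/7 indifference point of the
  raw-sum definition; correlations across experiments mix bases with
  different nulls.  Rank correlations are invariant to the within-basis
  monotone shift, which is why Spearman is used for consistency.
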