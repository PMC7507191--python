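# Methods

## The task and its decision model

A temporal-bisection trial presents three brief events on a nominal
0–1000 ms timeline: anchors at 0 and 1000 ms and a probe in between. The
observer reports whether the probe was closer in time to the first or the
third event. Event times are abstract onset coordinates; physical stimulus
duration and rendering are presentation details outside the decision
model, which is why the expected unbiased PSE is the interval midpoint
(500 ms).

Bimodal trials can carry a conflict Δ ∈ {−50, 0, +50} ms: the audio-minus-
visual offset is +Δ at the probe and −Δ at both anchors, a 100-ms net
relative conflict. The offset is **split symmetrically** (±Δ/2 to each
modality around the nominal timeline). Nothing in the design pins which
modality carries the nominal timeline; the symmetric split is the unique
choice under which an equal-weight observer predicts exactly zero PSE
shift, which is the property the conflict manipulation is built to test.
Under this geometry the audio probe bisects its own anchors at nominal
probe time 500 − Δ and the visual probe at 500 + Δ.

Simulated observers use as decision variable the signed offset of the
(combined) perceived probe from the perceived midpoint of the anchors.
Each presented modality m contributes an internal estimate
x_m ~ Normal(true offset − bias_m, σ_m); bimodal estimates are combined by
the observer's integration mode (reliability-weighted MLE, audio-only, or
visual-only), and the response is "closer to third" iff the combined
estimate is positive. With probability λ (lapse) the response is a fair
coin flip, as is an exactly-zero estimate (a measure-zero event; any rule
would do). This construction makes the psychometric function in nominal
probe time exactly λ/2 + (1−λ)Φ((p − PSE)/σ_eff), so generator parameters
map one-to-one onto the fitted quantities:

| parameter | meaning | default | rationale |
|---|---|---|---|
| σ_A, σ_V | temporal noise SD per modality (ms) | — (per observer) | the fitted unisensory thresholds |
| bias_A, bias_V | shift of the perceived midpoint (ms) | 0 | PSE = 500 + bias |
| λ | lapse rate | 0.02 | child data without a lapse allowance bias σ estimates; set 0 to reproduce a plain cumulative-Gaussian fit |
| mode | MLE / AUDIO_DOMINANT / VISUAL_DOMINANT | — | the two hypotheses the analysis contrasts |

## Synthetic cohorts

Cohorts draw per-subject parameters from log-normal distributions for the
noise SDs and normal distributions for the biases. Defaults encode the
qualitative group structure the analysis is designed to detect, not any
measured values (no raw child data exist to calibrate against):

- **typical**: median σ_A = 100 ms, σ_V = 200 ms (audition more precise),
  biases ~ Normal(0, 30) ms, mode AUDIO_DOMINANT;
- **dyslexic**: median σ_A = σ_V = 300 ms (elevated, equal), biases
  ~ Normal(+250, 50) ms — a unisensory PSE near 750 ms — mode MLE.

The log-normal scale 0.3 (≈ ±30% between-child spread) and the bias SDs
are chosen once as realistic developmental variability; all are
config-overridable. The generator emulates binary bisection responses
under stationary parameters. It does **not** emulate attention drift,
learning, serial dependence, non-Gaussian internal noise, or asymmetric
lapses — so a green cohort test establishes that the *pipeline* recovers
what the stated model generates, not that real children satisfy the model.

## Adaptive (QUEST) placement

Each condition runs an independent maximum-likelihood adaptive track: a
posterior over candidate PSE values on a 1-ms grid over (0, 1000),
initialized to a Normal(500, 300) prior, updated after every response with
the Bernoulli likelihood of a fixed-slope psychometric function
(assumed σ = 150 ms, assumed λ = 0.02). Regular trials are placed at the
posterior mode plus Normal(0, 100 ms) perturbation (clipped to (1, 999))
so the function is sampled over its range; ~20% of slots are easy trials
placed uniformly within 100 ms of a random anchor. The adaptive procedure
tracks the PSE only, with the slope assumed fixed: the prior, perturbation
level and assumed slope are declared defaults (the experimental protocol
this emulates does not state them), chosen so a 30-trial track both
converges and leaves the slope estimable. The adaptive readout is never
used for analysis; estimates always come from refitting the full trial
log. All posterior arithmetic stays in the log domain, so long one-sided
response runs cannot underflow the posterior.

## Fitting

PSE and σ maximize the Bernoulli likelihood of the binary responses with λ
fixed (default 0.02; λ = 0 gives the plain cumulative-Gaussian fit).
Bernoulli ML on raw trials — rather than least squares on binned
proportions — is the standard-practice objective for adaptive data, where
bin occupancies are unequal by design. The optimizer is two-stage: a
coarse grid seed (33 PSE × 17 log-spaced σ values) followed by Nelder-Mead
refinement in (PSE, log σ), with σ bounded to [1, 1000] ms. The bound
keeps separable (step-like) small samples finite; such fits return σ at
the lower bound. Fits require ≥ 10 trials and both response classes.
Standard errors are case-resampling bootstrap SDs over 100 refits;
resamples that fail to fit (e.g. single-class draws) are dropped and
counted, and more than 50% failures raises an error rather than returning
a misleading SE.

Test oracles are independent of this path: an exhaustive (PSE, σ) grid
search must never beat the optimizer's likelihood, and at 1-ms resolution
the two must agree in argmin to one grid step.

## Integration predictions and pooling

Predictions are computed per subject from that subject's own unisensory
fits, never from group means; group-level predictions are means of
per-subject predictions. The three conflict conditions are pooled by
**trial concatenation** into one 90-trial fit for the bimodal threshold
(the only version defined at 30 trials per condition); only the threshold
readout of the pooled fit is interpreted. Conflict PSEs are normalized by
subtracting the subject's no-conflict PSE, and the identical subtraction
is applied to the model predictions before comparison. Sign convention
throughout: a positive shift means the PSE is later than 500 ms, so full
auditory dominance under Δ = +50 (audio later at the probe) yields −50 ms.

## Cohort statistics

Observed-vs-predicted comparisons use two-sided paired t tests with
Cohen's d = mean difference / SD of differences; constant nonzero
differences raise an error rather than emitting an infinite t.
Correlations report Pearson r (analytic t-based p) and Spearman ρ with a
10 000-resample bootstrap percentile 95% CI and a 10 000-draw permutation
two-sided p, both vectorized and seeded — permutation inference because
the cohorts are small (n ≈ 26–32) with no normality guarantee. Missing
pairs are dropped listwise and the effective n is reported. Two
correlations are compared with the standard Fisher r-to-z statistic
z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)).

## Known limitations

- **Plug-in bias of the prediction.** σ_VA is a concave function of the
  unisensory thresholds, so evaluating it at noisy fitted σ̂'s biases the
  prediction downward (Jensen), and the pooled fit carries its own
  finite-sample error. At 30 adaptive trials per condition this makes even
  a perfectly optimal simulated cohort show observed − predicted ≈ +75 ms
  (≫ 1 group SE); the offset falls to ≈ +3 ms at 300 uniform-probe trials
  per condition. Group-level agreement tests therefore run at trial counts
  where estimator bias is negligible; at experimental trial counts the
  paired test should be read as conservative against the optimal model.
- **Boundary censoring.** Probes are confined to (0, 1000) ms, so
  observers with strongly late PSEs (e.g. bias +250 ms with σ = 300 ms)
  have the upper flank of their psychometric function censored, degrading
  σ estimates at small n.
- **Correlation-comparison discrepancy.** For ρ ≈ −0.51 vs −0.03 at
  n = 32 per group the standard Fisher formula gives |z| ≈ 2.0, not the
  3.0 reported in the literature this design follows; the computation
  behind that printed value is unstated, and this package implements the
  standard formula.
- The packaged clinical table transcribes its source verbatim, including
  a gender tally (15/17 by code) that disagrees with the stated 16/16;
  reading/IQ gaps are kept as explicit missing values, never zero-filled.
- A 2×3 mixed ANOVA over group × conflict is deliberately not
  re-implemented; the report exposes the cell means and SEs any standard
  ANOVA routine can consume.
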