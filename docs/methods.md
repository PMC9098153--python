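# Methods

This note records the models behind `smht`, the defaults that matter, what
the synthetic generators do and do not emulate, and the places where the
design was genuinely open and a choice had to be made.

## Fuzzy factor analysis

The observation model is the common-factor decomposition X − FE(F) = L F + ε,
E(ε) = 0, fitted on the *correlation* scale so the Kaiser retention rule
(eigenvalue > 1, strict inequality, so an exactly-isotropic spectrum retains
nothing) is meaningful. Robustness enters through per-respondent memberships:

* membership update: Uₖ = 1 / (1 + (dₖ/s)²), with dₖ the Euclidean distance
  of the standardized response vector from the current weighted mean and
  s = median distance (times a `scale` multiplier, default 1). This
  Cauchy-type weight is smooth, bounded in (0, 1], parameter-light, and
  strictly decreasing in dₖ; a respondent at the weighted mean keeps weight
  1, one at the median distance keeps 0.5.
* alternation: weighted mean/SD → memberships → weighted mean …, one loop,
  `max_iter` 50, convergence when the weighted mean moves less than `tol`
  1e-4. Non-convergence returns a flagged model plus a warning, never a
  silent failure. With memberships pinned at 1 the procedure reduces exactly
  (to 1e-8 in the tests) to a classical principal-component extraction.
* moments are normalized by ΣUₖ (not ΣUₖ − 1); correlation-scale results are
  invariant to this choice, and it keeps the weighted mean an exact convex
  combination.
* loadings are √λⱼ e⃗ⱼ; per-factor contribution λⱼ/p. No rotation is applied
  by default; a varimax implementation is provided because recovery studies
  need it (see below).

KMO compares raw squared off-diagonal correlations with anti-image partial
correlations from R⁻¹; Bartlett's statistic is −(n−1−(2p+5)/6)·ln|R| with
p(p−1)/2 degrees of freedom.

**Rotational indeterminacy in recovery studies.** A simple-structure pattern
with equal-sized blocks yields three nearly equal block eigenvalues, so the
leading eigenvectors are arbitrary rotations within that subspace and raw
principal axes cannot match the planted pattern. The recovery and robustness
studies therefore varimax-rotate the retained loadings (a data-driven step
that never sees the target) before Hungarian permutation/sign alignment and
RMSE. Identical treatment is applied to the fuzzy and classical extractions
being compared.

## Psychometrics

Unbiased (n−1) variances throughout; the Pearson correlation is written with
matching N-conventions in numerator and scale terms, so it is convention-free,
and test–retest reliability and criterion validity literally share the same
kernel. Item discrimination uses the critical-ratio method with the classic
27% high/low groups and a Welch t; groups are formed by quantile thresholds
on the *rest score* (total minus the item under test) with boundary ties
included. Two reasons: ties make index-based splits depend on respondent
order, and a self-inclusive total correlates with any item — even pure noise
— biasing the method against deletion (measured: with self-inclusive totals
only 40% of contaminated replicates delete exactly the planted noise items;
with rest scores, 92%). Normality screening flags |skew| > 2 or |excess
kurtosis| > 7 — deliberate gross-departure thresholds for 5-point items, not
a formal test. Readability is the Flesch reading-ease formula
206.835 − 1.015·(words/sentences) − 84.6·(syllables/words); note that scores
of ~85 mean "easy prose" on this 0–100 scale, whereas grade-level variants of
the formula produce small numbers like 7–8 — the two are easily confused and
only the reading-ease form is implemented. Dimension vote weighting scores
Σg·countg/(5·total) and excludes dimensions with fewer than 142 total votes
or weighted mass under 80; the mass threshold is our operationalization of an
otherwise undefined secondary criterion.

## Affect channels

Text documents are lower-cased, split on any non-alphanumeric character
except in-word apostrophes. The sentiment model is multinomial Naive Bayes
with additive smoothing (default 1); out-of-vocabulary tokens carry no
evidence, so empty or fully-OOV documents return the class priors. Boosting
is SAMME: weak learners are NB models trained on weight-proportional
resamples (seeded), the round weight is αₜ = ln((1−εₜ)/εₜ) + ln(K−1), weights
of misclassified documents are multiplied by e^{αₜ}, and boosting halts at
the random-guessing boundary εₜ ≥ (K−1)/K or at εₜ = 0 (clamped at 1e-10 so
α stays finite). Binary problems reduce to standard AdaBoost, where the
ensemble training error obeys the ∏ₜ 2√(εₜ(1−εₜ)) bound checked in the tests.

The speech channel deliberately starts at the *feature* level: the scorer
consumes numeric prosody vectors (stand-ins for intonation, pitch level and
variability, energy, rate, voice quality) through a pluggable posterior
interface, so a trained sequence model can replace the reference
diagonal-Gaussian class-conditional scorer without touching the rest of the
pipeline. No audio, speech recognition, or TTS is modelled; the word-error
-rate metric (minimal edit distance over reference length) characterizes an
upstream transcription stage and is exercised against an emulated corruption
process.

**Valence maps.** Turning categorical affect into a score is the largest
interpolation in the package and is not prescribed by any standard: we fix
negative/objective/positive → 0/0.5/1 and sad 0, fearful 0.1, angry 0.2,
neutral 0.5, surprised 0.7, happy 1.0, and take expectations under the
predicted class distribution. The emotion ordering (distress-like emotions
low, activated-positive high) is declared once and never tuned; any
monotone re-mapping changes absolute fused scores but not the qualitative
fusion results.

## Fusion

All three components are oriented as distress in [0, 1]: the objective
component is the range-normalized scale total, the text and speech components
are one minus their valence expectation. Fusion is the convex combination
with weights 6 : 1.5 : 3.5 normalized by their sum (= 11). The binary rule is
at-risk iff score ≥ 0.5; the threshold and the ≥ tie rule are fixed so
decisions are reproducible. The calibration rate is
100·(acc_fused − acc_scale)/acc_scale against interview labels, and the
self-test error is the mean absolute difference between fused scores and
self-reported scores (operationalized in the pipeline as the objective
component, i.e. what a scale-only self-test would return).

## Synthetic generators: what they emulate, and what they do not

* **Likert responses**: z = Λf + √ψ·ε thresholded at global cutpoints
  (−1.5, −0.5, 0.5, 1.5), chosen so a unit-variance latent yields the
  symmetric category distribution (.067, .242, .383, .242, .067). Global
  (not per-item) cutpoints keep item marginals comparable and the structure
  recoverable; real instruments have item-specific, usually skewed
  marginals. Contamination is a +`outlier_magnitude` (default 4) latent mean
  shift applied to ⌊fraction·n⌋ respondents — an "acquiescent/extreme
  responder" model matching the outlier framing of the fuzzy extraction —
  and their indices are returned for verification.
* **Retest**: the latent score behind each response is reconstructed by a
  truncated-normal posterior draw, mixed with fresh noise at latent
  correlation ρ, and re-thresholded. Raw √reliability mixing undershoots the
  target after discretization, and any item-level calibration overshoots on
  the totals when items correlate; instead ρ is solved (Brent) so the
  closed-form *expected total-score* correlation — available because retest
  entries are conditionally independent given the base matrix — equals the
  target. Reliability 1 returns an exact copy. Measured recovery at n = 2000:
  within ±0.015 of a 0.85 target.
* **Criterion**: validity·z(totals) + √(1−validity²)·noise, placed on an
  established-instrument-like scale; continuous, so no attenuation.
* **Cohorts**: a binary state drives all channels symmetrically — latent
  response means split ±effect/2, documents mix the neutral unigram model
  with the positive (healthy) or negative (at-risk) pole, and emotion
  occupancy shifts from neutral/happy-leaning to sad/fearful-leaning with
  feature separation 2·`prosody_effect` noise-SD between prototypes.
  Defaults (scale 0.8, text 0.6, prosody 1.0, interview noise 0.05, 50%
  prevalence) describe a moderately informative screening setting. One root
  seed spawns fixed-offset child seeds per channel.

Passing tests on these generators show the estimators recover what was
planted under a well-specified model; they do not show robustness to
item-specific marginals, differential item functioning, non-normal latents,
real language, or real prosody. The built-in 40-word maritime lexicon makes
the sentiment task nearly separable at realistic document lengths — held-out
accuracy near 1, far cleaner than any real corpus.

## Numerical choices and degenerate inputs

Eigenvector signs fix the largest-magnitude entry positive; eigen-ties at
exactly the Kaiser threshold are excluded; rank-deficient LᵀL falls back to
the pseudo-inverse with a warning; all-zero memberships, constant matrices,
singular correlation matrices, zero-variance totals, empty corpora and
out-of-range fusion components raise typed validation errors; an s = 0
membership scale (all rows identical) returns unit weights. Boosting with a
first weak learner already at the guessing boundary falls back to a single
unweighted learner so the ensemble stays usable. JSON reports are written
with sorted keys and no timestamps; the provenance hash covers the
scientific configuration but not output paths, so runs into different
directories remain byte-comparable.

## Problem sizes

Default study sizes — 283 × 18 questionnaire (three 6-item factors, loadings
0.7, 5% contamination), 50-seed recovery/robustness studies at n = 500, and
20 × 1000-subject fusion cohorts — were chosen so planted effects sit well
inside estimator resolution while a full run stays in the seconds range.

## Known limitations

The fuzzy membership rule is one of many reasonable robust weightings; no
claim of optimality is made. Polychoric correlations, confirmatory models,
missing data, IRT, and rotation-aware retention rules are out of scope. The
valence maps and the self-test operationalization are declared conventions,
not estimated quantities. Accuracy figures quoted anywhere in this
repository are properties of the synthetic conditions, not of any real
screening population.
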