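# smht — dual subjective–objective mental-health assessment toolkit

`smht` builds and validates a Likert mental-health screening scale and fuses
it with two *subjective* affect channels — free-text sentiment and speech
prosody — into a single calibrated risk score. It is aimed at researchers in
psychometrics and occupational health who want a fully reproducible,
synthetic-data test bed for this kind of dual-channel assessment design
(the motivating population is seafarers, whose mental-health screening is
complicated by small samples and strong response biases).

## What is inside

**Outlier-robust ("fuzzy") exploratory factor analysis.** Classical EFA
estimates the item correlation matrix with equal weight per respondent;
aberrant response vectors distort the factor structure. The fuzzy variant
iterates a membership-weighted mean

  FE(F) = Σₖ xₖ Uₖ / Σₖ Uₖ,  Uₖ = 1 / (1 + (dₖ/s)²),

where dₖ is the distance of standardized respondent k from the weighted mean
and s a median-distance scale, then eigendecomposes the weighted correlation
matrix: loadings L = (√λ₁ e⃗₁, …, √λₖ e⃗ₖ), Kaiser retention (λ > 1),
least-squares factor scores F = (LᵀL)⁻¹Lᵀ(x − FE(F)). Sampling adequacy is
checked with KMO and Bartlett's sphericity test.

**Psychometric validation suite.** Cronbach's α = K/(K−1)·(1 − Σσ²ᵧᵢ/σ²ₓ),
test–retest reliability and criterion validity (one shared Pearson kernel),
critical-ratio item discrimination (Welch t between high/low rest-score
groups), skew/kurtosis normality screening, Flesch reading-ease readability,
and five-point vote weighting for candidate scale dimensions.

**Affect channels.** A from-scratch multinomial Naive Bayes sentiment
classifier over {negative, objective, positive} strengthened by multi-class
AdaBoost (SAMME, αₜ = ln((1−εₜ)/εₜ) + ln(K−1)) whose weighted vote maps to a
valence score in [0, 1]; a pluggable Gaussian prosody scorer over six
emotions (neutral, happy, sad, angry, fearful, surprised); and a word-error
-rate metric for an upstream speech-to-text stage.

**Weighted fusion.** Components oriented as distress in [0, 1] are combined
as Σwᵢcᵢ/Σwᵢ with default ratio 6 : 1.5 : 3.5 (objective : text : speech);
decisions use a 0.5 threshold, and the *calibration rate* is the relative
accuracy improvement of the fused decision over the scale-only decision
against interview ground truth.

**Synthetic-data generators** plant known structure in every channel (latent
common-factor Likert responses with outlier contamination, retest pairs
hitting a target reliability, criterion scores hitting a target validity,
class-conditional unigram text, Gaussian prosody, multi-channel cohorts with
a binary ground-truth state), so every downstream stage is tested against a
known truth.

## Worked example

```bash
python analysis/01_simulate_data.py --seed 0     # writes results/data/
python analysis/02_factor_structure.py --seed 0
```

prints

```
KMO = 0.851  (>= 0.6 acceptable, >= 0.9 marvellous)
Bartlett chi2(153) = 1792.7, p = 2.17e-277
retained 3 dimensions (eigenvalues > 1: [4.38 3.   2.69]), cumulative contribution 55.9%
recovery: k=3 retained in 100% of 50 seeds, mean aligned loading RMSE 0.036
robustness (5% outliers at 4 SD): fuzzy beats classical in 100% of 50 seeds (RMSE 0.059 vs 0.097)
```

KMO 0.851 and the vanishing Bartlett p say the simulated 283 × 18 item matrix
is factorable; the Kaiser rule finds exactly the three planted dimensions;
and under 5% contamination the fuzzy extraction's loading error (0.059) beats
the classical one (0.097) in every replicate. Continuing,

```bash
python analysis/03_scale_validation.py --seed 0
python analysis/05_fusion_calibration.py --seed 0
```

reports α = 0.875, test–retest R = 0.878 (target 0.87), criterion r = 0.655
(target 0.65), and for the 1000-subject cohorts a fused accuracy of 0.867
versus 0.827 for the scale alone — a +4.87% calibration rate, with the
degenerate weighting (1, 0, 0) collapsing exactly to scale-only decisions.

The same pipeline is scriptable through the CLI (`smht run --config
configs/demo.json`) or the library (`smht.run_pipeline`).

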