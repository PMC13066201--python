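# Methods

This note documents the models and procedures implemented in `hostscent`,
the choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## Scientific setting

Polyphagous fruit flies (Tephritidae) must solve two olfactory problems at
once: *detect* host fruit of many species, and *discriminate* between those
species. Fruit volatilomes overlap partially — some compounds are emitted by
a single fruit species, others by nearly all of them — so the tuning of the
peripheral olfactory system with respect to a compound's *sharedness* among
host fruits determines how well each function can be served. The package
implements the computational side of this question: a synthetic volatilome
generator, the preprocessing chain from abundance matrices to model stimuli,
the sharedness index, a random olfactory-receptor (OR) ensemble model with
detectability / discriminability / joint-functionality scoring, and the
partial-correlation statistics used on antennal-response tables.

## Synthetic volatilome generator (`hostscent.synthetic`)

The generator emulates a multi-species GC–MS headspace survey at the aligned
abundance-matrix level (no chromatogram or peak simulation).

Structure and defaults:

- **28 fruit species**, each with 3–8 replicate samples drawn with weights
  giving a median of 7 replicates (≈ 190 samples per condition).
- **600 compounds** by default (the analysis drivers use 511 for intact and
  665 for sliced fruit, the scale of the real survey). Each compound carries
  a chemical class (drawn from a 16-class vocabulary dominated by esters and
  terpenoids), an atmospheric lifetime (log-normal around 24 h) and a
  depletion rate (log-normal, order 1) used only as covariates downstream.
- **Sharedness structure.** The number of emitting species per compound is
  drawn from a truncated geometric distribution on 1…27 with success
  parameter 0.12, giving the long-tailed sharedness profile (many
  species-specific compounds, a declining tail up to near-universal ones)
  with a single knob; emitting species are then assigned uniformly without
  replacement. The empirical distribution of emitting-species counts in real
  fruit data is not published at this granularity, so the truncated
  geometric is an explicit modelling stand-in, exposed in the configuration.
- **Abundances** are log-normal: per-compound base level (ln-scale mean 10,
  sd 1.5), a species-level offset (sd 1.0), and a sample-level offset
  (sd 0.45). Within an emitting species, a compound appears in a sample with
  probability 0.8. Between-species sd > within-species sd reproduces the
  low within- relative to between-species variability of real volatilomes
  (asserted on generator output in the tests, not claimed of real fruit).
- **Controls.** 20 blank-bag control samples carry only a 5% subset of
  "contaminant" compounds at elevated levels (ln-scale +1 over the compound
  base), exercising the control filter.
- **Intact vs sliced** are paired datasets: the sliced condition has a
  superset of the intact compounds (factor 665/511) and a detection
  probability raised by 0.1, reflecting wound-induced volatiles.
- **Seeding.** A master seed spawns fixed per-stage substreams (metadata,
  design, noise, controls), recorded in the dataset metadata; regeneration
  is bit-identical.

What the generator does **not** emulate: correlated emission of compounds
within chemical classes, phylogenetic autocorrelation between related fruit
species, ripeness and storage effects, or instrument drift. Passing tests on
this data therefore show that the analysis machinery behaves as specified
under the assumed statistical structure — not that real fruit data would
yield the same coefficient values.

### Antennal-response fixture

`generate_eag_table` constructs a long (individual × compound) response
table with a *known* partial correlation between log response and
sharedness, controlling for atmospheric lifetime, depletion rate and
chemical class. Sharedness is residualized on those covariates at the
compound level, and the regression coefficient is set to
`rho / sqrt(1 − rho²) · noise_sd / sd(residual)`, so the population partial
correlation equals the target. Covariate effects are linear in the controlled
variables (hence removed exactly by the estimator), individual offsets are
Gaussian (sd 0.3), and the log-scale construction is exponentiated so the
shift-selected Box–Cox step downstream is meaningful.

## Preprocessing (`hostscent.preprocess`)

Order-fixed chain:

1. **Control filter.** A compound is excluded when a one-sided rank-sum test
   supports control > fruit abundance at α = 0.05. The exact null
   distribution is used when both groups have ≤ 10 observations and no ties;
   otherwise the normal approximation with tie correction. Compounds absent
   everywhere are retained and flagged untestable; exclusions are monotone
   in α and α = 0 excludes nothing.
2. **Geometric-mean normalization** per sample over its positive entries;
   zeros stay zero.
3. **Box–Cox (λ = 0.014) + Pareto scaling.** Only positive (detected)
   entries are transformed — Box–Cox is undefined at 0 and the olfactory
   model treats absence as "no stimulus", so zeros become a distinguished
   absent marker (NaN), never dose 0. Pareto scaling is per compound
   (column), the metabolomics convention: centre on the mean, divide by the
   square root of the standard deviation; zero-variance columns are centred
   only and flagged.
4. **Dose mapping.** Detected transformed values are mapped affinely onto
   the 0–5 log-unit stimulus range: global minimum → 0, global maximum → 5.
   The anchors can be supplied externally so paired intact/sliced runs share
   one scale. How the original analysis placed normalized abundances on its
   0–5 scale is not documented; the global min–max affine map is this
   package's explicit choice, as is applying the full Box–Cox/Pareto chain
   before the mapping. A degenerate all-equal matrix maps to 2.5 and is
   flagged.

## Sharedness index (`hostscent.sharedness`)

For one compound with per-species detection proportions `p_s`, the index is
the Shannon entropy (natural log) of `q_s = p_s / Σ p_s`. For 0/1 vectors it
equals ln k exactly for k emitting species, so it spans 0 (one species) to
ln 28 ≈ 3.33. Proportions are renormalized before the entropy, mirroring the
standard ecology diversity routine (cross-checked against R vegan's
`diversity` and `scipy.stats.entropy` in the tests). Subset variants (e.g. a
13-species host subset, maximum ln 13 ≈ 2.56) restrict the proportion vector
first; compounds absent from the whole subset are flagged absent (NaN)
rather than scored 0, because 0 means "exactly one species", not "none".

## Olfactory model (`hostscent.olfactory`)

One model = `n_ors` OR units (10 or 20; each unit stands for all sensory
neurons expressing one receptor). Each OR detects a fixed number of
compounds drawn without replacement from the full compound universe,
independently across ORs — a compound may drive several ORs or none.
Per (OR, compound) pair:

- threshold `t ~ Uniform(0, 5)` log-dose units;
- dynamic-range width `w` log-normal with **natural-scale** mean 3 and
  sd 1. The alternative reading (underlying-normal μ = 3, σ = 1) would give
  a mean width of ≈ 33 log units, far beyond the 5-unit dose range, and is
  rejected; the underlying parameters are σ² = ln(1 + (1/3)²),
  μ = ln 3 − σ²/2.

Activation of an OR by a compound at log dose d is the clamped ramp
`clip((d − t)/w, 0, 1)`; absent compounds contribute 0. OR activity combines
compound activations as `1 − Π(1 − x)`, keeping activity in [0, 1]
(saturation); the antennal (EAG) response is the unweighted sum of OR
activities, bounded by `n_ors`. Thresholds may exceed `5 − w`, leaving some
pairs unsaturatable within the dose range; nothing truncates them. Models
serialize to JSON for exact replay, and per-model RNG substreams derive from
the ensemble master seed and model index.

## Ensemble analysis (`hostscent.ensemble`)

The full grid is 2 OR counts × 3 compounds-per-OR levels (10/20/60 for
10 ORs, 5/10/30 for 20 ORs) × 2 input conditions, 10,000 models per cell =
120,000 models. Per model:

- **Detectability** = Σ EAG responses over all volatile samples.
- **Discriminability** = out-of-bag proportion of samples correctly
  assigned to fruit species by a random forest (default 1000 trees) on the
  per-sample OR-activity vectors. The source description of this index
  ("opposite of the out-of-bag scores, i.e. the number of correctly
  classified samples divided by the total") is self-contradictory; this
  package uses the proportion correct, 1 − OOB error, so that larger is
  better. Two engines compute the statistic: R `ranger` (batched over the
  ensemble in a single R process; the default — on these small matrices it
  is several-fold faster) and scikit-learn's `RandomForestClassifier`;
  hyperparameters beyond tree count are each library's defaults, and a test
  asserts the engines agree. A constant response matrix returns chance level
  (1/28) and is flagged degenerate.
- **Joint functionality** = product of the two indices after each is
  standardized over the ensemble and mapped to `0.5 + z·s` with
  `s = 0.5/max|z|` — guaranteeing mean 0.5 and range within [0, 1]. The
  phrase "standard deviation adjusted for values between 0 and 1" admits
  alternatives (e.g. clipping a fixed-sd rescale); the max-|z| scaling is
  recorded here and configurable in principle via the function itself.
- **r_prob** = point-biserial (Pearson) correlation between the 0/1
  detection indicator and sharedness over the whole universe.
- **r_amp** = Pearson correlation between single-compound EAG amplitude and
  sharedness over *detected* compounds, computed separately at four probing
  doses {1.25, 2.5, 3.75, 5.0} (even coverage of the range; the original
  doses are unpublished). Models with undefined correlations (constant
  indicator, < 3 detected compounds, zero response variance) are flagged
  NaN and excluded listwise from fits, with counts reported.

Indices and correlations are z-scored within each configuration cell before
cross-cell pooling. `tradeoff_fit` regresses each z-scored index on
z(r_prob), z(r_amp) and their interaction (OLS via statsmodels) and reports
the mean r_prob / r_amp among top-decile models per index. The qualitative
trade-off signature on synthetic data: top-decile *detectability* models
have above-mean r_prob and r_amp (tuned to shared compounds), top-decile
*discriminability* models below-mean (tuned to species-specific compounds).
The exact F statistics of the original 120,000-model screen depend on the
deposited fruit data and full-scale cells and are not reproduction targets.

## Partial-correlation statistics (`hostscent.stats`)

- **Shift-selected Box–Cox.** A constant c (positive or negative, keeping
  x + c > 0) is sought by bounded scalar minimization of |λ̂(c)|, where λ̂ is
  the maximum-likelihood Box–Cox exponent; the transform is declared
  log-equivalent when |λ̂| ≤ 0.05 (the source states no bracket; the
  tolerance is recorded in the output) and ln(x + c) is returned together
  with a Shapiro–Wilk W statistic. If no c qualifies, the best c is used
  and flagged.
- **Residualization.** Qualitative factors (individual, chemical class, …)
  are removed from every quantitative variable by least-squares residuals on
  intercept + drop-first dummies. Single-observation levels fit exactly
  (residual 0). By Frisch–Waugh, the subsequent partial Pearson correlation
  given the residualized quantitative covariates equals the full-design
  computation; tests verify this against precision-matrix inversion and
  `pingouin.partial_corr`.
- **Bootstrap.** Case resampling of observation rows (the resampling unit is
  the row; the source states only "bootstrap, 1000 samples"), percentile 95%
  CI, and a two-tailed p = 2·min(P̂(θ* ≤ 0), P̂(θ* ≥ 0)) floored at 1/B. An
  estimator undefined on > 20% of resamples is an error. For the
  antennal-recovery pipeline the bootstrap runs on a pre-assembled numeric
  design (identical estimator, dummy expansion done once).

## Problem sizes in the test suite and analysis drivers

The package's own study conditions for verification runs: the default
28-species / 600-compound volatilome; trade-off screens of 500 models per
cell over 10 master seeds at 200 trees; structural comparisons at 150
models per cell (RF) and 5,000 models (correlation independence, no RF);
recovery studies of 200 antennal tables (20 individuals × 30 compounds,
B = 1000). The analysis drivers default to 300 models per cell across the
full 12-cell grid. These scaled ensembles preserve the screen's design —
cell structure, z-scoring, listwise exclusion — at sizes a single desktop
core handles comfortably; full-scale runs only require raising `n_models`.

## Known limitations

- The sharedness profile of real fruit volatilomes enters only through the
  truncated-geometric stand-in; absolute index distributions differ from
  the deposited data.
- The olfactory model has no OSN heterogeneity, adaptation, temporal
  dynamics or glomerular gain — deliberate simplifications of the modelled
  system itself.
- The discriminability statistic inherits random-forest Monte-Carlo noise;
  at 200 trees the per-model sd is ≈ 0.01–0.02, which the ensemble-level
  analyses average over.
- `generate_eag_table` covers a single dose per table; multi-dose designs
  (as in the dose-interaction analyses of real recordings) would need the
  table concatenated over doses.
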