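# Methods

This note documents the models implemented in `protolex`, their
assumptions, the defaults that matter, and the numerical and design choices
made where more than one convention was defensible.

## Phoneme representation

The shipped inventory (`protolex/data/inventory_maori.tsv`) has ten
consonants — two of them written as digraphs (`ng`, `wh`) — and five vowel
qualities with short and long (macron-marked) counterparts, twenty phoneme
symbols in all.  Orthography is tokenized greedily left-to-right with
longest match, so digraphs and macron-marked vowels each yield one symbol;
case is folded first.  Each symbol counts as one phoneme for stimulus
lengths (a long vowel is one phoneme, not two).  Legality for this open
syllable CV language means no consonant clusters and a vowel-final form;
written consonant clusters such as `w`+`h` are orthographically
indistinguishable from the digraphs, which is why legality-constrained
generation never produces them and round-tripping is only guaranteed for
legal forms.

Vowel-length collapse replaces each long vowel with its short counterpart.
A model trained "collapsed" applies this mapping to its training sequences
and to every form it scores; the *visual* presence of a macron in a
stimulus is carried separately as a binary covariate, so a rater can be
insensitive to length phonotactically yet sensitive to the diacritic.

## Trigram phonotactics

Training sequences are padded with two start boundaries and one end
boundary, making word onsets and offsets first-class trigram events.
Counts accumulate weights: weight 1 per type for dictionary statistics, or
the corpus frequency per type for token-stream statistics — mathematically
identical to training on the literally expanded stream, without
materializing it.  Conditional probabilities use add-k smoothing,

    P(s | s₋₂, s₋₁) = (c(s₋₂, s₋₁, s) + k) / (c(s₋₂, s₋₁, ·) + k·V),

with default k = 0.01 (configurable) so nonwords always receive finite
scores; with k = 0 an unseen trigram yields an explicit −∞ score rather
than being dropped.  V is the outcome alphabet: all twenty inventory
symbols plus the end boundary, *also* for collapsed models.  Keeping the
alphabet fixed means collapsed and uncollapsed models agree exactly on
corpora without long vowels; the smoothed mass a collapsed model leaves on
long-vowel outcomes is negligible at the default k.

The phonotactic score is the mean log₂ probability per trigram
(L + 1 trigrams for a form of L phonemes).  Length normalization is used
because stimuli range over 3–12 phonemes and an unnormalized sum would
confound score with length.

**Parsed scoring.**  Under a morph-trained model a stimulus may be scored
at its best segmentation: a dynamic program over split points maximizes
the *total* log-probability, each segment scored as an independently
padded sequence, and the maximum is divided by the total number of trigram
terms (L + number of segments).  Normalization is global, over the whole
parse, not per segment; this convention is the package's choice where both
are defensible, and it keeps parsed and unparsed values on the same
mean-log₂ scale.  Ties break toward fewer segments, then leftmost-longest,
so output is deterministic; the DP state carries (score, segment count,
segment lengths) and is verified against exhaustive enumeration of all
2^(L−1) split patterns for L ≤ 8 in the tests.

## Stimulus construction

Nonwords are sampled symbol-by-symbol from a smoothed trigram model until
the end boundary and rejected unless they have exactly the target length,
pass legality, and are new (not in the lexicon or among earlier items);
the rejection budget defaults to 10,000 attempts.  Because nonwords come
from the same model that scores them, they span a similar score range as
the words.  Real-word stimuli are sampled stratified across the frequency
ranking, after trimming the extreme 1% tails of the word score
distribution — a word far outside the score range that sampling can reach
would be unmatchable, and curated stimulus sets avoid such outliers.
Words are ranked by descending corpus frequency into five equal bins
(remainder to the most frequent bins).  Matching is greedy without
replacement: each word takes the unused nonword of equal phoneme length
minimizing the absolute score difference, subject to a tolerance of 0.25
mean-log₂ units (configurable; the matcher is greedy rather than an
optimal assignment because it is deterministic and near-optimal for the
pool sizes used, 4 or more nonwords per word).  A participant list samples
30 pairs per bin without replacement and shuffles the pooled 300 items so
paired items are not adjacent.

## Ordinal models

Ratings 1–5 are modeled with proportional-odds cumulative-link logit
models, P(Y ≤ k) = logistic(τₖ − xᵀβ).  The logit link is the default (the
latent noise of the synthetic raters is logistic, so the fitted model is
exactly the generative one).  Design matrices have no intercept — the
cutpoints absorb it; categorical terms are treatment-coded against their
first level, and `a:b` denotes elementwise interaction.

During optimization the cutpoints are reparameterized as τ₁ plus positive
log-transformed increments, which enforces their ordering without
constraints.  `fit_clm` starts from β = 0 with cutpoints at the marginal
cumulative logits and runs BFGS with analytic gradients on the
per-observation mean deviance to a gradient norm below 1e-6.  Standard
errors come from the observed information (finite differences of the
analytic gradient at the optimum).  `fit_clmm` adds one Gaussian random
intercept per participant, integrated out by adaptive Gauss–Hermite
quadrature: per likelihood evaluation the posterior mode of each
participant's intercept is found by a safeguarded Newton iteration
(vectorized across participants, warm-started between evaluations) and the
default 15 Hermite nodes are centered and scaled at the mode; refining to
31 nodes changes the log-likelihood by < 1e-3 on the default synthetic
data.  The outer optimization is L-BFGS-B on (β, τ, log σ); a variance
collapsing to the lower bound is reported as a boundary fit, not an error.
AIC is 2p − 2ℓ with the random-intercept variance counted as one
parameter, and AIC comparisons are structurally restricted to fits of the
identical response vector.

At 30 participants the maximum-likelihood σ̂ has sampling sd of roughly
σ/√(2G) ≈ 0.13, so variance-recovery checks use 200 participants × 50
items, where the estimator's own noise is small against the tolerance;
slope recovery is checked on the 30 × 240 design.  Fitting a *pooled*
fixed-effects model to mixed-generator data attenuates slopes by roughly
1/√(1 + 0.346 σ²) — expected behaviour, which is why slope recovery under
random intercepts is assessed with the mixed fitter.

## Monte Carlo subsampling

Vocabularies (type sets) are drawn under three schemes: `unweighted`
(uniform without replacement), `frequency_weighted` (sequential weighted
sampling without replacement, implemented with exponential sort keys,
inclusion biased toward frequent types), and `n_highest_frequency`
(deterministic top-N, ties broken by entry order).  Sampling is without
replacement in all cases because the output is a vocabulary — a set of
types.  Per replicate: subsample → retrain the trigram model → rescore and
re-standardize the stimuli → refit the per-group cumulative-link model →
record AIC.  Replicate seeds derive from the master seed by a counter-based
scheme (scheme index, size index, replicate), so runs are bit-for-bit
reproducible and order-independent.  Fit failures are recorded as NaN;
more than 5% failures in a cell aborts.  Summaries report per-cell mean
AIC, 95% bootstrap percentile intervals of the mean (1,000 resamples,
seeded), and the difference to the full-source baseline.  The Monte Carlo
stages use the fixed-effects fitter; headline analyses use the mixed
fitter — at hundreds of replicates the fixed-effects fit is what keeps the
grid tractable, and the comparison is within-group either way.

## Synthetic ground truth

The generator emulates the study conditions at desk scale: a random
legality-constrained trigram grammar produces 2–5-phoneme morphs (long
vowels down-weighted to a quarter of the short-vowel mass, so macrons are
present but minority); words concatenate 1–3 morphs with probabilities
(0.50, 0.35, 0.15) — concatenation of legal morphs is automatically legal —
with morph reuse skewed by a Zipf(0.8) law so some morphs recur across
many words; duplicate forms merge; token frequencies follow Zipf(1.0) over
generation rank (most frequent type ≈ 10n tokens).  Defaults are 1,200
morphs / 4,000 words, anchored to the full-scale shape of ~3,600 morphs /
~18,700 words at desk cost; the large Monte Carlo world uses 2,000 /
10,000.

Raters are drawn from the latent-utility model
u = α_p + β_g·z(score) + δ·word + γ·macron + ε with α_p ~ N(0, σ_p²) and
standard-logistic ε; the rating is 1 plus the number of cutpoints below u.
Defaults: β = 1.5 for the two exposed groups and 0.3 for the unexposed one
(echoing the near-identical steep slopes vs the shallow one), δ = 1,
γ = 0.3, σ_p = 1, cutpoints (−2.25, −0.75, 0.75, 2.25); desk-scale group
sizes 30/12/24 preserve the study's participant ratios.  All magnitudes
are synthetic defaults, not estimates of anything.  A Gaussian-noise
switch exists solely as a misspecification stressor.  Because the
generator *is* the fitted model family, passing recovery tests shows the
machinery is correct and the comparisons identifiable — it does not show
that real ratings follow a proportional-odds model, that real lexical
statistics are this separable, or anything about effect sizes in real
populations.  The generator also does not simulate acquisition dynamics,
item-level random variation beyond the score covariates, or rater
exclusion artifacts.

## Problem sizes and runtime

Default test and analysis scale: 150–400 stimuli, 15–33 simulated
participants per analysis, Monte Carlo grids of 3 schemes × 4 sizes × 100
replicates (the published protocol's 1,000 replicates are a configuration
flag away), 20-replicate recovery suites.  The full test suite runs in a
few minutes on one CPU; `scripts/acceptance.py` takes about a minute.

## Known limitations

- One random-effect grouping factor (participant); crossed participant ×
  item effects are out of scope, with item covariates standing in for
  by-item structure.
- Greedy matching can fail where an optimal assignment would succeed;
  pool enlargement and outlier trimming make this rare at defaults.
- Quadrature handles a scalar random intercept; random slopes would need a
  different integrator.
- Morph frequency in a morph inventory counts occurrences (a morph twice
  in one word counts twice, weighted by word frequency); a type-based
  switch is provided since either convention is defensible.
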