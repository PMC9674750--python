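# Methods

This note documents the models and procedures implemented in `crossmap`,
the assumptions behind them, the choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish
about real data.

## The mapping model

The core object is a linear map `M` from a language space (distributional
word vectors, dimension `d_lang`) to a visual feature space (CNN-style
per-image activations, dimension `d_vis`, reduced to `d′` by truncated
SVD).  `M` minimises the summed squared error `Σ ‖v − M·l‖²` over training
pairs — a multivariate linear regression with no intercept: the model
family is deliberately the simplest possible, so that any zero-shot
success is attributable to the geometry of the two spaces rather than to a
flexible learner.  Because the map is linear it applies to *any* word
vector, including words with no images; that extrapolation is the point.

**Solver.**  `numpy.linalg.lstsq` with a relative singular-value cutoff of
1e-10 — a rank-revealing pseudoinverse, deterministic and robust to
rank-deficient inputs.  A ridge penalty is available behind a flag
(`ridge=0` by default) because ill-conditioned synthetic spaces otherwise
fail noisily; it is never on in any default path.  An optional flag
length-normalises language vectors before fitting (default off; nothing in
the model requires unit-norm inputs, and cosine-based evaluation is
scale-free anyway).

**Regimes.**  *Prototype*: one training pair per label, the arithmetic
mean of its image vectors.  *Exemplar*: `k` individual image vectors per
label (default `k = 20`).  SVD reduction of the visual side (default
target `d′ = 300`) is computed separately per regime, since the exemplar
matrix has `k`× the rows and a different spectrum.  Exemplars are drawn
from the post-cap inventory (after the ≥100/≤200-images-per-label
filtering), which is the natural reading of the pipeline's order.

**SVD conventions.**  Reduced rows are `U_k S_k`; new vectors project via
`V_k`.  Each right singular vector's sign is fixed so its
largest-magnitude component is positive — geometry is unaffected, but
serialized models become byte-reproducible.  `target_dim` may exceed the
numerical rank (trailing components are numerically zero), not
`min(n, d)`.

**Retrieval.**  Exemplar scheme: argmax cosine between the prediction and
every image vector.  Prototype scheme: argmax cosine between the
prediction and the prototypes, then — within the winning label — argmax
cosine between the *prototype* and its images (the second stage ranks
images by typicality of their category, not by similarity to the
prediction).  Cosine is used in every stage for consistency; all ties
break lexicographically so retrieval is deterministic across platforms.

## Neighborhood metrics

For a target word `w` and the set of `n` visually grounded training
labels `t_i`: the count of training labels among the `k = 50` nearest
neighbors; the competition rank (1-based, ties share the minimum rank,
target excluded from its own ranking) and cosine of the nearest training
item; and the mean rank / mean cosine over all training items,
`mts(w) = (1/n) Σ cos(w, t_i)`.  Ranks are computed within whatever
lexicon is supplied.  A target that is itself a training label is excluded
from its own profile with a warning — these metrics are meant for words
outside the training set.

## Item selection

**Five-condition design.**  Candidates are nouns with frequency strictly
between 100 and 12,000, present in the language space and outside the
training set; an optional familiarity screen on a known-proportion column
is available.  A median split on concreteness assigns ratings *at* the
median to the abstract side (an arbitrary but documented and tested tie
rule).  Conditions: far = random seeded draws from the zero-visual-
neighbor words (both sides); abstract/near and concrete/maximum = the 23
words with the most visual neighbors on each side; concrete/near = the
23-word subset of the remaining concrete words whose mean count best
matches the abstract/near mean.  Because neighbor counts are small
integers, that matching is solved *exactly* by a subset-sum dynamic
program (choose 23 items whose count total is closest to the target
total) rather than greedily — cheap, deterministic, and provably optimal.

**Binned decorrelation sampler.**  Both covariates (concreteness, mean
training-item similarity) are cut into `n_bins = 10` equal-width bins over
their observed ranges (the maximum closes into the top bin); from each
cell inside a selection window at most `per_cell = 4` items are drawn
uniformly, undersized cells contributing everything.  The achieved Pearson
r of the selection is reported next to the pooled r.  One property is
worth stating because it is easy to get wrong: with *no* window, capped
per-cell sampling over a bivariate-Gaussian pool does **not** decorrelate
— the occupied cells form an elliptical region, and a uniform fill of an
ellipse has exactly the ellipse's correlation.  Decorrelation comes from
restricting to a central rectangular window of cells, inside which the
grid is densely populated, so the selection approximates a uniform fill of
a rectangle.  The default window is "all cells" (the window's boundaries
are an experimental-design choice, not derivable from the data); the tests
and the acceptance script demonstrate decorrelation with the central 6×6
window `((2,7),(2,7))`, which shrinks r ≈ 0.53 pools to ≈ 0.24 in every
replicate.

**List splitting.**  A seeded random partition into maximally even lists
(sizes differ by ≤1): 371 items over 3 lists gives 124/124/123.

## Synthetic worlds

The generator stands in for the heavyweight inputs (a trained embedding
space, CNN features for hundreds of images per label, human norms) so the
pipeline runs and is tested entirely offline.  It emulates three
structural facts:

* **Concreteness-coupled geometry.**  Words are unit directions
  interpolated between a word-specific random direction and the centroid
  direction of the training labels, with interpolation weight
  `w = clip(0.42 + 0.16·z, 0.02, 0.9)` where `z` is a standard-normal
  latent correlated `ρ` with concreteness.  Because mean training-item
  similarity is a smooth, nearly linear function of `w`, the realised
  correlation between concreteness and `mts` lands within ±0.1 of `ρ`
  (verified across seeds).  The default `ρ = 0.53` matches the
  concreteness–groundedness correlation observed in real lexicons.
* **A planted linear map.**  Each training label's images are
  `v = l·M* + Normal(0, noise_sd)` with a hidden `M*` kept on the returned
  world object, so end-to-end recovery is testable: at `noise_sd = 0` the
  fitted map reproduces `M*` to numerical precision and held-out zero-shot
  retrieval is essentially perfect; accuracy decays monotonically in
  `noise_sd`.
* **Choice behaviour.**  2AFC responses follow
  `logit P = β₀ + β_c·x_c + β_n·x_n + β_cn·x_c·x_n + u_participant + u_item`
  with centred normal random intercepts; 10 catch trials per participant
  are answered correctly with probability `1 − catch_error_rate`.
  Defaults (`β_c = 1.09`, `β_n = 0.8` per far→near→maximum step,
  `τ_p = τ_i = 1`, 55 participants) are of the magnitude seen in real
  experiments of this kind: condition effects around 1 logit and combined
  random-intercept variance near 2, i.e. a conditional R² near 0.4–0.5.

**Scale.**  Defaults are desk-scale: 1000 words, 50 language dimensions,
64 visual dimensions, 200 training labels × 25 images, noise 0.5.  The
real pipeline's counts (7801 labels, 20 exemplars → 156,020 pairs,
400×300 map) are exercised exactly in the design-arithmetic checks with
low-dimensional features, where the counting identities are
dimension-independent.

**What passing tests do not show.**  The generator has one global grounded
cluster, isotropic noise, no polysemy, no frequency-dependent embedding
quality, and a perfectly linear true map.  Synthetic success therefore
demonstrates the correctness of the machinery (estimation, retrieval,
selection, inference), not that real language and vision spaces are
linearly alignable.  One concrete consequence of the single-cluster
geometry: training labels crowd everyone's neighborhoods, so
zero-visual-neighbor ("far") words only exist when the training fraction
is small and the neighborhood size `k` modest — the simulation CLI
exposes `--k` for that reason.

## Mixed-effects logistic regression

`MixedLogit` fits `logit P(y=1) = x'β + u_p + u_i` with crossed random
intercepts by maximising the Laplace approximation to the marginal
likelihood — the standard estimator for this model class.  Random effects
are parameterised as `u_g = τ_g·b_g` with standardised `b_g`, which keeps
the objective smooth at `τ = 0` so variance components can collapse to
zero without numerical trouble.  The inner problem (the mode of `b` at
fixed `(β, τ)`) is solved by damped Newton iterations with a dense
Cholesky of the `q×q` penalised Hessian (`q` = participants + items, a few
hundred at most); the outer problem maximises the Laplace log-likelihood

`ℓ(β, τ) = ℓ_data(η̂) − ½‖b̂‖² − ½ log det(I + Λ'Z'WZΛ)`

over `(β, τ)` jointly with L-BFGS-B (bounds `τ ≥ 0`), matching the
estimator used by the reference implementations of this model; the
package's estimates agree with R's `lme4::glmer` to ~1e-2 on coefficients
and variance components (cross-checked in the test suite).  Wald standard
errors come from the fixed-effect block of the inverse penalised Hessian
at the optimum, conditional on `τ̂` — the conventional choice.  Quasi-
separation is flagged (extreme linear predictors or standard errors) and
the fit marked non-converged rather than silently returned.

**Designs.**  Treatment coding with abstract/far as the reference level.
In the five-condition design the maximum level exists only on the concrete
side, so the concrete×maximum product is aliased with the maximum dummy;
the interaction term therefore contributes a single parameter
(concrete×near), and dropping "visual neighbors" removes two (near,
maximum) — degrees of freedom in the likelihood-ratio tests count exactly
these columns.  In the continuous design both covariates enter linearly
plus their product; shifting covariates to a zero minimum (for an
interpretable intercept) provably changes only the intercept, a fact the
tests verify on refits.

**Backward elimination.**  Interaction first (marginality), then the
remaining main effects, at each round removing the term with the largest
LRT p-value if `p ≥ α = 0.05`, refitting, and stopping when everything
left is significant.  `X² = max(0, 2Δℓ)` with df = the parameter-count
difference.

**Variance explained.**  Marginal R² = `σ²_f / (σ²_f + Στ² + π²/3)` and
conditional R² = `(σ²_f + Στ²) / (same)`, with `σ²_f` the variance of the
fixed-effect linear predictor over the observed design and `π²/3` the
logistic residual variance.

**Exclusions.**  Participants answering fewer than 8 of 10 catch trials
correctly are dropped entirely; catch rows never enter the analysis table;
an exclusion log records every participant's catch score and fate.

## Numerical and procedural conventions

* All randomness flows through explicitly seeded `numpy` generators; every
  sampling operation is a pure function of (inputs, parameters, seed).
* Neighbor and retrieval ties break lexicographically; rank ties share the
  minimum (competition) rank; equal-frequency label contests in
  multi-label resolution go to the alphabetically earlier label.
* Cosine with a zero vector raises — it is never silently 0.
* The word2vec text reader demands the header and exact row counts;
  malformed files fail with the offending line, never a guess.
* Inner Newton tolerance 1e-10 on the penalised log-likelihood; outer
  finite-difference step 1e-5; LRT statistics clamped at 0.

## Problem sizes used in the checks

Oracle and calibration checks run at sizes where the independent oracle is
exact or the Monte-Carlo error is controlled: 50×8→6 regressions against
the normal equations; 100-label spaces against full-sort neighbor oracles;
200-word planted worlds with 30 held-out labels; 200 null replicates of
12×24 trials for the LRT type-I rate; 40 replicates of 60×100 trials for
Wald coverage; 9 replicates of 35-participant five-condition experiments
for the elimination patterns.  These sizes make the whole suite run in a
few minutes while keeping every binomial check's standard error well
inside its asserted margin.

## Known limitations

* The Laplace approximation is mildly conservative at very small group
  counts (the type-I rate of the LRT sits near 0.03–0.07 rather than
  0.05 at 12 participants); this matches the behaviour of the standard
  implementations of the same estimator.  Likewise, Wald intervals are
  conditional on the estimated variance components and so run a little
  below nominal coverage (≈0.90–0.95 observed at 60 participants × 100
  items for a unit effect).
* No by-participant random slopes: with one observation per
  participant×item cell they are weakly identified and routinely fail to
  converge; the model class is fixed at crossed random intercepts.
* The synthetic world is a single-cluster, linear, isotropic idealisation
  (see above); it is a test harness, not a model of a lexicon.
* The exemplar regime's memory footprint grows as
  `labels × k × d_vis`; at the real-data scale users should stream or
  down-sample rather than materialise the raw 4096-dimensional matrix.
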