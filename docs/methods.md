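# Methods

This note records the statistical model behind each stage of `funclink`,
the conventions and tunable parameters, what the synthetic-data generator
does and does not emulate, and the numerical choices that were genuinely
open.

## Trait preparation and functional distances

Trait tables carry a schema marking each column continuous, ordinal,
nominal or binary, with an optional `ln_transform` flag (used for strongly
right-skewed variables such as geographic range size; the transform
requires strictly positive values and errors otherwise, naming the
offending species). Continuous and ordinal columns are standardized to
zero mean and unit variance with the **sample (n−1) denominator**; ordinal
traits are first mapped to integer ranks via their declared level ordering,
because they sit naturally on a graded scale and only truly unordered
(nominal) traits are dummy-coded — one 0/1 column per level. Constant
columns are kept as zeros with a warning rather than dropped, so column
bookkeeping stays stable.

Gower distances are computed **on the prepared matrix** (scaled columns +
dummies), each column normalized by its observed range and zero-range
columns skipped: `d(i,j) = (1/p) Σ |x_ik − x_jk|/range_k`. Range
normalization makes the distance invariant to affine rescaling of any
single column (tested), and dummy columns contribute symmetric mismatch
terms. Missing values are disallowed rather than pairwise-deleted — the
generator never produces them, and silent pairwise deletion changes the
effective weighting per pair in ways that are hard to audit.

Environmental variables come in three categories (vegetation, temperature,
precipitation), at least two raw variables each. Each category is reduced
to the first principal component of the correlation matrix (variables
standardized before the SVD). The PC1 sign is fixed so the composite
correlates positively with the category's mean raw variable, making
"higher composite = greener / warmer / wetter" readable in every model
downstream; the explained-variance fraction and loading signs are returned.

## Functional trees

Trees are built by canonical Saitou–Nei neighbour joining on the Gower
matrix. Ties in the Q-criterion are broken by the smallest (i, j) pair in
input label order, making the construction deterministic across platforms.
Negative branch-length estimates (possible on non-additive input) are
clamped to zero and the clamped mass recorded on the tree. On additive
input the patristic distances reproduce the input exactly; the test suite
verifies this to 1e-8 on hundreds of random additive trees and
cross-checks against an independent neighbour-joining implementation.

The final three-way join node is retained as the reference root: the
branch-based beta decomposition needs a rooted orientation, and this is how
the construction output is naturally stored. With two taxa the single edge
is split at its midpoint by the root; path lengths are unaffected. A
`reroot: none | midpoint` switch documents the sensitivity but defaults to
the construction root.

## Alpha components

For region r with species set S_r, the minimal spanning subtree of the
functional tree induced by S_r has branch-length multiset B_r, and

- richness = Σ B_r (equals the patristic distance for two species, and the
  total tree length for the full pool),
- divergence = mean B_r,
- regularity = dispersion of B_r.

Regularity is reported twice: as the **population (n denominator) variance**
of branch lengths — the literal quantity — and as the bounded evenness
`1/(1 + CV²)` ∈ (0, 1], which *increases* as branch lengths become more
even and is the form used in regressions by default
(`regularity_metric: evenness | variance`). The two differ in direction:
variance grows with irregularity while "regularity" as a concept shrinks,
so the evenness transform preserves interpretability of signs in the
comparative stage. Singleton regions get richness 0 and NaN
divergence/regularity with an explicit flag — they carry no branch
information and are excluded from downstream regressions rather than
imputed. An independent brute-force oracle (union of all leaf-pair paths,
edge by edge) backs every component.

## The region pseudo-phylogeny and PGLS

Treating regional diversity values as independent observations is biased:
the same species occur in many regions. The remedy replaces the phylogeny
of classical comparative methods with a **dendrogram of regions**: flea and
host incidence matrices are concatenated column-wise, Bray–Curtis
dissimilarity computed between regions (for binary rows this is
1 − 2a/(2a+b+c)), and a complete-linkage dendrogram built. The dendrogram
becomes an ultrametric tree with **leaf depth = merge height / 2**, so the
patristic distance between two regions equals their cophenetic merge
height — the convention is fixed by this testable equivalence. Zero-height
merges (identical regions) are permitted and yield zero-length branches.

Generalized least squares then uses the Brownian-motion covariance
`C_ij = depth(MRCA(i,j))`, `C_ii = total depth`:
`β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y`, σ² by maximum likelihood (n denominator),
t statistics on n−k degrees of freedom with the unbiased residual variance.
If C is numerically singular (duplicate regions), a jitter of
1e-10·mean(diag C) is added and logged. Only plain Brownian motion is
implemented — no Pagel's λ or Ornstein–Uhlenbeck — matching the plain usage
this pipeline mirrors.

Forward stepwise selection starts from the intercept-only model and adds
the candidate with the largest AIC decrease (AIC = 2k − 2 logLik, k
counting coefficients plus σ²) until no addition helps. Plain AIC is used,
not AICc. A known property follows: an independent noise predictor enters
with probability ≈ P(χ²₁ > 2) ≈ 0.16 (slightly higher at n ≈ 30), so with
several pure-noise candidates the intercept-only model survives only about
half the time. The test suite freezes this Monte-Carlo-verified behaviour
rather than a stricter rate the procedure cannot deliver.

Residual spatial autocorrelation is tested with Moran's I under
row-standardized inverse great-circle-distance weights (a `knn` scheme is
available): I = (n/W) Σ w_ij z_i z_j / Σ z_i², E[I] = −1/(n−1), variance
from the standard randomization moments with a normal-approximation
two-sided p. Coincident coordinates make inverse-distance weights
undefined and raise an error suggesting jitter.

## Branch-based beta diversity

Each region's branch set K_r collects the edges on the root-to-leaf paths
of its species, weighted by branch length. With a = shared length,
b and c = lengths unique to either region, the dissimilarity is the Ochiai
complement `1 − a/√((a+b)(a+c))` — the incidence member of the
Gower–Legendre S12 family, chosen because incidence (not abundance) data
drive the whole pipeline. No square-root transform is applied to the
complement. Identical regions give 0; regions whose species hang on
opposite sides of the root give 1. Geographic distances are haversine
great-circle distances with mean Earth radius 6371.0 km.

## Generalized dissimilarity modelling

Observed dissimilarities d_ij ∈ [0,1] are modelled as
`μ_ij = 1 − exp(−η_ij)` with
`η_ij = a₀ + Σ_p Σ_{k=1..3} b_pk f_pk(i,j)`, all coefficients (including
a₀) constrained non-negative. Each predictor gets **three order-3
(degree-2) I-splines** with knots at the 0th/50th/100th percentiles of its
observed values — three splines because the importance/height tables report
three coefficients per predictor, and the quantile-knot rule keeps the
basis data-adaptive. Scalar (per-region) predictors contribute
`|I_k(x_i) − I_k(x_j)|`; matrix predictors (host functional dissimilarity,
geographic distance) pass their pair distance through an I-spline with
knots on the distance distribution. Environmental composites enter as site
values (differences taken internally), the convention for scalar
predictors; constant predictors are dropped with a warning.

Fitting minimizes the binomial-form deviance
`D = 2 Σ [d ln(d/μ) + (1−d) ln((1−d)/(1−μ))]` (limit terms at d ∈ {0,1};
μ clipped to [1e-10, 1−1e-10]) by iteratively reweighted non-negative
least squares on the link scale with step-halving, converging when
|ΔD| < 1e-8 (max 100 iterations; non-convergence returns the last iterate,
flagged). Deviance explained = 100·(1 − D_model/D_null) with the
intercept-only null. The non-negativity constraint makes every fitted
transform non-decreasing from 0 at the predictor minimum, and the height
(coefficient sum) of each transform is the total turnover attributable to
that gradient holding the others fixed.

Predictor importance permutes region identities **for that predictor
only** — site values for scalars, rows and columns jointly for matrices,
preserving within-predictor structure — refits, and reports the mean
percent decrease in deviance explained over `n_perm` permutations
(default 100); the p-value is the fraction of permutations with deviance
explained at least the full model's, and the model-level p permutes all
predictors jointly. Importance of an irrelevant predictor can be slightly
negative by chance and is reported as computed; it is undefined (error)
when the full model explains no deviance.

## The synthetic realm generator

The generator emulates the *structure* of regional survey data: 15–40
regions on a jittered grid spanning 20° latitude × 40° longitude (so
great-circle geometry is meaningfully non-Euclidean); six environmental
variables, two per category, each a linear function of the spatial
gradients plus Gaussian noise; hosts with two 3-level discretized traits,
three continuous traits (one ln-flagged and exponentiated), and one 3-level
nominal trait, all derived from a latent 6-dimensional standard-normal
profile; and fleas with the canonical flea schema (ctenidia and body-size
ranks, three continuous ecological traits, 3-level microhabitat).

Coupling is controlled by two parameters:

- `theta_match` ∈ [0,1]: flea latent traits are
  `theta_match · (kernel-weighted mean of compatible hosts' profiles) +
  (1 − theta_match) · noise`, weights `exp(−d²/0.5)` in latent distance.
  Each flea is compatible with the nearest 25% of the host pool around a
  preference profile (a jittered copy of its principal host's profile).
  The kernel weighting keeps a flea's traits close to the hosts it actually
  uses; an unweighted mean over the whole compatible set over-smooths the
  trait field and erases most of the recoverable signal.
- `theta_env` ≥ 0: a flea passes the environmental filter of region r with
  probability `exp(−theta_env · ||position_r − optimum_f||²)`; expected
  flea richness is non-increasing in `theta_env` (tested).

Two design choices isolate *trait-mediated* coupling from species-count
artefacts, which is the property the whole test battery leans on:

1. **Fixed regional host richness.** Each region holds exactly half the
   host pool, sampled without replacement with probabilities proportional
   to logistic environmental suitability. Regional host functional
   diversity therefore varies compositionally, not through richness. With
   Bernoulli occupancy instead, flea and host functional richness correlate
   strongly (r ≈ +0.5) even with traits fully decoupled, purely through
   species counts — a confound, not a recovery signal.
2. **Principal-host occupancy.** A flea occurs where its principal host
   occurs (and the environmental filter passes). The principal host is a
   member of the compatible set, so a flea is present only where a
   compatible host is present. Gating on "any compatible host" instead
   couples flea counts to host trait dispersion through compatibility-ball
   coverage, biasing the decoupled case; gating on the principal host makes
   flea counts hypergeometric-stable and leaves trait identity as the only
   channel. Principal-host assignments are balanced across the host pool.

Measured with the full observed-trait pipeline (80 replicates): at
`theta_match = 0`, the mean flea–host functional-richness correlation is
−0.02 (no spurious coupling); at `theta_match = 0.9` the PGLS slope of
flea on host richness is positive in ≈98% of replicates, and host
functional dissimilarity is the top-ranked GDM predictor in ≈96–97% of
realms.

What the generator does **not** emulate: real trait distributions and their
phylogenetic conservatism (there are no phylogenies at all), abundance
(incidence only, as in the target analyses), sampling effort artefacts,
realm-scale differences in species-pool size, and spatial autocorrelation
of flea occurrence beyond the environmental filter. Passing recovery tests
therefore demonstrates that the *chain of estimators* recovers known
coupling under realistic data shapes, not that any particular empirical
realm satisfies the generator's assumptions.

## Problem sizes and runtime conventions

The test suite and the acceptance script choose deliberately modest problem
sizes — realms of 15–40 regions and 14–60 species per taxon, 80–500
Monte-Carlo replicates, 20–100 permutations per importance estimate —
which keep every calibration within seconds to a couple of minutes while
leaving Monte-Carlo standard errors well inside the asserted bands. All
stochastic stages take explicit seeds, and every seed is recorded in the
serialized outputs.

## Known limitations

- The GDM reports point fits and permutation tests only; no confidence
  bands for the I-splines and no prediction to unsampled sites.
- Stepwise selection inherits plain AIC's ≈16% false-entry rate per noise
  candidate; users wanting stricter parsimony should filter on the reported
  per-coefficient p-values or use the selection path.
- Moran's I weighting (inverse distance vs k-nearest-neighbour) is a
  convention, not an inference; p-values shift between schemes.
- The branch-based beta decomposition depends on the tree's rooting; the
  construction root is used throughout, with midpoint rerooting exposed as
  a config switch but not further analysed.
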