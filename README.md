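# funclink

Linking the functional diversity of parasites to the functional diversity
of their hosts and to the off-host environment, across the regions of a
biogeographic realm.

`funclink` implements the full inference chain used in comparative studies
of flea–small-mammal systems, where the question is whether the functional
structure of regional parasite assemblages tracks the functional structure
of regional host assemblages:

1. **Mixed-trait preparation and Gower distances.** Species × trait tables
   mix continuous, ordinal, nominal and binary variables. Flagged columns
   are ln-transformed, continuous/ordinal columns standardized, nominal
   traits dummy-coded, and pairwise functional distances computed as the
   range-normalized Gower distance
   `d(i,j) = (1/p) Σ_k |x_ik − x_jk| / range_k ∈ [0,1]`.
2. **Functional trees.** A neighbour-joining tree built from the Gower
   matrix places species at the tips; its branches are the functional
   diversity units of every downstream quantity.
3. **Functional alpha diversity.** For each region, the species present
   induce a minimal spanning subtree; functional **richness**,
   **divergence** and **regularity** are the sum, mean and dispersion of
   its branch lengths (dispersion is reported both as the raw variance and
   as the bounded evenness `1/(1+CV²)`).
4. **Pseudo-phylogenetic GLS.** Regions are not independent — the same
   species recur across regions. A dendrogram of regions (Bray–Curtis on
   the combined flea+host incidence, complete linkage) is treated as an
   ultrametric pseudo-phylogeny; flea components are regressed on host
   components and environmental PCA composites by generalized least squares
   under the Brownian-motion covariance `C_ij = depth(MRCA(i,j))`, with
   forward stepwise selection by AIC and Moran's *I* residual diagnostics
   (inverse great-circle-distance weights).
5. **Functional beta diversity.** Each region is represented by the set of
   functional-tree branches on the root-to-leaf paths of its species;
   between-region dissimilarity is the branch-length-weighted Ochiai
   complement `1 − a/√((a+b)(a+c))` (the Gower–Legendre S12 family member
   for incidence data).
6. **Generalized dissimilarity modelling.** Flea functional dissimilarity
   is regressed on host functional dissimilarity, environmental composites
   and great-circle geographic distance through the link
   `μ = 1 − exp(−η)`, with every predictor transformed by three monotone
   I-splines with non-negative coefficients fitted by iteratively
   reweighted non-negative least squares on the binomial-form deviance.
   The height (coefficient sum) of each I-spline measures the total
   functional turnover along that gradient, and predictor importance is the
   percent drop in deviance explained when that predictor's region
   identities are permuted.

A synthetic-realm generator (`funclink.simulate`) produces realistic realms
— jittered-grid regions, gradient-plus-noise environments, hosts with mixed
traits and logistic environmental niches, fleas whose occurrence follows
their principal host and whose traits are coupled to host traits with
tunable strength `theta_match` and filtered by the environment with
strength `theta_env` — so every stage of the chain has a ground-truth
recovery test.

## Worked example

```python
import pandas as pd
from funclink import *

realm = simulate_realm(n_regions=24, n_hosts=26, n_fleas=22,
                       theta_match=0.8, theta_env=0.5, seed=42)

flea_tree = nj_build(gower_distance(prepare_traits(realm.flea_traits)))
host_tree = nj_build(gower_distance(prepare_traits(realm.host_traits)))
flea_alpha = alpha_components(flea_tree, realm.flea_incidence).table
host_alpha = alpha_components(host_tree, realm.host_incidence).table

region_tree = region_pseudotree(realm.flea_incidence, realm.host_incidence)
env = env_composites(realm.env, realm.env_categories)
candidates = pd.DataFrame({"host_richness": host_alpha["richness"]}).join(env.scores)
fit = phylostep_forward(flea_alpha["richness"].to_numpy(),
                        candidates.loc[region_tree.regions],
                        bm_covariance(region_tree))
print(fit.params.round(3))

flea_beta = functional_dissimilarity(flea_tree, realm.flea_incidence)
host_beta = functional_dissimilarity(host_tree, realm.host_incidence)
pairs = build_site_pairs(flea_beta, scalar_predictors=env.scores,
                         matrix_predictors={"host_beta": host_beta,
                                            "geographic_distance": great_circle(realm.coords)})
gfit = gdm_fit(pairs)
print(f"GDM deviance explained: {gfit.deviance_explained:.1f}%")
imp = var_importance(pairs, n_perm=50, seed=42, fit=gfit)
print(imp.table.round(2))
```

which prints

```
                coef     se      t      p
intercept      0.263  0.748  0.352  0.729
vegetation     0.235  0.071  3.289  0.004
temperature   -0.178  0.068 -2.631  0.016
host_richness  0.621  0.394  1.577  0.130
GDM deviance explained: 73.3%
                     importance  p_value
vegetation                -0.44     0.54
temperature               -0.56     0.98
precipitation              0.47     0.24
host_beta                 14.94     0.00
geographic_distance        2.47     0.00
```

The stepwise PGLS keeps host functional richness plus two environmental
composites (the positive host slope, 0.62, is the trait-coupling signal;
the realm was generated with `theta_match=0.8`), and in the GDM the
permutation importance of host functional turnover dwarfs every
environmental gradient, with geographic distance a distant second — the
pattern the generator encodes.

The same pipeline is scriptable from the shell via the `funclink` CLI
(`simulate`, `prep-traits`, `build-tree`, `alpha`, `region-tree`, `pgls`,
`beta`, `gdm`, `varimp`); every artifact is plain CSV/Newick/JSON.

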