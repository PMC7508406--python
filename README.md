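# relaxsel

Phylogenetic multilevel meta-analysis of how antipredator traits change
across generations of human contact.

When animals live near or with humans — in cities, in captivity, or under
domestication — predation pressure relaxes, and traits that evolved to
avoid predators (flight-initiation distance, vigilance, alarm calling,
stress physiology) are expected to decay in their mean and, transiently,
to inflate in their between-individual variability. `relaxsel` implements
the full analysis pipeline for testing this relaxed-selection hypothesis
on meta-analytic trait data: trait harmonization, nonlinear trajectory
fitting, Bayesian multilevel meta-regression with phylogenetic random
effects, model ranking by DIC, and heterogeneity partitioning. A
first-class synthetic-data generator emulates the statistical structure of
such datasets so every stage is testable without any external download.

## The model

Trait means (z-standardized within context × study × trait) are modelled
across generations *x* of human contact with an inverse-decay curve

    f(x) = y_ini + k · aˣ,       0 < a < 1,

where *y_ini* is the asymptote, *k* the initial offset and *a* the
per-generation decay factor. The absolute coefficient of variation
|CV| = |SD/mean| follows a baseline-plus-bump curve built from a scaled
Weibull density,

    g(x) = y_ini + a · (k/λ) · u^(k−1) · e^(−u^k),   u = (x − t_min)/λ,

which rises after the onset *t_min* and then declines — the signature of a
transient variance inflation under relaxed selection. Both curves are
fitted by CMA-ES (covariance matrix adaptation evolution strategy)
minimizing the weighted mean absolute error, best of 5 restarts.

The fitted shape is then tested in a Gaussian mixed model

    y = Xβ + Σ_l Z_l u_l + e,    u_phylo ~ N(0, σ²_phylo A),
    Var(e_i) = σ²_e / w_i,

with random levels study, species, phylogeny (A = Brownian correlation
matrix from an ultrametric tree) and trait type, sampled by a blocked
Gibbs sampler with inverse-Wishart (V = 1, ν = 0.02) variance priors.
The basis-covariate slope tests the curve's fit; 95% credible intervals
excluding zero are read as significant. Life-history interaction models
(foraging guild, sociality, maximum longevity) are ranked by DIC weights,
and heterogeneity is partitioned into per-level I² shares plus the
phylogenetic heritability H² = σ²_phylo / (σ²_phylo + σ²_species).

## Worked example

```python
from relaxsel import (
    default_config, simulate_dataset, standardize_dataset,
    fit_inverse_cmaes, generations_to_asymptote,
)
from relaxsel.mixed import MCMCConfig, significance_of_fit
from relaxsel.phylo import read_newick, prune_tree, phylo_correlation

ds = simulate_dataset(default_config(seed=7))
std, _ = standardize_dataset(ds.records)
dom = std[std.context == "domestication"]

fit = fit_inverse_cmaes(dom.generation, dom.standardized_mean,
                        dom.weight, seed=7)
print(fit.params)
print(round(generations_to_asymptote(fit.params, fraction=0.05), 1))

tree = prune_tree(read_newick(ds.newick), set(dom.species_id))
summary, _, _ = significance_of_fit(
    dom, fit.params, MCMCConfig.scaled_down(seed=7),
    phylo=phylo_correlation(tree),
)
print(summary[summary.term == "basis"][["post_mean", "lower", "upper",
                                        "pMCMC", "significant"]])
```

prints

```
InverseParams(y_ini=-0.9386120293001561, k=2.528531640150839, a=0.9047582983972019)
29.9
   post_mean    lower     upper     pMCMC  significant
1   2.515986  2.48186  2.549028  0.000556         True
```

The fitted decay factor `a ≈ 0.905` means the trait loses ~9.5% of its
remaining excess per generation; with the 5% criterion the asymptote is
reached after ~30 generations of domestication. The basis slope's 95%
credible interval excludes zero, so the decay is significant after
accounting for study, species, phylogenetic and trait-type effects.

The same pipeline is available from the shell:

```bash
relaxsel simulate --out data/ --seed 7
relaxsel fit data/records.csv --curve inverse --context domestication --seed 7
relaxsel run --config pipeline.yaml --out results/
```

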