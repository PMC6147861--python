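# lupine

Cryptic population structure analysis for diploid microsatellite data.

Continuous wildlife populations — wolves are the motivating case — can hide
strong, geographically coherent genetic subdivision without any obvious
barrier or phenotypic difference. Detecting that structure, classifying
individuals as admixed or non-admixed, mapping each genetic group's
territory, counting dispersers, and estimating recent migration between
groups together require a chain of methods usually spread across half a
dozen single-purpose programs. `lupine` implements that chain as one tested
Python package:

* **Bayesian admixture clustering** (Gibbs sampler; independent or
  correlated/F-model allele frequencies), replicate alignment
  (label-switching resolution), the **Evanno ΔK** model-choice table, and
  hierarchical re-clustering; a PCA + k-means (DAPC-style) alternative with
  a BIC curve.
* **Gap-based classification** of individuals into non-admixed / admixed /
  unassigned from their membership proportions `q_i`, with per-cluster
  cut-offs placed in the largest gap of the membership distribution.
* **Population-genetic statistics**: He/Ho/F, rarefied allelic richness and
  private allelic richness `AR(g)`, `pAR(g)`, Lynch–Ritland pairwise
  relatedness, Weir–Cockerham θ (= AMOVA ϕST) with permutation tests,
  Jost's D, Monte-Carlo exact HWE and LD tests with Bonferroni correction,
  and a Mantel isolation-by-distance test on shared-allele distances.
* **Spatial structure**: minimum convex polygons per genetic group
  (`P_total` over all attributable members, `P_non_admixed` over non-admixed
  ones), disperser detection (non-admixed individuals sampled outside their
  own group's polygon), nearest-border distances, and overlap counting
  between collared animals' home-range polygons (`P_s`) and group
  territories.
* **Recent migration rates** between groups via a two-generation Bayesian
  assignment model (Metropolis-within-Gibbs; per-individual posteriors over
  resident / first- / second-generation migrant states), with
  credible-interval edge lists.
* A **synthetic-data generator** that draws genotypes from the correlated
  F-model (`p_kl ~ Dirichlet(π_l (1−F_k)/F_k)`), places territories as discs,
  plants dispersers and collar-track excursions, and returns full ground
  truth for recovery testing.

In the standard notation: `q_ik` is individual i's membership in cluster k;
`ΔK = |L''(K)| / sd(L(K))` with `L(K) = mean ln Pr(X|K)` over replicate
runs; θ is the Weir–Cockerham multiallelic fixation index; `AR(g)` is the
expected allele count in a rarefied sample of g gene copies; `m[l][q]` is the
fraction of group l composed of migrants from group q per generation, with
`m[l][l] ≥ 2/3` by model constraint.

See `docs/methods.md` for the models, priors, numerical choices, and the
limits of what the synthetic benchmarks demonstrate.

## Worked example

```python
import numpy as np
from lupine import (SimConfig, simulate_dataset, fit_admixture,
                    align_replicates, detect_cutoffs, classify_individuals,
                    build_group_polygons, diversity_summary)

# a wolf-shaped dataset: 11 clusters (6-53 individuals), 46 loci,
# 7 planted dispersers
table, metadata, truth = simulate_dataset(SimConfig(seed=17))

runs = [fit_admixture(table, K=11, iterations=1500, burn_in=500, seed=s)
        for s in range(3)]
_, q, similarity = align_replicates(runs)
part = classify_individuals(q, detect_cutoffs(q))
geom = build_group_polygons(part, metadata)

print(f"replicate similarity: {similarity:.3f}")
print(f"non-admixed: {part.labels.count('non_admixed')}/{table.n_samples}")
print(f"dispersers detected: {len(geom.dispersers)}")
div = diversity_summary(table, [str(k) for k in truth.true_cluster])
print(f"mean He across the 11 groups: {div.He.mean():.3f}")
```

Output (seed 17):

```
replicate similarity: 0.960
non-admixed: 163/207
dispersers detected: 7
mean He across the 11 groups: 0.569
```

Reading: the three MCMC replicates agree almost perfectly after label
alignment; about three quarters of individuals sit above their cluster's
gap cut-off (non-admixed); all 7 planted dispersers are recovered as
non-admixed individuals located outside their own group's territory; and
per-group expected heterozygosity is moderate, as configured by the
generator's drift parameter.

A command-line interface mirrors the library:
`lupine simulate | validate | select | cluster | classify | stats | spatial |
migrate` (see `lupine --help`).

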