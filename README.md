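# seednet

Network-based candidate disease-gene discovery. `seednet` implements, as a
tested and reusable pipeline, an integrative analysis for nominating new
disease genes from known ones: it intersects a weighted gene co-expression
network with a protein–protein interaction (PPI) network, extracts the
subnetwork connecting known disease genes ("seeds") with the limited
k-walks random-walk algorithm, prioritizes the recruited "linker" genes by
a ranking score, and validates candidates by expression correlation and
survival-risk stratification. The design follows the pancreatic-cancer
candidate-gene workflow built on STRING interactions and TCGA tumor
expression, and ships the published seed and linker tables as packaged
reference data.

It is aimed at computational biologists who have a seed-gene list, an
expression matrix and a PPI edge list, and want a deterministic,
scriptable version of this workflow — plus a synthetic-cohort generator
for validating every stage against planted ground truth.

## The method

**Common network.** From a genes × samples expression matrix, pairwise
Pearson correlations *r* are soft-thresholded into an adjacency
*a* = |*r*|<sup>β</sup> (β = 1 by default, so weights are |*r*|); edges above an
absolute threshold are kept, with the correlation sign retained as
metadata. The co-expression edge set is intersected with the PPI edge set
(STRING links, `combined_score`/1000 as weight); surviving edges carry
the co-expression weight.

**Limited k-walks.** For each seed *s*, a random walk starts at *s* with
transition probabilities P(i→j) = w<sub>ij</sub>/Σ<sub>k</sub> w<sub>ik</sub> and is absorbed by
any other seed; walks longer than a budget *L* are discarded. Edge
relevance is the conditional expected number of traversals,

E<sub>s</sub>(i,j) = (1/Z<sub>s</sub>) Σ<sub>l=0</sub><sup>L−1</sup> [α<sub>l</sub>(i)·P(i→j)·β<sub>L−l−1</sub>(j) + α<sub>l</sub>(j)·P(j→i)·β<sub>L−l−1</sub>(i)],

where α<sub>l</sub> are forward occupation masses, β<sub>m</sub> backward absorption masses
and Z<sub>s</sub> = β<sub>L</sub>(s) the absorption probability. Relevances are averaged
over start seeds with Z<sub>s</sub> > 0, and the subnetwork is assembled from the
highest-relevance edges until the seeds are connected. An exhaustive
walk-enumeration oracle (`brute_force_relevance`) verifies the recursion
on small graphs.

**Ranking score.** Each linker *g* in the subnetwork gets
RS(*g*) = Σ<sub>(g,h)</sub> m·w(g,h) with m = 2 when *h* is a seed;
candidates are linkers with RS strictly above a cutoff (RS > 1 in the
published analysis) or the top-k by rank.

**Validation.** Seed–candidate Pearson correlations (t-reference p,
Benjamini–Hochberg adjusted), Welch t-tests against binary clinical
covariates, and survival stratification: per-sample signature sums are
split at the median and the two arms compared by the log-rank test
(computed as the score test at β = 0 of a one-covariate proportional-
hazards model, cross-checked against `lifelines`).

## Worked example

`examples/01_reference_table_selection.py` applies the selection step to
the packaged published tables:

```
seed genes:          52
linker genes:        82
subnetwork nodes:    134
max ranking score:   1.6
candidates (RS > 1): BARD1, KRT19, MST1R, LGALS1, S100A14, RNF168
```

52 seeds plus 82 recruited linkers form the 134-node extracted
subnetwork; exactly six linkers exceed RS = 1 (two more sit exactly at
1.0 and are excluded by the strict inequality) and become the candidate
genes.

`examples/03_synthetic_pipeline.py` runs every stage on a generated
cohort (5 seed + 5 planted linker genes sharing a latent factor among
300 background genes, 100 samples) and checks the result against the
planted truth:

```
stage counts:
  coexpression_network: {"nodes": 10, "edges": 45}
  common_network: {"nodes": 10, "edges": 35}
  kwalks_subnetwork: {"nodes": 10, "edges": 12, "seeds": 5, "linkers": 5, "L": 50}
planted linkers:  ['LINK01', 'LINK02', 'LINK03', 'LINK04', 'LINK05']
top-5 candidates: ['LINK01', 'LINK02', 'LINK03', 'LINK04', 'LINK05']
precision at 5:   1.00
survival log-rank p: 2.19e-08 (n retained 91)
```

The ranking recovered all five planted linkers, and the signature's
median split separates survival sharply because the planted module
factor drives the hazard. The other examples cover the k-walks toy
(`02`) and the survival stage on a 179-sample cohort (`04`).

A thin CLI wraps the same library calls:

```bash
seednet generate --seed 0 --out fixture/
seednet run --config pipeline.yaml
seednet rank --subnetwork sub.tsv --seeds seeds.txt
seednet survival --expression expr.tsv --clinical clin.tsv --genes KRT19,BARD1,...
```

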