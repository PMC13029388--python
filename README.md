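# vinherit

Statistical framework for asking whether clonally propagated plants
inherit their mother's microbiome — built around the design used in
vineyard *mass selection*, where scions from old "mother" vines (PM) are
grafted and replanted as "daughter" vines (PF) across several estates
("chateaux"), and both generations are sampled in multiple compartments
(leaf, root, soil) for bacterial (16S) and fungal (18S) amplicon
communities.

The package implements three layered hypotheses on an ASV/OTU count
table with aligned metadata:

* **H1 — what structures the communities.** Alpha-diversity panel
  (Chao1, ACE, Shannon, Gini–Simpson, inverse Simpson, Fisher's α,
  Pielou evenness) with PM-vs-PF Wilcoxon rank-sum contrasts per
  stratum; Bray–Curtis dissimilarity, principal coordinates analysis,
  and PERMANOVA with per-factor R²; LEfSe-style biomarker discovery at
  the family rank.
* **H2 — do daughters resemble their own mother.** Per-stratum
  (chateau × tissue × kingdom) hierarchical clustering (UPGMA), plus a
  quartile statistic: a mother–daughter pair is *clustered* when its
  Bray–Curtis distance falls within the first quartile of the stratum's
  pairwise-distance distribution, with per-chateau proportions and exact
  binomial CIs. Under the no-inheritance null the proportion calibrates
  to 0.25 by construction.
* **H3 — deterministic vs. stochastic assembly.** Abundance-weighted
  βMNTD between paired samples, standardized against a taxa-shuffle null
  into βNTI; the normalized stochasticity ratio (NST, deterministic
  below 50%, stochastic above) per mother–daughter family; and a
  permutation test that repeatedly reassigns daughters to mothers within
  a stratum (family sizes preserved) to Z-score each family's mean βNTI
  or NST against its exchangeability null.

A lineage-structured synthetic-community generator makes the whole
pipeline testable without field data: Yule tree, Brownian-motion taxon
optima (phylogenetic signal), Gaussian environmental filtering with
additive site/compartment/generation shifts, a tunable
vertical-transmission fraction `v` mixing the mother's realized
composition into each daughter, and multinomial sampling at
Poisson-distributed depths.

## Core quantities

For samples *j*, *k* with relative abundances *f*:

* Bray–Curtis: `D_jk = Σ_i |f_ij − f_ik| / Σ_i (f_ij + f_ik)`.
* βMNTD: `½ [ Σ_i f_ij · min_{i′∈k} d(i,i′) + Σ_i f_ik · min_{i′∈j} d(i,i′) ]`
  with *d* the patristic distance; βNTI is its z-score against tip-label
  shuffles.
* NST per pair: with observed similarity `G = 1 − D` and null
  expectation `E`, selection strength `SS = (G−E)/(1−E)` if `G ≥ E` else
  `(E−G)/E`; stochasticity `ST = 1 − SS`; a family's NST is the mean ST
  over its within-family pairs.
* PERMANOVA: Anderson's pseudo-F on the squared-distance partition,
  `R² = SS_between / SS_total`, p by free label permutation.

## Worked example

```python
from vinherit.simulate import paper_preset, simulate_study
from vinherit.beta import bray_curtis, permanova
from vinherit.lineage import classify_pairs, proportions

cfg = paper_preset(n_taxa=80, depth=2000, seed=1, v=0.3)   # 4 estates, 47 mothers, 151 daughters
table, phylo, designs, truth = simulate_study(cfg)

dm = bray_curtis(table)
print(permanova(dm, table.metadata,
                ["compartment", "chateau", "generation"], n_perm=199, seed=1))
```

prints (marginal fits, residual rows omitted):

```
       term  df       R2  p_value
compartment   1 0.860909    0.005
    chateau   3 0.027985    0.010
 generation   1 0.001864    0.400
```

— plant compartment dominates the variance partition, site explains a
few percent, and generation is weak and non-significant, the expected
hierarchy for this design. Continuing with the H2 statistic in one
stratum:

```python
leaf = next(d for d in designs if d.stratum[:2] == ("Latour", "leaf"))
sub = table.subset_samples(sorted({*leaf.mothers, *leaf.daughters}))
print(proportions(classify_pairs(bray_curtis(sub), leaf)))
```

```
                       stratum  clustered  total  proportion   ci_low  ci_high
('Latour', 'leaf', 'bacteria')         38     75    0.506667 0.388639 0.624152
```

With transmission `v = 0.3`, half the mother–daughter pairs sit inside
the first distance quartile — well above the 0.25 expected under no
inheritance.

The same analyses are scriptable from the shell (`vinherit simulate`,
`alpha`, `ordination`, `permanova`, `lefse`, `lineage`, `assembly`), and
`vinherit run --config run.yaml` orchestrates the full H1→H2→H3 flow
with deterministic per-stage seeds, TSV outputs and a JSON manifest.

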