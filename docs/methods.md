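# Methods

This note documents the models, defaults and design choices behind
`vinherit`, in the spirit of a statistical-methods appendix.

## Data model

All stages consume a `CommunityTable`: a taxa × samples matrix of raw
integer counts with aligned per-sample metadata (`chateau` — the
confounded site factor bundling location, practices, cultivar and
rootstock; `compartment` ∈ {leaf, root, soil}; `generation` PM = mother
/ PF = daughter; `lineage`; `vine_id`) and ranked taxonomy. Bacterial
(16S) and fungal (18S) tables are always separate objects; no operation
crosses kingdoms. Counts are oriented taxa-rows × sample-columns; a
transposed file is accepted only when its row labels match the metadata
sample ids, anything ambiguous is an error — silent transposition being
the classic count-table bug. Missing taxonomy ranks are empty strings
and aggregate as `unclassified <parent>`.

The *family* — one mother plus her sampled clonal daughters, within one
chateau × compartment × kingdom stratum — is the exchangeability unit of
every permutation test.

## Synthetic communities

The generator emulates a multi-estate mass-selection study with known
ground truth.

* **Phylogeny.** Yule (pure-birth, rate 1) tree, made ultrametric by
  extending tip branches to the present. Pure birth rather than
  birth–death: one parameter fewer, and extinction adds nothing to the
  phylogenetic signal the assembly analyses need.
* **Traits.** Per-taxon environmental optima evolve by Brownian motion
  (rate `bm_rate`, default 1) from a root value of 0, so related taxa
  prefer similar environments — the signal βNTI-style analyses assume.
* **Environment.** Each sample's scalar environment is an additive
  combination of site (`site_effect`, default 1.2, sites spaced on
  [−1, 1]), compartment (`compartment_effect`, default 3.0; leaf +1,
  root −1, soil −0.5), generation (`generation_effect`, default 0.15;
  PM +½, PF −½) plus Gaussian sample-level noise (`env_noise`, default
  0.4). The defaults encode the qualitative hierarchy the design
  implies: compartment ≫ site ≫ generation.
* **Assembly.** Expected relative abundances follow Gaussian
  environmental filtering,
  `p_i ∝ base_i · exp(−(opt_i − env)² / (2σ_sel²))`, with lognormal(0,1)
  base abundances shared across samples (realistic rank-abundance
  curves). `sigma_sel` (default 1.5) sets selection strength; values
  ≥ 1e9 switch filtering off (neutral regime). Computation is in log
  space so strong selection never underflows to an all-zero weight
  vector.
* **Inheritance.** A daughter's expected composition is
  `v · p_mother_realized + (1 − v) · p_env`: the mixture uses the
  mother's *realized* (sampled) composition, because inheritance
  operates on what the mother actually hosts, not on her expectation.
  Soil samples never mix (soil is not plant tissue).
* **Sampling.** Library sizes are Poisson(`depth`, default 5000) and
  counts multinomial. Every sample owns an RNG stream hashed from
  `(seed, sample_id)`, so enlarging a design never perturbs existing
  samples.
* **Preset.** The four-estate preset uses family structures 15×5, 10×3,
  12×3 and 10×1 (47 mothers, 151 daughters per compartment per
  kingdom). The fourth estate's mother-to-daughter mapping is recorded
  ambiguously in the field design it mirrors; the preset assumes one
  daughter per mother.

What the generator does **not** emulate: nursery-stage filtering as an
explicit process, soil→root→leaf transfer dynamics, overdispersed
(beyond-multinomial) count noise, taxon-specific amplification bias, and
contamination. Passing tests therefore demonstrate correctness of the
statistical machinery under a plausible assembly model, not robustness
to every artefact of real amplicon data.

### Assembly regimes

Two named regimes anchor the calibration experiments:

* **Neutral** — `v = 0`, `sigma_sel ≥ 1e9`: composition is driven by the
  shared base abundances plus multinomial noise only.
* **Strong filtering** — `sigma_sel = 0.2` with `env_noise = 1.0`:
  the selection width is one fifth of the environmental spread, so small
  environmental differences among samples translate into large
  compositional divergence (variable selection). This is the regime in
  which deterministic assembly is detectable as divergence, matching
  the empirically common pattern of positive βNTI deviations. An
  intermediate `sigma_sel` comparable to the environmental spread is
  deliberately *not* used as a calibration regime: there selection and
  drift produce similar pair dissimilarities and NST hovers near its
  threshold.

## Alpha diversity

Chao1 is bias-corrected (`S_obs + F1(F1−1)/(2(F2+1))`), defined even
without doubletons; ACE uses the standard rare-taxon threshold of 10;
Shannon is in nats and Pielou divides by `ln S_obs`; Simpson is reported
as Gini–Simpson (1 − Σp²) alongside its inverse; Fisher's α solves
`S = α ln(1 + N/α)` by bracketed Brent root-finding (tolerance 1e-10).
Indices are computed from raw counts — no rarefaction; library size is
carried as a covariate instead, and relative-abundance input is rejected
because the estimators that need singleton structure are undefined on
it. PM-vs-PF contrasts use the two-sided Mann–Whitney rank-sum test,
exact when both groups have ≤ 20 tie-free observations, otherwise the
tie-corrected normal approximation.

## Ordination and PERMANOVA

PCoA is classical Gower scaling; axes with eigenvalue above `1e-8 × λ_max`
are kept, and the negative-eigenvalue mass is reported without
correction. PERMANOVA offers *marginal* fits (each factor alone — the
form in which single-factor R² values are usually quoted) and
*sequential* Type-I partitions in user order. Permutations are free
(unrestricted) by default, matching common `adonis`-style usage when no
blocking information is given; a `strata` argument restricts shuffles
within levels of a column. A tiny negative residual from floating-point
cancellation under perfect separation is clamped so the pseudo-F
degenerates to +∞ rather than a large negative number. p-values use the
`(1 + exceedances)/(1 + n_perm)` convention.

## Biomarkers

LEfSe-style: aggregate to a rank (family by default), Kruskal–Wallis
screen on relative abundances at α = 0.05 with no multiple-testing
correction (the tool convention), then a bootstrap-averaged (30 rounds,
stratified ⅔ subsamples) linear-discriminant effect size on per-million
abundances, reported as log10 and thresholded at 2. Two deliberate
simplifications relative to the original tool: a single-level class
factor (the contrasts here are generation × tissue, with no subclass
structure), and the effect size is the average of the raw and
discriminant-weighted class-mean gaps per feature — monotone in the gap
and on the familiar 2–5 scale, but not numerically identical to the
original implementation's scores.

## Pair clustering (H2)

Clustering is UPGMA (average linkage) per chateau × tissue × kingdom
stratum; the linkage method is selectable since field reports often omit
it. Samples are sorted lexicographically before linkage so distance ties
resolve deterministically toward the smallest sample id. The quartile
threshold Q1 is the 25th percentile (linear interpolation) of *all*
pairwise distances within the stratum — the same pool the dendrogram is
built from; pooling globally would mix compartment effects into the
threshold. A mother–daughter pair is clustered when its distance is ≤ Q1
(inclusive, so a degenerate all-equal distribution classifies as
clustered). A pool restricted to mother–daughter distances is available
for sensitivity analysis. Proportions carry exact (Clopper–Pearson)
95% CIs.

## Assembly processes (H3)

**βMNTD/βNTI.** Abundances are converted to within-sample relative
abundances before βMNTD; each taxon is matched to its nearest
phylogenetic neighbour present in the partner sample (itself when
shared). The null shuffles taxon labels across all tips of the stratum's
tree with abundances fixed — the standard taxa-shuffle null — with one
shared permutation per replicate across all pairs, and the observed
value is z-standardized. Pairs whose null has zero spread (e.g. two
samples sharing every taxon, including exactly identical communities,
which remain identical under any relabelling) are flagged rather than
scored. βNTI is scale-free: rescaling all branch lengths rescales βMNTD
but leaves the z-score unchanged (verified to 1e-9). Default 999 nulls
in the API; the pipeline default is 199, which changes βNTI standard
errors immaterially at these problem sizes.

**NST.** Pair similarity uses Ruzicka (abundance-weighted Jaccard) by
default, Bray–Curtis selectable. The null ("PF"-style) fixes each
sample's observed richness, draws taxa with probability proportional to
their occupancy frequency, and assigns regional mean relative abundances
to the drawn taxa. Null expectations are computed **once per stratum**
(all samples of the chateau × tissue × kingdom block) and shared across
families. This is a deliberate scoping choice with two benefits: every
family's NST is measured against the same regional null, and the
mother–daughter permutation test can reassign daughters without
recomputing nulls, making the permutation distribution exact relative
to the stored pair-level quantities. Per-pair selection strength is
clamped to [0, 1] before averaging; a flag records when clamping fired.

**Permutation test.** The per-family statistic is the mean βNTI over the
family's mother–daughter pairs, or the mean pair stochasticity over all
within-family pairs for NST. Nulls reassign the stratum's pooled
daughters to mothers uniformly at random, preserving family sizes —
never across strata, since reassigning across chateaux would conflate
the (strong) site effect with the inheritance null. Two-sided p-values
come from centred absolute deviations with the +1 correction; Z-scores
are `(obs − null_mean)/null_sd`; stars mark p < 0.05 / 0.01 / 0.001.
With few families the number of distinct assignments bounds attainable
p from below (two singleton families ⇒ p ≥ ½); degenerate nulls are
flagged, and pair statistics that are undefined (flagged βNTI) are
dropped from null moments rather than propagated.

## Numerical and degenerate-input conventions

* Empty samples: alpha indices become flagged NaN rows, never
  exceptions; βMNTD on an empty profile is an error.
* Zero-sum samples are a named error wherever relative abundances are
  required.
* All-zero taxon rows are retained and flagged at read time.
* All randomness flows through `numpy.random.Generator` seeded
  explicitly; the pipeline derives stage seeds from the global seed and
  the stage name, and the run manifest records seed, parameters and
  package versions.

## Problem sizes used in calibration runs

The test suite and the acceptance script run desk-scale versions of the
calibration experiments: 60–80 taxa, depths near 2000, single-site
strata of 8–10 families with 3 daughters each (≥ 200 families pooled for
type-I calibration), 99–200 null replicates and 199 permutations. These
sizes were chosen so each experiment's Monte-Carlo error is comfortably
inside the asserted bands; the full four-estate preset (47 mothers, 151
daughters per compartment per kingdom) is exercised for the variance
partition, where per-sample cost is lowest.

## Known limitations

* The LEfSe scores are effect sizes on the right scale, not replicas of
  the original tool's numbers; rank-based screens agree exactly.
* NST's null scope (stratum-level) and model ("PF") are package
  defaults; field analyses citing the NST framework sometimes use
  group-level nulls, which would make family NST values incomparable
  across permutations — the manifest records the choice.
* βNTI on pairs sharing their full taxon set is undefined (flagged);
  deep sequencing of small communities makes this more likely.
* The simulator's scalar environment cannot represent interactions
  (e.g. site-specific compartment effects); its additive shifts suffice
  for the variance-partition hierarchy but not for studying interaction
  recovery.
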