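# Methods

This note documents the models, parameter choices and numerical conventions
behind `clonalsnv`, and what the synthetic benchmark does and does not
establish about real resequencing data.

## Variant retention model

A candidate site survives only if three independent callers report the same
`(chrom, pos, ref, alt)` key with identical per-clone genotypes. Positional
overlap alone is not enough: "the same variant" is read as the same call,
so a genotype disagreement in any clone excludes the site. Intersection is
commutative and its output is a subset of each input by construction.

Per-clone evidence filters (all must hold, in every clone, for the site to
pass — sites are filtered, not individual genotypes):

| filter | rule | default |
| --- | --- | --- |
| depth | dp_min ≤ DP ≤ dp_max | [15, 150] |
| VAF genotype | hom-ref ≤ vaf_ref_max; het ∈ [vaf_het_min, vaf_het_max]; hom-alt ≥ vaf_hom_min; anything else is *ambiguous* and fails | 0.025 / [0.25, 0.75] / 0.95 |
| strand bias | two-sided Fisher exact on the 2×2 ref/alt × forward/reverse table; discard at p ≤ α | α = 10⁻⁴ |
| position bias | two-sided Mann–Whitney comparing alt- vs ref-read variant offsets; discard at p ≤ α | α = 10⁻⁴ |
| read edit distance | a read passes iff edit ≤ ⌊length / 25⌋; zero-length reads never pass | 1 per 25 bp |

Two conventions were genuinely open and are fixed as follows. First, the
significance level "p ≤ 10⁻⁴" is read as the *discard* condition: sites
with significantly biased evidence are removed, since retaining them would
defeat the purpose of the filter; the boundary p = α itself is discarded.
Second, the VAF windows apply to every clone at the site, not only to the
variant carrier; a single ambiguous clone fails the whole site.

The named tests are the package's own choice — the convention of the
callers whose output this stage consumes. The Mann–Whitney p is exact when
both samples are ≤ 30 observations and tie-free, and uses the tie-corrected
normal approximation otherwise; two identical constant samples carry no
positional information and return p = 1.

The VAF gap zones are the mechanism that trades chimeric sensitivity for
precision: a heterozygous mutation confined to the L1 layer has expected
VAF 0.5 · f_L1 ≈ 0.2 (at the default f_L1 = 0.4), inside the (0.025, 0.25)
gap, so most of its sampled VAFs fail; an L2-confined mutation at
0.5 · (1 − f_L1) ≈ 0.3 usually passes.

## Classification

For four clones with genotypes in {hom-ref, het, hom-alt} relative to a
reference genome taken as homozygous reference everywhere:

* **SNP** — all four share one identical non-reference genotype
  (cultivar-level variant, no information about clones);
* **SC-het** — one het, three hom-ref; **SC-ref** — one hom-ref, three
  het; **SC-hom** — one hom-alt, the other three *sharing one* state
  (het or hom-ref);
* **Sh-het / Sh-hom** — a 2 + 2 split into exactly two states, the focal
  pair being the one carrying the higher-dosage state;
* **complex** — everything else, including three-state patterns and
  two-state patterns that match no class above (e.g. one het against three
  hom-alt). Complex sites are reported, never silently dropped.

The SC-hom background is required to be uniform: patterns where the other
three clones mix het and hom-ref go to `complex`. This is the stricter of
the two defensible readings and may undercount SC-hom relative to a looser
rule; the full 3⁴ = 81-pattern table is pinned by an independently written
oracle in the test suite.

## Synthetic generator

The generator emulates a two-lineage clonal study design: a founder splits
into an "Ar" and an "Fr" lineage ancestor (internal branches, default 40
years each), and clones hang off them with terminal branches cycling
through (70, 75, 25, 90) years — long-propagated pairs, one young clone and
one divergent clone, mirroring a realistic mix of propagation histories.

Mutations are planted clock-like: per branch, Poisson(μ · years · n_sites)
events, each on a fresh site. μ defaults to 2 × 10⁻⁴ per site per
branch-year — a scaled rate chosen once so that a 10-kb benchmark region
accumulates a few hundred somatic variants and every clone, including the
youngest, contributes enough chip-eligible markers; real per-base somatic
rates are orders of magnitude smaller and would need genome-scale site
counts. Events are heterozygous gains on a hom-ref background, except a
fraction (`loh_fraction` = 0.05) that are losses of heterozygosity at
ancestrally heterozygous sites (founder heterozygosity 0.15, the source of
SNP-class sites), resolving to hom-ref with probability 0.9, else hom-alt.
This is what produces the SC-ref and SC-hom classes without multi-hit
bookkeeping. Transitions are drawn with probability ts/(ts+tv) at the
configured ts/tv = 4.1, so the realized ratio converges by the law of
large numbers. Each mutation is whole-plant, L1-confined (p = 0.1) or
L2-confined (p = 0.2); the layer scales the expected VAF as above.

Read evidence: depth ~ Poisson(30); alt count ~ Binomial(DP, p) with
p = VAF·(1−e) + (1−VAF)·e/3 at per-base error e = 10⁻³; strands Bernoulli
(a strand-bias parameter exists to create filterable sites); offsets
uniform on the 150-bp read. Virtual callers genotype the planted truth,
dropping sites at their false-negative rate (0.05 / 0.08 / 0.10) and
injecting private heterozygous false positives (0.002 / 0.004 / 0.003 per
free site); false positives are caller-private with overwhelming
probability, which is why the three-way intersection removes essentially
all of them.

The chip cohort plants two founder profiles that differ at a configurable
fraction of diagnostic markers (default 0.55 of 41 markers, alternating
between lineages), adds Poisson(0.05) private mutations per sample and
masks entries at the missing rate. What this does **not** model: shared
technical artifacts between callers (correlated false positives),
alignment-induced systematic bias, copy-number variation, sample
contamination, and within-lineage substructure. Passing the benchmark
therefore demonstrates the pipeline's correctness under its stated error
model, not robustness to correlated artifacts.

## Genotype analyses

**Collapsing.** Under the default `match_any` policy a missing entry is
compatible with any state; a sample joins the first non-conflicting group
and resolves the group consensus where it can. This relation is not
transitive, so results are deterministic in sample order (the order of the
input table). A `strict` policy requires identity including missingness.
Genotypes are named MLG01… by descending size, ties by smallest member id.

**Median-joining network.** Each marker is one multistate character with
states {0, 1, 2}; a 0↔2 change is one mutational step (character-state
semantics; a `dosage_steps` flag counts it as two). The network is the
ε-relaxed minimum spanning network (all tied edges kept; ε = 0 default)
augmented with median profiles: per-marker majority of triples that share
a neighbourhood in the current network, accepted when they strictly beat
the triple's best two-edge connection, iterated to closure. Medians of
degree ≤ 2 are pruned. Because accepted medians need not lie on every
pairwise geodesic, median detours can end up longer than a displaced
direct link; after pruning, any observed-backbone minimum-spanning-network
edge whose endpoints are farther apart through the network than directly
is restored, guaranteeing the network contains a spanning structure of
minimum-spanning-tree weight over the observed genotypes.

**Neighbor joining.** Classic Q-criterion agglomeration; ties broken by
taxon input order; negative branch-length estimates are clamped to zero
(the computed pair distance stays on the sibling edge); the final pair is
joined through an arbitrary root with the remaining distance split evenly,
which leaves all leaf-to-leaf path lengths intact. On additive matrices
the generating topology and all path lengths are recovered exactly (tested
against an independent path-length oracle and scikit-bio's NJ).
p-distances treat the het code as a distinct state — R vs A is one
difference like any other — with pairwise deletion of missing characters.
Bootstrap supports resample markers with replacement and report, for each
internal bipartition of the full-data tree, the percentage of replicate
trees containing it (no consensus tree is built). The outgroup is the
all-hom-ref reference genotype; rooting splits its pendant edge at the
midpoint and is idempotent.

**PCoA.** Gower double-centering B = −½ J D J of the *squared* codominant
distance matrix, eigendecomposition, coordinates scaled by √λ; percent
variance is reported over positive eigenvalues only (the codominant
distance is squared Euclidean on dosage vectors, so negative eigenvalues
are numerically negligible).

**AMOVA.** One level, on the squared codominant distance matrix
(per-locus (d_a − d_b)²: 0 / 1 / 4). SS_total = (1/N) Σ_{i<j} d²;
SS_within sums the per-group analogues; V_w = SS_w/df_w;
V_a = (SS_a/df_a − V_w)/n₀ with the unequal-size coefficient
n₀ = (N − Σn_g²/N)/(G−1); Φ_PT = V_a/(V_a+V_w). V_a can be negative under
this method-of-moments estimator; the raw value is retained and Φ_PT is
clamped at 0 for reporting. The p-value permutes individuals among groups
with sizes fixed (the Φ_PT null of the codominant-distance framework; the
term "bootstrap" sometimes attached to this p refers to these label
permutations) and uses (count+1)/(n_perm+1) with 900 permutations by
default.

## Problem sizes and determinism

The benchmark sizes are the package's own defaults: 10,000 sites for the
four-clone resequencing stage, 107 + 107 samples × 41 markers for the
cohort, 200 bootstrap replicates, 900 permutations. The full pipeline runs
in seconds. One global seed fans out to per-stage substreams
(`SeedSequence([seed, stage_index])`), so toggling a stage never perturbs
another stage's randomness and identical configurations give bit-identical
outputs and manifest checksums.

## Known limitations

* Classification is defined for exactly four clones; other designs raise.
* The median-joining search enumerates triples sharing a neighbourhood
  rather than all quasi-median triples; on highly reticulate data it may
  place fewer medians than an exhaustive implementation.
* The AMOVA is single-level; hierarchical designs (regions within groups)
  are out of scope.
* Bootstrap supports on zero-length internal edges of degenerate
  (all-identical) inputs are reported as computed; they reflect
  deterministic tie-breaking, not phylogenetic signal.
* Flank clearance for panel design uses variant positions only; it does
  not model primer thermodynamics or probe specificity.
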