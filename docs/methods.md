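# Methods

## The analysis

Meta-analysis GWAS hits for type 2 diabetes frequently fall outside gene
bodies and carry no obvious mechanism. `locushub` implements an analysis
that asks whether such variants participate in a shared regulatory
architecture: SNPs are first collapsed into linkage-disequilibrium (LD)
blocks treated as single loci, each locus is then connected to other loci
through three evidence layers — physical chromatin contacts
("spatial"), significant trans expression associations ("eqtl"), and
curated protein/phenotype links ("functional") — and finally sets of
GWAS loci that connect directly or through intermediary loci are
reported as *hubs*, together with the bridging paths that explain them.

## Locus definition (LD blocks)

Two SNPs belong to the same haplotype block when their pairwise LD
reaches **r² ≥ 0.8 or D′ ≥ 0.8**; the relation is closed transitively,
so blocks are connected components of the threshold graph. Both
thresholds are configurable. Pairwise LD is only computed for
same-chromosome pairs within a 500 kb window (configurable); a pair
inside the window with no LD entry is an error rather than a silent
non-edge, because the difference between "not in LD" and "LD never
computed" changes the partition.

Standard definitions are used: D = p_AB − p_A·p_B; D′ = |D|/D_max with
D_max = min(p_A(1−p_B), (1−p_A)p_B) for D > 0 and
min(p_A·p_B, (1−p_A)(1−p_B)) for D < 0; r² = D²/(p_A q_A p_B q_B). These
satisfy r² ≤ D′² and both lie in [0, 1], which the test suite fuzzes.

With phased haplotypes, p_AB is a direct count. With unphased dosages it
is the maximum-likelihood estimate from the classic two-locus EM: allele
frequencies are fully observed, only double heterozygotes are
phase-ambiguous, and the single free parameter p_AB is iterated from a
linkage-equilibrium start (tolerance 1e−8, ≤1000 iterations; the
equilibrium start biases likelihood ties toward smaller |D|, a
conservative choice). Note that the EM estimate and the phased count are
*different estimators*: they differ by phase-resolution sampling noise of
order 1/√n even when both are correct, so the suite validates the EM
against an exhaustive-likelihood grid oracle (1e−4) and checks
EM-vs-phased convergence only at large n (0.01 at n = 5000). A
monomorphic SNP has undefined LD; this is signalled distinctly
(`LdUndefinedError`) and treated as "no information", never as an error
or an edge.

Loci are named by the genes their span overlaps, joined with "/" in
genomic order (e.g. `CELSR2/PSRC1`); a span overlapping no gene falls
back to a `chrom:start-end` id. Missing genotypes are removed pairwise
(complete case). Internal coordinates are 1-based inclusive; BED/BEDPE
I/O converts from/to 0-based half-open.

## Trans-eQTL scan and the compound verdict

Each SNP-probe pair is tested per population with a Spearman rank
association on the dosage (0/1/2) against expression. Rho uses average
(tie-corrected) ranks. The two-sided p-value is exact — full
permutation enumeration — for n ≤ 9 and the usual t-approximation with
df = n − 2 above. The t-approximation is known to be off by up to ~0.02
in mid-range p at n = 9, which is why the exact path exists at small n;
at the sample sizes of real panels (n ≳ 50) it is accurate.

The cross-population rule declares a pair **significant** when

1. p < 0.05 in at least three testable populations (*replication*), or
2. p < 0.001 in any single population (*single_pop*),

with replication taking precedence when both fire. No further
multiple-testing correction is applied — the compound rule is the
replication filter — though a Benjamini–Hochberg column is available for
reporting. Populations where the SNP is monomorphic, expression is
constant, or fewer than 5 complete samples remain are *untestable* and
excluded from the count (an untestable population is not p = 1).
Under a global null with continuous p-values the rule's false-positive
rate is exactly

P[(Bin(8, 0.05) ≥ 3) ∪ (min of 8 U(0,1) < 0.001)]
= 1 − Σ_{k<3} C(8,k)·0.049^k·0.95^(8−k) ≈ 0.0134,

and the measured rate on simulated dosage data matches it to within
3 binomial standard errors at 20,000 pairs (the small residual inflation
comes from the discreteness of ranks over three dosage levels under the
t-approximation).

Cis/trans: a pair is *trans* when SNP and probe sit on different
chromosomes or more than 1 Mb apart (common eQTL convention; the window
is configurable and a distance of exactly the window is cis). Unlocated
probes are `unclassified` and never produce edges.

## The multilayer graph

Spatial edges: a contact pair contributes an edge when its two anchors
overlap two distinct loci, each locus extended by a 10 kb flank
(configurable to 0 for strict overlap; proximity-ligation anchors are
fragment-scale while loci are gene-scale). Duplicate contacts over the
same locus pair merge into one edge with accumulated evidence; contacts
whose anchors fall in the same locus are self-loops and dropped. eQTL
edges connect the SNP's locus to the probe's locus for every significant
verdict; results mapping into a single locus stay in the table but yield
no edge. Functional edges are read from a curated table only — the
protein/phenotype links are literature facts, not something this
pipeline infers. Since intermediary loci need not contain any SNP, the
locus table used for the graph is the union of SNP-derived block loci
and annotation-only gene loci. Chromosome names are normalized to the
no-"chr" form; mixing conventions without auto-normalization is an
explicit error. The graph is a `networkx.MultiGraph`: the same locus
pair can carry one edge per layer.

## Hub discovery

A *bridging path* is a simple path between two distinct GWAS loci whose
interior nodes are all non-GWAS, of at most `max_path_len` edges
(default 3 — long enough for both a two-step intermediary bridge and a
three-step spatial-then-functional chain). The graph is restricted to
edges lying on at least one bridging path; connected components of the
restriction containing ≥ `min_gwas` (default 2) GWAS loci are the hubs.
Each hub reports, per GWAS pair it connects, all bridging paths of
minimal length for that pair, with per-step layer labels; a pair of GWAS
loci in the same hub need not have its own bridging path (they may be
linked through a third GWAS locus). All layers are traversable by
default; a layer filter supports spatial-only analysis. Hub identity is
the set of GWAS members, hubs are ordered by descending GWAS count then
lexicographic ids, and the whole computation is invariant to input
order. `shared_intermediary_pairs` additionally lists every GWAS pair
with a common direct non-GWAS neighbour (the two-step bridge view).

Evaluation against planted truth counts a detected hub as correct iff
its GWAS member set equals a planted one; precision is 1.0 by convention
when nothing is detected, recall 1.0 when nothing is planted.

## Synthetic data generator

The generator emulates the study design the pipeline targets — eight
population panels (default) with block LD, additive eQTL effects, and
contact lists with planted hubs — not real population genetics: no
coalescent history, no admixture, no microarray normalization artifacts.
Passing tests therefore demonstrate that the machinery recovers what its
model class contains, not that real HapMap/Hi-C data would behave as
cleanly.

* **Genotypes.** Per population, each SNP's allele frequency is drawn
  uniformly in [0.05, 0.95]; SNPs in a declared block share the block's
  frequency. Block LD is planted via a latent haplotype per block: each
  member copies the latent allele with probability √level and otherwise
  redraws from the block frequency, giving pairwise haplotype
  correlation `level` exactly (r² = level²; level 1 duplicates the
  column). A redraw, rather than a literal bit-flip, is used so the
  marginal allele frequency is preserved. Haplotypes are paired into
  dosages.
* **Expression.** expr = Σ beta·dosage + N(0, noise_sd), with defaults
  beta and noise chosen at effect sizes a lymphoblastoid eQTL study
  would call strong-but-realistic (beta 1.5 expression units per allele
  copy against unit noise in the recovery experiments, n = 60 per
  population); probes without a planted effect are pure noise.
* **Contacts.** Each planted hub leg emits either one contact anchored
  inside the GWAS gene and the intermediary gene (spatial) or a curated
  functional row. Background contacts are placed uniformly *outside* all
  annotated genes (± flank) by rejection sampling, so background can
  never create locus-locus edges; persistent rejection failure is a
  reported error, not a hang.
* **Determinism.** Every draw flows from the single config seed through
  per-stage, per-population `numpy` substreams; identical config + seed
  reproduce outputs bit for bit.

## Problem sizes used in the shipped checks

The calibration and recovery experiments run at 20,000 null pairs
(8 populations × n = 100), 200 recovery replicates (8 × n = 60), 100
randomized oracle-equivalence instances per operation, and 10,000-draw
invariant fuzzes — sizes chosen so each experiment's Monte-Carlo error
is far below the effect being checked while the whole battery completes
in a few minutes on one core.

## Numerical choices and degenerate inputs

* EM: tolerance 1e−8, ≤1000 iterations, Fréchet bounds enforced each
  step.
* Exact permutation p counts permutations with |rho| ≥ |rho_obs| − 1e−12
  (ties included, so p > 0).
* r² and D′ are clamped to [0, 1] against floating-point overshoot.
* Constant vectors, n < 5, monomorphic SNPs, unlocated probes and empty
  p-value lists all map to explicit "untestable/undefined" signals, not
  to fabricated p-values.
* `compound_verdict` is monotone: lowering any p-value can never turn a
  significant pair non-significant (fuzzed).

## Known limitations

* LD for collapsing is computed from a single pooled panel; the original
  web-tool LD sources are population-specific and not reproduced here,
  so the LD input is explicit and swappable.
* The contact list is taken as given; no contact-strength weighting or
  significance testing of contacts is attempted, and no enrichment test
  of hubs against degree-matched random graphs is included.
* Expression is assumed pre-adjusted; no covariate or latent-factor
  correction is performed.
* Biallelic SNPs only; confidence-interval-style block definitions
  (Gabriel et al.-type) are out of scope.
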