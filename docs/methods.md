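# Methods

This note documents the models, parameter choices, and numerical decisions
behind `grnrewire`, and what the synthetic benchmarks do and do not show.

## Coordinate and data model

All genomic coordinates are 0-based half-open internally; GFF3 and VCF
(1-based) are converted at the I/O boundary only. Genes missing from a
species' annotation are represented as absent — never imputed as zero
expression — because downstream pruning must distinguish "gene lost" from
"gene unexpressed". A separate flag marks genes present in a genome but
absent from its annotation (consumed from a table produced by an external
homology search); edges touching such genes are removed as mis-annotation
artifacts rather than treated as biology.

## Motif models and exact p-values

A PSSM is built from aligned binding sites with a pseudocount of 0.25 per
base per column (Laplace-style smoothing, proportional to a uniform
background), giving natural-log odds against the background; a base at its
background frequency scores zero. Species with ≥3 extrapolated sites get a
species-specific (CS) matrix; sites from all species are otherwise pooled
into one cross-species (CW) matrix. Extrapolation accepts the best ungapped
match of a vertebrate site in a promoter at ≥70% identity (inclusive),
breaking ties toward the TSS-proximal position and then the + strand.

The p-value of a window score is exact under an i.i.d. background: each
column's score distribution is discretized on a lattice of granularity
ε = 1e-3 (log-odds units) and convolved by dynamic programming; the reported
value is the survival function at the lattice score. Against exhaustive
enumeration of all 4^w sequences (w ≤ 6) the error is below 10ε. Ambiguous
bases contribute zero to the score; windows with >20% ambiguous bases are
skipped. Both strands are scanned (the reverse-complement matrix has its own
DP distribution, so asymmetric backgrounds are handled exactly).

Calling is two-stage: per-window p ≤ 1e-4 (the standard scanning default;
the upstream permutation-based per-matrix threshold optimization is not
reproducible and is replaced by this constant, overridable per PSSM), then
Benjamini–Hochberg q < 0.05 within each (species, motif) family over **all
tested windows**, the narrowest defensible family. Motifs are retained only
within 5 kb of the TSS; the 100-nt window density out to 20 kb is computed
to justify and visualize that cutoff.

Randomized-promoter controls support mononucleotide permutation and an
Eulerian-path dinucleotide shuffle (all 16 dinucleotide counts preserved
exactly). Note the calibration subtlety: the scanner's null is i.i.d., so
the mononucleotide shuffle is the matched control (measured hit rate at
p ≤ 1e-4 is ~1.0e-4 per window); a dinucleotide shuffle preserves the
order-1 autocorrelation of the generated promoters and inflates the rate
~3.5-fold, which is a property of the sequences, not a miscalibration.

## Confidence tiers

Hit evidence maps to a fixed confidence score: extrapolation supported by
both mouse and human (1a, 0.3), mouse only (1b, 0.2), human only
(1c, 0.15); matrix scans by provenance CS (2a, 0.125), CW (2b, 0.110),
JASPAR (2c, 0.115). When multiple tiers apply to a site the highest score
wins. These constants annotate edges; they never weight the rewiring
metrics, which are threshold-based.

## Tissue specificity and modules

τ is computed on the log layer log(x+1) (it requires non-negative values,
so the mean-centered layer is unsuitable), with categories broad (τ ≤ 0.5),
intermediate, narrow (τ ≥ 0.9), boundaries inclusive as printed. An
all-zero profile yields an explicit "undefined" flag, not 0.

Module assignment is a deliberate simplification of probabilistic
tree-mixture clustering: k-means (k = 10 by default, kept as a constant
rather than re-selected) is fit once on the concatenated (gene, species)
mean-centered profiles; the resulting module means are canonically ordered
(lexicographically) and every species' genes are assigned from those shared
means, so module indices are comparable across species and invariant to
gene order. A loader accepts externally computed assignments. Ancestral
labels use Sankoff parsimony with unit substitution cost; top-down ties
resolve toward the parent's label, then the lowest module index, making the
reconstruction deterministic. Parsimony slightly undercounts changes
relative to the generating process — acceptable because the metrics compare
labels, not rates, along the tree.

## Synthetic data: what it emulates

The generator mirrors the study design: five species on a ladder phylogeny,
six tissues, ten modules. Defaults and their rationale:

- **Branch lengths 0.005–0.03** (neutral-substitution-like units). The
  gain/loss rate grid runs to 400 with acceptance below 100; such rates are
  only identifiable when rate × branch length is order 0.1–1. Longer
  branches saturate the two-state chain and leave only the gain:loss ratio
  identifiable.
- **Module means**: each module strongly expressed (log-scale mean 6) in one
  or two tissues, baseline (1) elsewhere; **expression noise sd 0.5** in log
  space. Separation/noise ≈ 10 makes module recovery essentially exact —
  the benchmark tests label bookkeeping along the tree, not clustering
  difficulty.
- **Per-branch state-change probability 0.0625**: over the 8 branches of
  the tree this yields ~40% of genes with at least one state change,
  matching the scale reported for the motivating study system.
- **Promoters**: order-1 Markov background (GC 0.4, persistence 0.25);
  planted sites sampled from the motif's frequency matrix; a "broken" site
  has its maximum-information column substituted with the least-favored
  base, emulating a validated single-base binding-site disruption.
- **SNP panel**: 3 clades × 8 samples, sites assigned one genotype class
  per clade (the reference clade conserved), with diet/habitat/palette
  traits constant within clades.

What the synthetic data does **not** emulate: realistic genome composition,
linkage, demography, cell-type mixtures, or correlated noise across tissues.
Passing benchmarks therefore demonstrate algorithmic correctness and
calibration under the stated model, not performance on real RNA-seq or
genome alignments.

### The planted-site recovery fixture

Recovery (≥95% of intact full-consensus plants, <5% of broken plants) is
measured at the pipeline's full calling thresholds, because the FDR stage is
what separates intact (exact p ≈ 8e-7) from broken (p ≈ 2.5e-5) sites; the
per-window gate alone does not. The fixture uses a fixed base-balanced
consensus (5 strong / 5 weak bases) so the margin is composition-independent,
and plants sites in 40 of 200 promoters per species (160 decoys): when every
promoter carries a true site, Benjamini–Hochberg becomes adaptively
permissive (large significant rank raises the effective cutoff) and broken
sites can re-enter — a real property of FDR control, and a regime unlike
genome-scale scanning where true sites are a small minority of windows.

## Expression network (per-gene greedy)

For each target gene, TFs are added by forward selection on the merged
30-dimensional profile: at each step the TF giving the largest
residual-sum-of-squares reduction enters if its partial-F p-value is ≤ 0.05,
up to 10 regulators; missing species are handled by masked least squares on
the observed dimensions; collinear candidates tie-break deterministically by
TF identifier. Edge significance is the entry p-value, BH-corrected across
**all candidate (TF, target) pairs tested** — not merely the selected edges.
Correcting only over selected edges leaves the greedy selection bias (a
minimum over candidates) uncorrected and collapses planted-regulator
precision; with the full-family correction the null calibration holds
(≤5% of independent targets receive any edge) and planted regulators are
recovered with precision and recall ≥0.9 on the default benchmark.

## Edge matrix and pruning

Expression and motif evidence are unioned per edge by default (an
intersection mode is available); evidence provenance, the maximum
confidence score, and the minimum q-value annotate each row. Projection
marks an edge *ineligible* — distinct from absent — in species lacking the
TF or TG gene. Pruning removes rows that are (1) present in fewer than two
species, (2) absent anywhere due to gene loss or mis-annotation (any
ineligible cell), or (3) anchored by a node outside the co-expression
modules; many-to-many orthogroups containing a flagged-missing gene are
removed wholesale. Pruning is idempotent.

## Rewiring metrics

**Focal rewiring.** A qualifying edge has a presence pattern unique to the
focal species — present only there, or absent only there. The second case
is the signature a lineage-specific binding-site disruption leaves on an
otherwise conserved edge, and it is the only case that can exist in a
pruned matrix (pruning guarantees ≥2 present cells per row). A TF is
rewired for the focal species when it owns a qualifying edge, its module
label there differs from every other extant species, and it still
participates in other edges in every comparison species. Qualifying edge
sets are disjoint across focal species by construction.

**Degree-corrected score.** Each incident edge contributes the summed
squared deviation of its cross-species presence vector (ineligible species
excluded) from the vector's centroid, divided by (S − 1); the node score is
the sum over edges divided by the node's degree in the union network. The
score is zero iff all incident edges are identically present, and adding
fully conserved edges dilutes it. Candidate sets are compared to the
background by the two-sample Kolmogorov–Smirnov test (asymptotic p). Note
that KS p-values of a discrete statistic are stepwise, hence slightly
conservative; calibration is therefore asserted as rejection rate = nominal
level, not literal uniformity.

**Gain/loss rates.** The two-state chain has
P(0→1)(t) = (g/(g+l))(1 − e^{−(g+l)t}) and symmetrically for loss; the root
prior is the stationary distribution (a fixed-root alternative is a flag).
Likelihood uses pruning, vectorized over the ≤2^S distinct patterns;
ineligible leaves are marginalized (summed over both states), not treated
as absence. The joint likelihood is maximized by exhaustive search over the
{0, 5, …, 400}² lattice (the reproducible replacement for an EM fit; an
optional EM refinement could start from the grid argmax). Ties break toward
smaller g+l, then smaller g. A TF needs ≥25 edge patterns; an estimate is
accepted only if both rates are below 100; all-present or all-absent
pattern sets are flagged uninformative. On 2000 simulated patterns at
(g, l) = (20, 10) the grid maximum recovers the truth exactly.

## Variants and segregation

Intersection uses half-open interval logic, verified against a quadratic
brute-force oracle. Minus-strand motif overlaps complement the alleles and
mirror the position within the motif (an involution). Concordance requires
the promoter-alignment column to show exactly the reference allele in the
reference row and the alternative in the other species' row, with gaps
discordant by reason; flank conservation defaults to ≥90% identity over
±20 alignment columns (gaps count as mismatches; both the window and the
threshold are parameters — the source criterion is qualitative). Genotype
classes relative to the reference species' allele: conserved (homozygous
reference), heterozygous-segregating (phase-independent), homozygous-
segregated; missing genotypes are excluded from summaries.

## Independent contrasts

Standard Felsenstein recursion; polytomies and non-positive branch lengths
are errors, never silently resolved, because contrast values depend on the
resolution. Contrast regression is through the origin; the naive tip
regression (with intercept) is reported alongside so the effect of fitting
the phylogeny is directly comparable. Genotypes enter as dosage codes
(0 / 0.5 / 1 by default; the map is configurable and recorded). Under
independent Brownian traits the through-origin slope p-values are uniform
(checked by KS at α = 0.01 over 500 replicates) and standardized contrasts
have unit variance (within 5% over 10⁴ pooled contrasts).

## Problem sizes and benchmarks

The default benchmark sizes — 120–200 genes, 200 planted sites over
1-kb promoters with 160 decoy promoters per species, 2000 CTMC patterns,
100-target PGG benchmark, 24-sample SNP panel, 32-tip Brownian calibration —
were chosen so each stage's statistical claim is testable with comfortable
error margins while the full suite and the acceptance script each run in
well under a minute per stage on one CPU.

## Interfaces

The library functions are the primary interface; a thin `grnrewire` CLI
covers the stages natural to run from a shell (`simulate`, `scan`, `tau`,
`gainloss`, `pic`). Stages that operate on in-memory multi-table state
(edge-matrix integration, focal rewiring, variant overlap) are exposed as
functions rather than subcommands, since a file-level CLI would only
re-serialize intermediate state the caller already holds.

## Known limitations

- Module assignment is a simplified stand-in for probabilistic tree-aware
  clustering; it assumes module means are shared across species.
- The exact p-value null is i.i.d.; promoter autocorrelation inflates tail
  probabilities slightly (see the calibration note above).
- Only promoter scanning is implemented (no conserved non-coding elements,
  no enhancers); pairwise variants are consumed as tables, not computed
  from whole-genome alignments.
- Grid-ML rate estimates are bounded by the lattice (resolution 5, range
  0–400); rates outside the identifiable regime for the given branch
  lengths surface as boundary estimates flagged unaccepted.
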