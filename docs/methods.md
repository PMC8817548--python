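# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices made where conventions diverge,
and what the synthetic-data generator does and does not emulate.

## CDS filtering

A coding sequence is kept only if it is longer than 300 nt (strictly:
length ≤ 300 is removed), has a length divisible by three, contains only
`{A,C,G,T}`, starts with `ATG`, ends with `TAA`/`TAG`/`TGA`, and has no
in-frame internal stop. Rules are evaluated in the fixed order
`not_triplet → too_short → ambiguous_base → bad_start → bad_stop →
internal_stop` and each rejected record is attributed to its *first*
failing rule, so the report's counts always sum to the input size and
filtering is idempotent. Two conventions worth noting:

* the triplet-length rule is not part of the classical filter recipe but
  is required for codon statistics to be defined at all; it is counted
  under its own reason so the addition is visible in reports;
* any character outside `{A,C,G,T}` counts as "uncertain" — no IUPAC
  whitelist is attempted;
* the terminal stop codon is retained in the stored record (stop-codon
  RSCU needs it) but excluded from all sense-codon statistics.

## Composition indices

GC1/GC2/GC3 are the percent G+C at codon positions 1–3 over sense
codons; the terminal stop is excluded and the single-codon families ATG
(Met) and TGG (Trp) are included — the codonW convention. GC3s restricts
the third position to codons of amino acids with at least two synonymous
codons, i.e. it additionally excludes ATG and TGG. By construction
GC = (GC1+GC2+GC3)/3 exactly over the same codon set.

### 5′→3′ GC3 gradient

The phrase "genes divided into 100 groups" admits two readings, both
implemented:

* **positional** (default, the 5′→3′ reading): each gene's sense codons
  are cut into 100 contiguous, equal-as-possible segments (segment *b*
  of a gene with *L* codons covers indices ⌊bL/100⌋ … ⌊(b+1)L/100⌋−1);
  bin *b* pools third-position G+C over segment *b* of every gene. Genes
  with fewer than 100 sense codons cannot fill every segment and are
  skipped with a logged count. The result is invariant under gene-order
  permutation.
* **ranked**: genes sorted by gene-level GC3 and cut into 100 equal-size
  groups; bin = group mean. This is a quantile profile, not a positional
  one.

Neither mode is claimed to be "the" published convention; the choice is
recorded in each run's output.

## RSCU and derived statistics

RSCU follows Sharp & Li: `RSCU_ij = n_i · x_ij / T_i` for codon *j* of a
family with `n_i` synonymous codons and total `T_i`. Families with
`T_i = 0` are reported as *missing*, never 0 (a zero would read as
extreme bias). Species-level RSCU always pools counts over all filtered
genes rather than averaging per-gene RSCU values — the genome-wide
convention.

High-frequency codons: RSCU > 1.5 **or** within-family relative
frequency > 0.60, both strict inequalities (ties excluded); stops and
the 1-fold families are never eligible. Stop-codon RSCU treats
{TAA, TAG, TGA} as one 3-member family. The XCG/XCC ratio is
Σ RSCU(XCG) / Σ RSCU(XCC) over X ∈ {A,C,G,T} — a ratio of sums, not a
mean of per-X ratios; values below 1 indicate CpG suppression at codon
positions 2–3.

## Effective number of codons

Observed ENc is Wright's (1990) estimator. Per family with amino-acid
count n ≥ 2 and frequencies p_j, the homozygosity estimate is

    F̂ = (n·Σp_j² − 1)/(n − 1),

which is unbiased for Σp² under multinomial sampling; families with
n < 2 contribute nothing (the estimator divides by n−1). F̂ is averaged
within each degeneracy class and

    ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,

capped at 61. If the 3-fold class (Ile alone) is unobserved, F̄₃ is
imputed as (F̄₂+F̄₄)/2, following codonW's practice; if any other class
average is undefined or zero the gene's ENc is undefined and the gene is
excluded with a logged count rather than raising. A gene using one codon
per amino acid gives every F̂ = 1 and ENc = 20 exactly; equal usage of
every synonymous codon at large counts saturates the cap at 61.

The mutation-only expectation given GC3s fraction F is

    ENc_exp = 2 + F + 29/(F² + (1−F)²),

maximal at F = 0.5 (60.5) and symmetric up to the linear term. The
per-gene deviation statistic (ENc_exp − ENc_obs)/ENc_exp is binned into
the seven half-open intervals [−0.2,−0.1) … [0.4,0.5); half-open edges
avoid double counting, and values outside the span are reported under a
separate out-of-range entry so percentages always total 100.

## Neutrality plot

Per-gene GC12 = (GC1+GC2)/2 is regressed on GC3 by unweighted ordinary
least squares (`scipy.stats.linregress`), reporting slope, intercept,
Pearson r, R² and the two-sided p-value from the t distribution with
n−2 df. At least 3 genes and non-zero GC3 variance are required. A slope
near 1 means mutation pressure acts on all three positions alike; near 0
means positions 1–2 are selectively constrained.

## Codon pairs

Pairs are *overlapping* adjacent sense codons — (c₁,c₂), (c₂,c₃), … — so
a gene with L sense codons yields L−1 pairs; pairs involving the
terminal stop are excluded. The junction table classifies each pair by
the dinucleotide straddling the boundary (third base of the first codon,
first base of the second; the XY of nnXYnn) into 16 percentages.

RSCPU lifts the Sharp–Li form to pairs. The synonymous family of a pair
is taken to be all pairs encoding the same *ordered amino-acid
dipeptide* (family size m = n_i·n_j); within a family with total T,
RSCPU = m·count/T. The narrower last-codon-only reading of "synonymous
codon pair" exists in the literature; the dipeptide-family semantics is
the standard interpretation and is flagged in the RSCPU output header
(`family=dipeptide`). High-frequency pairs use RSCPU > 1.5 or
within-family share > 0.60, strict.

## Cross-species comparison

Gradient distances are plain Euclidean distances between 100-bin
gradient vectors (fractions, so distances are dimensionless and small).
Biclustering applies agglomerative hierarchical clustering with
Euclidean distance and complete linkage (`scipy.cluster.hierarchy`)
independently to the rows (species) and columns (codons) of the
species × 59-codon RSCU matrix — the 61 sense codons minus ATG and TGG,
whose RSCU is identically 1 and carries no signal. Rows are raw RSCU
values, deliberately unstandardized: RSCU is already family-normalized.
Complete-linkage heights are monotone non-decreasing; scipy's
agglomeration is deterministic for a given input, and leaf order comes
from the standard dendrogram traversal. Dendrograms are exported as
Newick (branch length = parent merge height − child merge height) plus a
merge-list TSV.

## Synthetic-data generator

The generator emulates the statistical structure the analyses measure,
not real gene anatomy. All models emit valid CDSs (ATG start, uniform or
weighted terminal stop, no internal stops, no ambiguity codes) with gene
lengths uniform over a configurable sense-codon range (minimum 101, so
every gene passes the length filter and fills a 100-bin positional
gradient). A single integer seed drives everything; species panels
derive one independent stream per label from (seed, label), so removing
a label never perturbs the others.

* **mutation_only(θ)** — amino acids i.i.d. (uniform over 20 by
  default; composition carries no signal for any statistic here), codon
  within the family by per-position nucleotide probabilities restricted
  to the family: positions 1–2 uniform, and the third-position G+C mass
  θ split over the G/C third bases the family actually offers (1−θ over
  its A/T bases). The availability normalization makes
  P(third base ∈ {G,C} | family) = θ *exactly* for every degenerate
  family — including 3-fold Ile, which lacks a G-ending codon — so
  pooled GC3s estimates θ and, for a T/C-ending 2-fold family, the
  expected RSCU of the C-ending codon is 2θ. This is the null the
  ENc-plot curve describes, up to residual family-structure effects.
* **weighted(w)** — explicit within-family codon weights; used to build
  species "clades" with distinct codon preferences.
* **gradient(θ_start, θ_end)** — mutation_only with θ linear in codon
  position; under uniform amino-acid usage the expected GC3 at a
  position is (18θ + 2)/20 (Met and Trp always contribute G).
* **coupled(slope, intercept, σ)** — per gene, GC3 target drawn
  uniformly from (0.25, 0.65) by default and a GC12 target set to
  intercept + slope·(GC3 − center) + N(0, σ); codons drawn from
  independent per-position nucleotide probabilities with stop codons
  rejected. The default GC3 range is wide enough that regression
  dilution from finite gene length (600 codons in the shipped analyses:
  attenuation < 0.015 on the slope) stays well inside recovery
  tolerances.
* **cg_suppression** ∈ (0,1] multiplies the weight of the four NCG
  codons (family models) or thins them by rejection (coupled model),
  pushing XCG/XCC below 1 in expectation.

What the generator does **not** emulate: amino-acid composition biases,
length–expression correlations, isochore structure, introns/UTRs, or
any real species' parameter values. Green tests therefore certify the
estimators and their null behavior, not agreement with any particular
genome.

## Problem sizes and runtime

The shipped analyses and tests use deliberately modest sizes chosen so
each stage's sampling error is small relative to the tolerances being
checked: 500 genes × 300 codons for the mutation-only ENc null (mean
deviation tolerance ±0.05), 2000 genes × 600 codons for
neutrality-slope recovery (tolerance ±0.03 on a slope of 0.37), 1500–
2000 genes × 600 codons for gradient-endpoint recovery, and 25-gene
species for clade-recovery clustering. Each runs in seconds on one
core; scaling any of them up only shrinks the sampling error.

## Known limitations

* ENc edge-case handling (missing 2-fold class, the Ile imputation)
  follows codonW's documented behavior but codonW's handling of every
  rare degenerate input is not independently verifiable; this package
  excludes-and-logs rather than guessing.
* The deviation-histogram bin edges are a convention (half-open); a
  tool using closed-right bins will disagree for genes exactly on an
  edge.
* RSCPU for families only partially observed assigns unobserved member
  pairs an implicit RSCPU of 0 (they are absent from the output rather
  than listed).
* Species-level analyses assume pooled counts observe every family;
  `build_rscu_matrix` refuses gene sets small enough to violate this.
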