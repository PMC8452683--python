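# Methods

This note documents the models behind `mitoduo`: what the synthetic
generators emulate, the exact rules each analysis stage implements, the
defaults and why, and the numerical choices that matter.

## The study system

Doubly uniparental inheritance (DUI) maintains two mitochondrial
lineages in one species: the female-transmitted F-type and the
male-transmitted M-type. The package targets the *Arctica islandica*
configuration: two circular mitogenomes of ~17.4 kb at ~5.5% nucleotide
divergence, unevenly distributed (hotspots in atp6, cytb, cox3, nad4,
nad4L, nad6, 16S, tRNA-Ile, tRNA-Cys and the two non-coding regions;
conserved 12S, cox2, nad3, nad5 and most tRNAs), a 127-bp M-type
insertion in 16S, a 10-residue M-type cox1 extension, multiplex-PCR
mitotype screening, qPCR tissue quantification, read-based homoplasmy
checks, and reduced ETS/COX capacities in M-carriers.

## Synthetic genome pairs

**Reference layout.** The F-type reference is a fixed gene order of 12
protein-coding genes, 22 tRNAs (66 bp each), 12S (846 bp) and 16S
(1,245 bp) rRNAs and two non-coding regions, separated by 2-bp spacers;
the NCRs absorb whatever the configured genome length (default
17,428 bp) leaves over, and a genome too short to host the feature set
is rejected. CDS sequences are random non-stop codons between an ATG and
a stop codon (TAA/TAG under the invertebrate mitochondrial code,
translation table 5). All genes sit on the + strand, as in venerid DUI
species.

**Substitution model.** A single-parameter site-wise model: each
eligible site mutates with probability `baseline × multiplier`, where
the multiplier is 3.0 for hotspot features, 0.2 for conserved features
and 1.0 otherwise, and the substituted base is uniform over the three
alternatives. No transition/transversion bias is modelled — the
downstream statistics (set-disjointness, p-distance, k-mer uniqueness)
are insensitive to the substitution spectrum, only to its placement. The
baseline is solved in closed form, `b = target · L / Σ multiplier_i`
over eligible sites, so the expected genome-wide p-distance equals the
configured target (default 0.055) exactly; over 20 seeds the realized
mean sits within binomial noise of it.

**Reading-frame safety.** Start and stop codons are excluded from
substitution; a substitution that would create an internal stop is
redrawn among the remaining alternatives (at most a handful of sites per
genome are affected, absorbed by the calibration denominator). Both
genomes therefore translate every CDS cleanly under table 5 — an
invariant the tests assert.

**Structural events.** The 16S insertion (default 127 bp, A/T-rich
random sequence, since real mitochondrial indels are AT-biased and the
actual inserted sequence plays no diagnostic role beyond its length) is
placed at the 16S midpoint. The cox1 extension inserts 10 random
non-stop codons immediately before the stop codon, preserving frame, so
the M protein is exactly 10 residues longer. Both events are recorded in
the event log and in the true alignment (gap blocks in the F row), and
M-genome feature coordinates are shifted/grown accordingly.

**Coordinates.** 0-based half-open everywhere internally; feature and
window TSVs are written 1-based inclusive; BED output keeps BED's
native convention.

## Read simulation

Uniform-coverage substitution-error reads from the circular genomes
(origin-spanning reads wrap; strands random). The read count is Poisson
with mean `coverage × L / read_length`. All randomness is drawn in
fixed-size blocks before the per-read loop, so two runs at the same seed
that differ only in the F/M mixture fraction are coupled: the set of
M-labelled reads grows monotonically with the mixture and every read
keeps its position, strand and errors. This makes the
mixture-monotonicity property of read typing exact rather than
statistical. Indel sequencing errors are not modelled; the k-mer typing
stage is insensitive to them beyond a per-read loss of matching k-mers,
which the substitution model already exercises.

## Divergence scanning

**Fixed differences.** A column is diagnostic iff the set of states in
the M rows is disjoint from the set in the F rows, with the gap
character as a fifth state. The wording "all M differ from all F" is
implemented literally: a column with M={A,G}, F={A} is *not* divergent.
Ambiguity codes are rejected outright — the disjointness rule has no
defined semantics for partially overlapping IUPAC sets.

**Profile.** Counts per window of 500 columns, step 1, computed over the
*alignment* coordinates (gap columns included), linearly (no wrap across
the origin): the profile describes the aligned genome pair, and the two
insertions appear as solid blocks of divergent columns. Window positions
are reported by 1-based window start.

**p-distance.** Mismatches over compared sites with pairwise deletion
(columns gapped in either row excluded) — the default gap treatment of
the distance tool named by the field's standard workflow. The bootstrap
SE resamples alignment columns with replacement (default 1,000
replicates) and re-applies pairwise deletion within each replicate.

**Indels.** Maximal runs of columns gapped in exactly one group; the
carrier is the group holding sequence there. With a feature map
projected through the true alignment each record is annotated with its
containing feature; a feature's column span runs from its first to its
last base's column, so internal insertions fall inside the span and the
per-feature fixed-difference counts, plus an intergenic remainder,
partition the genome-wide count exactly.

## In-silico multiplex PCR

Primer sites are sought on both strands across the circular junction; a
site qualifies when total mismatches ≤ 2 (default) and the 3'-terminal
3 bases match exactly (the clamp — mismatch tolerance is a matching
model, not chemistry). Amplicons span from forward 5' end to reverse 5'
end inclusive (gel-size convention); products longer than 2,000 bp are
suppressed as spurious; multiple viable products are all reported and
flagged ambiguous.

The real assay's primer sequences are not published in the main text, so
the package designs synthetic primers deterministically against a
generator pair: for 16S, shared 22-mers in conserved flanks of the
insertion (the M band is then longer than the F band by exactly the
insertion length); for cytb, two allele-specific forward primers whose
3' base sits on a fixed difference — the clamp rejects the other
mitotype — at two offsets from a shared reverse primer, so the two
mitotypes give different band sizes. A loader accepts user primer TSVs
with expected sizes. Classification uses bands alone: F iff only
female-size bands are interpretable at ≥1 locus, M symmetrically, HET
when both band sets appear (the assay detects both genomes whatever
their ratio), FAIL otherwise; assay definitions whose F/M windows
overlap at the configured tolerance (default ±5 bp) are rejected at
load. Note the published band sizes imply a 126-bp 16S size difference
against a 127-bp indel — a primer-offset quirk of the real assay that
the synthetic design does not reproduce: here the size difference equals
the indel length exactly.

## qPCR quantification

Plates simulate Ct = Ct(1 ng) − log_E(amount) + N(0, σ) with default
efficiency 1.9, Ct(1 ng) = 21 and σ = 0.15 cycles — typical intercalating-
dye chemistry values, chosen once — plus a 5-point 10-fold standard
series (10 … 10⁻³ ng) and duplicate unknown wells; absent templates
report no amplification (NaN Ct). Analysis fits Ct against log10(amount)
by least squares; efficiency = 10^(−1/slope); efficiencies outside
(1, 2.2] and fits with r² < 0.9 are flagged. Quantification uses
amount = amount₀ · E^(Ct₀ − ct) with the curve's 1-ng point as the ΔCt
reference — equivalent to reading the amount off the curve, and the
natural anchor when none is named. Duplicates are averaged on the Ct
scale; pairs discordant by >1 cycle are flagged, not dropped. Normalized
abundance is the target over the geometric mean of two housekeeping
amounts; the housekeeping pair is a configuration input (a stability
criterion for choosing it is deliberately out of scope). Tissue calls:
homoplasmic when the minor type falls below the detection limit (default
the amount a Ct-38 well would report — the package's choice of an
"absent" threshold), heteroplasmic otherwise with the major/minor
imbalance bucketed in orders of magnitude (<1, 1–2, >2), FAIL when both
types are undetected. Copy-number contrasts use the ratio of group
medians with a seeded percentile bootstrap.

## Read typing

Alignment-free: diagnostic regions (by default the three densest
non-overlapping 300-column fixed-difference windows, projected onto each
genome's own coordinates — mirroring the choice of type-specific
regions) are indexed by their canonical (strand-collapsed) 31-mers,
minus every k-mer occurring anywhere in the other mitotype's genome,
including across the origin. This subtraction makes the F and M k-mer
sets disjoint by construction and renders cross-assignment of error-free
reads impossible, not merely unlikely. A read matches a region when ≥2
of its canonical k-mers (min_hits, suppressing single-error chimeras)
belong to that region's set; reads matching both mitotypes are discarded
as ambiguous rather than fractionally split; reads shorter than k are
skipped and tallied. Counts are normalized to matching reads per 100
bases of region length. Sample calls: heteroplasmic when both mitotypes
reach 5 matching reads, homoplasmic toward the only mitotype that does,
insufficient otherwise. The substitution of unique-k-mer assignment for
short-read alignment is a deliberate methodological replacement: it
exposes the same decision variable (read support for type-specific
regions) without an external aligner, at the cost of ignoring paired-end
and mapping-quality information that real mapping would use.

## Phenotype statistics

The generator draws lognormal activities with *arithmetic-mean*
parameterization (μ = ln(mean) − σ²/2, σ = 0.25 on the log scale) so
configured group-mean ratios are exact in expectation: ETS and COX means
× 0.69 / × 0.67 in M-carriers (both sexes), CS × 0.58 in females (both
mitotypes), and a × 3 mtDNA copy-number factor in M-carriers (inside the
2–5-fold band). Default n = 1,000 per sex × mitotype cell, i.e. 2,000
per marginal group — the size at which the recovery checks are run; at
that n the standard error of a percent-reduction estimate is well under
one point. Percent reduction is defined on group means (the field
reports reductions without naming the estimator; means pair naturally
with the lognormal generator), with a two-group percentile bootstrap
(default 2,000 replicates, seeded). Hypothesis testing is the
nonparametric suite: Kruskal-Wallis across the four cells, two-sided
Wilcoxon rank-sum post hocs with Holm adjustment (reported stars in this
field rarely name an adjustment; Holm is uniformly valid and exact-level),
and marginal rank-sum contrasts for mitotype and sex. Cells with fewer
than two observations are flagged and excluded from pairwise contrasts.
Parametric two-way F statistics are intentionally not reproduced.

## Population screen

The screening fixture transcribes the published seven-population table
verbatim (315 individuals, 300 F-carriers, 15 M-carriers; Iceland 60
with 10 M-carriers) including its totals row; simulation mode draws
binomial carrier counts from per-population probabilities.

## Problem sizes and determinism

Every generator consumes a single integer seed through named RNG
streams, so identical configurations are bit-identical across runs. The
shipped test-suite and acceptance-script problem sizes — 20 seeds for
divergence calibration, 5,000 reads for specificity, 200 individuals for
multiplex concordance, 1,000 samples for qPCR call accuracy, 2,000 per
group for effect recovery — were chosen as the smallest sizes at which
the checked quantities are estimated comfortably inside their stated
tolerances.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the pipeline needs
(divergence level and unevenness, structural events, mixture ratios,
qPCR chemistry, effect sizes), not real sequences: there is no attempt
to reproduce the published GenBank genomes, no selection on amino acids,
no sequencing-error indels, no PCR chemistry beyond mismatch/clamp
logic, and no inter-individual polymorphism within a mitotype (the
multiplex concordance check exercises the two canonical genomes).
Passing therefore demonstrates that the *computations* are correct and
calibrated on data with the reported structure — not that the biological
findings would re-derive from raw reads.
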