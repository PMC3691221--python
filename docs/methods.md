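# Methods

This note documents the models and procedures implemented in `mitocomp`,
the defaults they ship with, and the choices made where the design was
genuinely open.

## Genome model

Coordinates are 1-based and inclusive on the heavy strand, the convention
of printed mitogenome organisation tables; any half-open representation is
internal and invisible at interfaces. Features may wrap the circular
origin: a span with `stop < start` has length `L − start + 1 + stop`. The
intergenic value belongs to the *upstream* feature's row (distance to the
next feature, negative for overlaps), and the last row's value wraps back
to the first feature.

The genetic code is the vertebrate mitochondrial code (NCBI table 2): 60
sense codons, stops TAA/TAG/AGA/AGG, ATA = Met, TGA = Trp. Start codons
default to {ATG, GTG}, the initiators seen in fish mitochondrial protein
genes. AGA/AGG are treated as complete stops by the stop classifier for
code-table completeness even though the shipped study tables only use
TAA/TAG. Non-triplet 3′ ends reading `T` or `TA` immediately adjacent to
the downstream feature are classified as the truncated stops `T++`/`TA+`
(completed to TAA by post-transcriptional polyadenylation); a non-triplet
end that is not adjacent, or does not read T/TA, raises a classification
error, since it indicates a misannotation rather than a biological stop.

Base composition excludes N from the denominator. `N` against a base
counts as a difference in distance calculations (it attests divergence of
annotation quality if nothing else), while `N` against `N` and gap against
gap are excluded: shared absence or shared ambiguity carries no signal.

## Homology-transfer annotation

Reference feature sequences are aligned to the target with an internal
Smith–Waterman aligner (match +2, mismatch −3, gap open −5, gap extend −2;
Biopython's `PairwiseAligner` supplies the dynamic programming), so the
package needs no external alignment binary. The genome is doubled before
searching so placements crossing the origin are found, and both strands
are searched. A placement must reach 60% identity and 60% length coverage
by default — these thresholds are explicit configuration, not a claim
about any published pipeline, which typically leaves them unstated.
Among co-optimal alignments the one with the smallest target start, then
smallest query start, is selected.

The consensus step is a strict plurality vote on exact start and stop
coordinates, independently per boundary; ties are resolved toward the
candidate carried by the highest-scoring placement
(score = identity × coverage). An optional near-miss mode clusters votes
within ±k nt before voting. Strand requires a strict majority; anything
else is an explicit ambiguity error. CDS codon metadata (start codon, stop
class) is read off the target genome after placement; a consensus span
that yields no valid start/stop is reported as an issue rather than being
silently recorded. tRNA anticodons are carried through from the reference
annotation — structure-based tRNA validation is out of scope.

Measured on simulated genomes, self-annotation recovers every feature
exactly, and at ≤5% divergence without indels ≥95% of CDS/rRNA boundaries
land within ±2 nt of truth.

## Control region partitioning

The D-loop is divided into three canonical domains using two anchor
motifs: domain 2 (central conserved) begins at the CSB-F hit, domain 3
(variable) at the CSB1 hit, and domain 1 (hypervariable, containing the
TAS) is everything before CSB-F. Motifs are located by an exhaustive
Hamming-distance window scan; each motif's budget defaults to
⌈10% of its length⌉, which accommodates the ≤3 substitutions observed
between the two study species on a 45-mer TAS. Missing anchors produce an
error that names the motifs that *were* found, so a truncated or unusual
CR fails loudly.

## Relative rates by distance regression (DR)

For each gene the package computes raw p-distances with fully weighted
gaps: a gap aligned to a base counts as a difference, gap-vs-gap columns
are dropped from numerator and denominator. This deliberately retains
indel divergence — the reason the estimator is applied to the
control region, where substitution-model-based estimators discard the
indel-rich columns that carry most of the signal. Distances can be taken
over all taxon pairs (`pairwise`, the library default) or per taxon
against the alignment's plurality consensus (`vs_consensus`); both are
first-class because published descriptions of this approach mention both
and do not disambiguate.

Each gene's distance table is regressed on the reference gene's (12S rRNA
by convention, configurable) by least squares. Through-origin is the
default — a zero reference distance implies a zero gene distance under a
rate-ratio reading — with a free-intercept mode behind a flag; r² is
reported uncentered for the through-origin model. The slope is the
gene's *relative rate*. Standard partitions are produced automatically:
per-gene, per codon position of each codon alignment, 4-fold degenerate
third positions pooled over all coding genes (a site qualifies only if
every gap/N-free taxon has a 4-fold codon there), and the control region
both raw and after the gap-column filter (drop columns with gap fraction
above a threshold, default 0 = any gap), the desk-scale stand-in for a
stringent alignment-block filter.

**Known limitation — saturation.** Because p-distances are not corrected
for multiple hits, slopes of fast partitions are compressed toward the
reference: at a reference depth of ~0.05 substitutions/site a 4× partition
regresses ~10% low, and on trees with deep pairs the compression grows to
~20%+. This is a property of the estimator (shared with the original
approach), not of the implementation; the parameter-recovery study
therefore reports it explicitly.

**Parameter-recovery study** (run by the acceptance suite and script):
100 replicates of a 20-taxon star radiation — the canonical model of an
explosive radiation, under which "mean pairwise reference distance ≈ 0.10"
describes every pair — with six ~0.9–1 kb partitions at multipliers
{0.25, 0.5, 1, 2, 4} under the default HKY model, analysed in consensus
mode (the smaller per-taxon depths keep the 4× partition inside the
saturation budget). Measured: the estimated slopes rank the true
multipliers perfectly in ≥99/100 replicates and all five slopes fall
within ±20% of truth in ≥95/100.

## Codon usage

Counts run over in-frame codons of all coding genes (coding orientation),
excluding stop codons, incomplete truncated-stop tails and codons with N
or gaps. Normalisation is `count/total × 60`, so a uniformly used codon
scores exactly 1 and the row mean is 1 — the constant is structural (60
sense codons), not tuned. The inter-profile metric is unspecified in the
literature this mirrors; euclidean is the default with manhattan as an
option, and conclusions that depend on the metric should be checked under
both.

Clustering is agglomerative via the hand-implemented Lance–Williams
recurrence (`d(k, i∪j) = αᵢd(ki) + αⱼd(kj) + βd(ij) + γ|d(ki) − d(kj)|`)
with average linkage (UPGMA weights) by default and median, single and
complete available. Ties merge the smallest (i, j) label pair. Average
linkage agrees with an independent UPGMA implementation to 1e-10; median
linkage can produce height inversions, which are reported verbatim in the
newick output (negative branch lengths) rather than suppressed, because
suppressing them hides exactly the interpretability problem they signal.

## Accessibility profiles

Per-residue scores are unweighted means of an amino-acid scale over a
window (default 9) centred on each position; "fully weighted edges" means
windows truncate at the termini with every included residue at weight 1,
so the profile covers every residue. An `interior_only` mode drops
positions lacking a complete window. `X` residues are skipped and the mean
renormalised over the remaining residues. Profiles are min-max normalised
to [0, 1] per sequence (a global cross-profile mode exists for
multi-sequence panels); a constant profile is a hard error since it has no
range. The default scale is Janin's (1979) molar fraction of accessible
residues (higher = more exposed); the companion interior-to-surface
transfer-energy scale ships as an alternative. Positions are reported in
sequence coordinates; mapping through an alignment is the caller's choice.

## Simulator

Sequences evolve down a user-supplied rooted newick tree (branch lengths
in expected substitutions/site for a multiplier-1 partition) under HKY
with κ = 4 and stationary frequencies A .275, C .303, G .157, T .265 —
the heavy-strand composition of the study system — or JC for closed-form
checks. Each partition scales every branch by its rate multiplier. The
default genome layout is the full 39-feature organisation with sizes,
strands, start codons and stop classes of the *P. trewavasae* table and
per-class multipliers mirroring the reported rate-group means (CR 4×,
CDS 1.25×, 16S 1.2×, tRNA/OL 0.75×, 12S = 1 as reference).

Coding partitions pin the start codon and the (possibly truncated) stop,
and reject substitutions that create an in-frame stop by reverting the
affected codon to its parental state — a deliberate deviation from a pure
nucleotide model that keeps every simulated CDS translatable, at the cost
of slightly depressing the realised substitution rate at stop-adjacent
sites. Control-region partitions additionally undergo a Poisson indel
process (events ~ Poisson(rate × length × branch length), insertion or
deletion with equal probability, geometric lengths); residues carry global
column identifiers through the tree, so the emitted alignment is the
exact truth, with no realignment step. Features are concatenated exactly
abutting — the study tables' small overlaps and spacers are validated on
the shipped fixtures, not simulated. Identical config and seed give
byte-identical output.

What the simulator does *not* emulate: recombination (real mtDNA is
effectively clonal, so this is harmless), rate variation among sites
within a partition, selection beyond stop avoidance, heteroplasmy, and
sequencing error. Tests passing on simulated data therefore demonstrate
estimator correctness under the stated generative model, not robustness
to alignment error or model misspecification in real data. Two random
tree generators (Kingman coalescent and pure-birth Yule, both rescaled to
a target mean pairwise distance) are provided for test construction.

Lineage-specific codon bias is generated by a dedicated routine: a
log-preference vector over the 60 sense codons evolves by Brownian steps
down the tree and each leaf's codon counts are a multinomial draw from its
softmax preferences — sister taxa thus inherit similar usage, the signal
the clustering property test checks (sister pairs merge first in ≥90% of
replicates).

## Published-scale quantities

The study-scale numbers (overall nucleotide identity between the two
deposited genomes, per-gene rate values including the D-loop's, base
composition percentages) depend on ~25 downloaded genomes and external
multiple aligners, so they are not recomputed here; `examples/full_study.py`
documents the pipeline for users with the data. The desk-scale acceptance
surface is: exact reconstruction of both organisation tables, the coding
fraction, the TAS divergence, the parameter-recovery study, oracle
equivalence of the numerics, and the qualitative rate ordering
D-loop > CDS > rRNA > tRNA on simulated data. Problem sizes used by the
test suite (for example the reduced five-feature genome in
alignment-heavy tests) are chosen to exercise every code path at desk
scale; the full 39-feature layout remains the simulator default.
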