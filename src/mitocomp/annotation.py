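"""Homology-transfer annotation of mitogenomes.

A target genome is annotated by locally aligning reference feature sequences
from related taxa against it (both strands, across the circular origin),
filtering placements on percent identity and length coverage, and taking a
majority-rule consensus of the surviving coordinate votes. The module also
provides an ORF scanner, an approximate (Hamming) motif finder and the
partitioning of the control region into its three canonical domains anchored
on the CSB-F and CSB1 conserved blocks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .genome_model import (
    FeatureRecord,
    Mitogenome,
    GeneticCode,
    VERTEBRATE_MITO,
    classify_stop_codon,
    reverse_complement,
    StopClassificationError,
)

__all__ = [
    "LocalAlignment",
    "Placement",
    "MotifSet",
    "DEFAULT_MOTIFS",
    "ORF",
    "local_align",
    "place_feature",
    "consensus_annotation",
    "ConsensusResult",
    "AmbiguousStrandError",
    "scan_orfs",
    "find_motif_approx",
    "partition_control_region",
    "ControlRegionPartition",
    "ControlRegionError",
    "annotate_genome",
    "RefFeature",
    "feature_class_for_name",
]


# -- local alignment ---------------------------------------------------------

@dataclass
class LocalAlignment:
    """Best local alignment of a query inside a target (1-based inclusive)."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    score: float
    n_matches: int
    alignment_length: int

    @property
    def identity(self) -> float:
        return self.n_matches / self.alignment_length if self.alignment_length else 0.0


def _make_aligner(match: float = 2, mismatch: float = -3, gap_open: float = -5, gap_extend: float = -2) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def local_align(
    query: str,
    target: str,
    match: float = 2,
    mismatch: float = -3,
    gap_open: float = -5,
    gap_extend: float = -2,
    max_tie_scan: int = 32,
) -> LocalAlignment:
    """Smith-Waterman local alignment under affine gap scoring.

    Among co-optimal alignments the one with the smallest target start, then
    smallest query start, is returned (scanning at most ``max_tie_scan``
    enumerated optima).
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    alignments = aligner.align(target.upper(), query.upper())
    best = min(
        itertools.islice(alignments, max_tie_scan),
        key=lambda a: (a.aligned[0][0][0], a.aligned[1][0][0]),
    )
    t_blocks, q_blocks = best.aligned
    n_matches = 0
    aln_len = 0
    tseq, qseq = target.upper(), query.upper()
    prev_t_end, prev_q_end = None, None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t_end is not None:
            aln_len += max(ts - prev_t_end, qs - prev_q_end)  # gap columns
        n_matches += sum(tseq[ts + k] == qseq[qs + k] for k in range(te - ts))
        aln_len += te - ts
        prev_t_end, prev_q_end = te, qe
    return LocalAlignment(
        query_start=q_blocks[0][0] + 1,
        query_end=q_blocks[-1][1],
        target_start=t_blocks[0][0] + 1,
        target_end=t_blocks[-1][1],
        score=best.score,
        n_matches=n_matches,
        alignment_length=aln_len,
    )


# -- feature placement -------------------------------------------------------

@dataclass
class Placement:
    """One candidate location of a reference feature on a target genome."""

    feature_name: str
    ref_taxon: str
    start: int
    stop: int
    strand: str
    percent_identity: float
    length_coverage: float

    @property
    def score(self) -> float:
        return self.percent_identity * self.length_coverage


def place_feature(
    ref_feature_seq: str,
    genome: Mitogenome,
    both_strands: bool = True,
    min_identity: float = 0.6,
    min_coverage: float = 0.6,
    feature_name: str = "",
    ref_taxon: str = "",
) -> Placement | None:
    """Best placement of a reference feature sequence on a circular genome.

    The genome is doubled so placements spanning the origin are found; both
    strands are searched unless ``both_strands`` is False. Returns None when
    no alignment passes the identity/coverage thresholds.
    """
    ref = ref_feature_seq.upper()
    if len(ref) < 20:
        raise ValueError("reference feature shorter than 20 nt")
    L = genome.length
    extension = min(len(ref), L)
    target = genome.sequence + genome.sequence[:extension]

    candidates: list[tuple[float, Placement]] = []
    strands = ("H", "L") if both_strands else ("H",)
    for strand in strands:
        q = ref if strand == "H" else reverse_complement(ref)
        aln = local_align(q, target)
        coverage = (aln.query_end - aln.query_start + 1) / len(ref)
        start0, stop0 = aln.target_start, aln.target_end
        if start0 > L:
            start0 -= L
            stop0 -= L
        if stop0 > L:
            stop0 -= L  # wraps the origin
        placement = Placement(
            feature_name=feature_name,
            ref_taxon=ref_taxon,
            start=start0,
            stop=stop0,
            strand=strand,
            percent_identity=aln.identity,
            length_coverage=min(coverage, 1.0),
        )
        if placement.percent_identity >= min_identity and placement.length_coverage >= min_coverage:
            candidates.append((placement.score, placement))
    if not candidates:
        return None
    return max(candidates, key=lambda c: c[0])[1]


# -- consensus ---------------------------------------------------------------

class AmbiguousStrandError(ValueError):
    """The placements disagree on strand with no majority."""


@dataclass
class ConsensusResult:
    name: str
    start: int
    stop: int
    strand: str
    support_start: int
    support_stop: int
    n_placements: int


def _majority_vote(values: list[int], scores: list[float], near_miss_window: int = 0) -> tuple[int, int]:
    """Plurality vote with score tie-break; returns (winner, support).

    With ``near_miss_window`` > 0, values are clustered into +/- window bins
    before voting and the bin's highest-scoring exact value wins.
    """
    if near_miss_window > 0:
        groups: list[list[int]] = []
        for idx in sorted(range(len(values)), key=lambda k: values[k]):
            if groups and values[idx] - groups[-1][-1] <= near_miss_window:
                groups[-1].append(idx)
            else:
                groups.append([idx])
        best_group = max(groups, key=lambda g: (len(g), max(scores[k] for k in g)))
        winner_idx = max(best_group, key=lambda k: scores[k])
        return values[winner_idx], len(best_group)
    counts = Counter(values)
    top = max(counts.values())
    tied = [v for v, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0], top
    best_idx = max((i for i in range(len(values)) if values[i] in tied), key=lambda i: scores[i])
    return values[best_idx], top


def consensus_annotation(placements: list[Placement], near_miss_window: int = 0) -> ConsensusResult:
    """Majority-rule consensus of coordinate votes from several references.

    Start and stop are voted independently on exact coordinate matches
    (or +/- ``near_miss_window`` bins); ties go to the vote carried by the
    highest-scoring placement. Strand requires a strict majority.
    """
    if not placements:
        raise ValueError("no placements passed thresholds: feature not found")
    scores = [p.score for p in placements]
    start, s_sup = _majority_vote([p.start for p in placements], scores, near_miss_window)
    stop, e_sup = _majority_vote([p.stop for p in placements], scores, near_miss_window)
    strand_counts = Counter(p.strand for p in placements)
    strand, strand_n = strand_counts.most_common(1)[0]
    if len(strand_counts) > 1 and strand_n * 2 <= len(placements):
        raise AmbiguousStrandError(f"no strand majority: {dict(strand_counts)}")
    return ConsensusResult(
        name=placements[0].feature_name,
        start=int(start),
        stop=int(stop),
        strand=strand,
        support_start=s_sup,
        support_stop=e_sup,
        n_placements=len(placements),
    )


# -- ORF scan ----------------------------------------------------------------

@dataclass
class ORF:
    """An open reading frame, stop codon included, on H-strand coordinates."""

    start: int
    stop: int
    strand: str
    start_codon: str
    length: int


def scan_orfs(
    genome: Mitogenome,
    code: GeneticCode = VERTEBRATE_MITO,
    min_length: int = 150,
) -> list[ORF]:
    """All maximal ORFs on both strands of a circular genome.

    An ORF starts at the first ATG/GTG after the previous in-frame stop and
    runs through its own stop codon. The scan works on the doubled sequence so
    reading frames may cross the origin; ORFs are reported once, sorted by
    H-strand start coordinate.
    """
    if min_length < 60:
        raise ValueError("min_length must be >= 60")
    L = genome.length
    found: list[ORF] = []
    seen: set[tuple[int, int, str]] = set()
    for strand in ("H", "L"):
        s = genome.sequence if strand == "H" else reverse_complement(genome.sequence)
        doubled = s + s
        for frame in range(3):
            i = frame
            orf_start: int | None = None
            while i + 3 <= 2 * L:
                codon = doubled[i : i + 3]
                if orf_start is None and i < L and codon in code.start_codons:
                    orf_start = i
                if code.is_stop(codon):
                    if orf_start is not None and orf_start < L:
                        length = i + 3 - orf_start
                        if length <= L and length >= min_length:
                            if strand == "H":
                                h_start = orf_start % L + 1
                                h_stop = (i + 2) % L + 1
                            else:
                                h_start = (L - 1 - (i + 2)) % L + 1
                                h_stop = (L - 1 - orf_start) % L + 1
                            key = (h_start, h_stop, strand)
                            if key not in seen:
                                seen.add(key)
                                found.append(
                                    ORF(h_start, h_stop, strand, doubled[orf_start : orf_start + 3], length)
                                )
                    orf_start = None
                i += 3
    found.sort(key=lambda o: (o.start, o.stop, o.strand))
    return found


# -- motifs & control region -------------------------------------------------

def _default_budget(motif: str) -> int:
    return math.ceil(0.1 * len(motif))


@dataclass
class MotifSet:
    """Named control-region motifs with per-motif mismatch budgets."""

    motifs: dict[str, str]
    max_mismatches: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.motifs.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"motif {name} contains non-ACGT characters")
            self.max_mismatches.setdefault(name, _default_budget(seq))


#: Control-region motifs of the P. trewavasae D-loop, the default anchor set.
DEFAULT_MOTIFS = MotifSet(
    motifs={
        "TAS": "ACGCAATGCATATATGTATTAACACCATTGTTTTATATTAAACAT",
        "CSB-F": "ATGTAGTAAGAGCCCACC",
        "CSB-E": "AGCGTGTGGGGGGT",
        "OH": "CTTTTTTTTTTTCCTTTCACTTGACATCTCAGAGTG",
        "CSB1": "ATTGCATAACTGATATCATGAGCATA",
        "CSB2": "AAACCCCCCCTACCCCC",
        "CSB3": "TGTAAACCCCCCGGAAACAG",
    }
)


def find_motif_approx(sequence: str, motif: str, max_mismatches: int = 0) -> list[tuple[int, int]]:
    """All windows of ``sequence`` within Hamming distance ``max_mismatches`` of ``motif``.

    Returns 1-based start positions in ascending order with their mismatch
    counts.
    """
    seq = sequence.upper()
    m = motif.upper()
    if len(m) > len(seq):
        raise ValueError("motif longer than sequence")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mot = np.frombuffer(m.encode(), dtype=np.uint8)
    n_windows = len(seq) - len(m) + 1
    mismatches = np.zeros(n_windows, dtype=np.int64)
    for j in range(len(m)):
        mismatches += arr[j : j + n_windows] != mot[j]
    hits = np.nonzero(mismatches <= max_mismatches)[0]
    return [(int(i) + 1, int(mismatches[i])) for i in hits]


class ControlRegionError(ValueError):
    """A required anchor motif was not found in the control region."""


@dataclass
class ControlRegionPartition:
    """The three D-loop domains and all motif hits, CR-relative (1-based)."""

    domains: dict[int, tuple[int, int]]
    motif_hits: dict[str, tuple[int, int]]  # name -> (position, mismatches)


def partition_control_region(cr_sequence: str, motifs: MotifSet = DEFAULT_MOTIFS) -> ControlRegionPartition:
    """Partition a control region into its three canonical domains.

    Domain 1 (hypervariable, contains the TAS) runs from the CR start to just
    before the CSB-F hit; domain 2 (central conserved, CSB-F/CSB-E/OH) begins
    at CSB-F; domain 3 (variable, CSB1-3) begins at CSB1. Each motif's best
    hit (fewest mismatches, then leftmost) is reported; missing CSB-F or CSB1
    is an error naming the motifs that were found.
    """
    cr = cr_sequence.upper()
    if len(cr) < max(len(m) for m in motifs.motifs.values()):
        raise ValueError("control region shorter than the longest motif")
    hits: dict[str, tuple[int, int]] = {}
    for name, motif in motifs.motifs.items():
        budget = motifs.max_mismatches[name]
        found = find_motif_approx(cr, motif, budget)
        if found:
            hits[name] = min(found, key=lambda h: (h[1], h[0]))
    for anchor in ("CSB-F", "CSB1"):
        if anchor not in hits:
            raise ControlRegionError(
                f"anchor motif {anchor} not found within its mismatch budget; "
                f"motifs found: {sorted(hits)}"
            )
    d2_start = hits["CSB-F"][0]
    d3_start = hits["CSB1"][0]
    if not (1 < d2_start < d3_start):
        raise ControlRegionError(
            f"inconsistent anchor order: CSB-F at {d2_start}, CSB1 at {d3_start}"
        )
    domains = {1: (1, d2_start - 1), 2: (d2_start, d3_start - 1), 3: (d3_start, len(cr))}
    return ControlRegionPartition(domains=domains, motif_hits=hits)


# -- whole-genome annotation -------------------------------------------------

@dataclass
class RefFeature:
    """A reference feature sequence used for homology transfer."""

    taxon: str
    name: str
    feature_class: str
    sequence: str
    anticodon: str | None = None


_CDS_NAMES = {"ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6", "COX1", "COX2", "COX3", "ATP6", "ATP8", "CYTB"}


def feature_class_for_name(name: str) -> str:
    """Feature class implied by a conventional mitochondrial feature name."""
    up = name.upper()
    if up in _CDS_NAMES:
        return "CDS"
    if up.startswith("TRNA"):
        return "tRNA"
    if up in {"12S", "16S", "12S RRNA", "16S RRNA"}:
        return "rRNA"
    if up in {"CR", "D-LOOP", "DLOOP"}:
        return "CR"
    if up == "OL":
        return "OL"
    raise ValueError(f"cannot infer feature class for {name!r}")


@dataclass
class AnnotationResult:
    records: list[FeatureRecord]
    consensus: dict[str, ConsensusResult]
    not_found: list[str]
    issues: list[str]


def annotate_genome(
    genome: Mitogenome,
    references: list[RefFeature],
    min_identity: float = 0.6,
    min_coverage: float = 0.6,
    near_miss_window: int = 0,
) -> AnnotationResult:
    """Annotate a genome by homology transfer from reference feature sets.

    Every reference copy of a feature is placed independently; placements
    passing the thresholds vote on coordinates under the majority rule. CDS
    codon metadata (start codon, stop class) is read off the target genome;
    features whose consensus span does not yield valid codon metadata are
    reported under ``issues`` instead of producing a record. Anticodons are
    carried through from the references (structure-based tRNA validation is
    out of scope here).
    """
    by_name: dict[str, list[RefFeature]] = {}
    for ref in references:
        by_name.setdefault(ref.name, []).append(ref)

    records: list[FeatureRecord] = []
    consensus: dict[str, ConsensusResult] = {}
    not_found: list[str] = []
    issues: list[str] = []
    for name, refs in by_name.items():
        placements = []
        for ref in refs:
            p = place_feature(
                ref.sequence,
                genome,
                min_identity=min_identity,
                min_coverage=min_coverage,
                feature_name=name,
                ref_taxon=ref.taxon,
            )
            if p is not None:
                placements.append(p)
        if not placements:
            not_found.append(name)
            continue
        try:
            cons = consensus_annotation(placements, near_miss_window=near_miss_window)
        except AmbiguousStrandError as exc:
            issues.append(f"{name}: {exc}")
            continue
        consensus[name] = cons
        fclass = refs[0].feature_class
        start_codon = stop_class = None
        if fclass == "CDS":
            if cons.stop >= cons.start:
                seq = genome.sequence[cons.start - 1 : cons.stop]
            else:
                seq = genome.sequence[cons.start - 1 :] + genome.sequence[: cons.stop]
            if cons.strand == "L":
                seq = reverse_complement(seq)
            start_codon = seq[:3]
            try:
                stop_class = classify_stop_codon(seq, adjacent_downstream=True)
            except (StopClassificationError, ValueError) as exc:
                issues.append(f"{name}: consensus span yields no valid stop ({exc})")
                continue
            if start_codon not in VERTEBRATE_MITO.start_codons:
                issues.append(f"{name}: consensus span starts with {start_codon}, not ATG/GTG")
                continue
        anticodon = next((r.anticodon for r in refs if r.anticodon), None)
        records.append(
            FeatureRecord(name, fclass, cons.start, cons.stop, cons.strand,
                          start_codon=start_codon, stop_class=stop_class,
                          anticodon=anticodon)
        )
    records.sort(key=lambda f: f.start)
    return AnnotationResult(records=records, consensus=consensus, not_found=not_found, issues=issues)
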