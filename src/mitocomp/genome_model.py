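"""Core data model for circular mitochondrial genomes.

Coordinates are 1-based and inclusive on the heavy (H) strand throughout,
matching the convention of printed mitogenome organisation tables. Features
may wrap across the origin of the circular molecule; wrap arithmetic is
defined in :func:`feature_length`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

__all__ = [
    "FeatureRecord",
    "Mitogenome",
    "GeneticCode",
    "VERTEBRATE_MITO",
    "FEATURE_CLASSES",
    "reverse_complement",
    "feature_length",
    "intergenic_gap",
    "base_composition",
    "classify_stop_codon",
    "extract_feature_seq",
    "translate_mito",
    "frameshift_consequence",
    "validate_genome_table",
    "ValidationReport",
]

FEATURE_CLASSES = ("CDS", "tRNA", "rRNA", "CR", "OL")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GeneticCode:
    """A codon table with explicit start codons.

    The default instance :data:`VERTEBRATE_MITO` is the vertebrate
    mitochondrial code (NCBI translation table 2): AGA/AGG are stops,
    ATA codes Met and TGA codes Trp, leaving 60 sense codons and the four
    stops TAA, TAG, AGA, AGG. Start codons default to {ATG, GTG}, the two
    initiators observed in fish mitochondrial protein genes.
    """

    def __init__(self, table: dict[str, str], start_codons: frozenset[str] = frozenset({"ATG", "GTG"})):
        self.table = dict(table)
        self.start_codons = frozenset(start_codons)
        self.stop_codons = frozenset(c for c, aa in self.table.items() if aa == "*")
        self.sense_codons = tuple(sorted(c for c, aa in self.table.items() if aa != "*"))
        if len(self.table) != 64:
            raise ValueError("codon table must cover all 64 codons")

    def amino_acid(self, codon: str) -> str:
        """Translate one codon; codons with ambiguity characters give 'X'."""
        aa = self.table.get(codon.upper())
        return aa if aa is not None else "X"

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon.upper()) == "*"


def _vertebrate_mito_table() -> dict[str, str]:
    ncbi = CodonTable.unambiguous_dna_by_id[2]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = "*"
    return table


#: The vertebrate mitochondrial genetic code with ATG/GTG start codons.
VERTEBRATE_MITO = GeneticCode(_vertebrate_mito_table())

_STOP_CLASSES = ("TAA", "TAG", "AGA", "AGG", "TA+", "T++")


@dataclass
class FeatureRecord:
    """One annotated genomic feature — a row of a mitogenome organisation table.

    ``start``/``stop`` are 1-based inclusive H-strand coordinates;
    ``stop_class`` distinguishes complete stop codons from the truncated
    'TA+'/'T++' ends completed to TAA by post-transcriptional polyadenylation.
    """

    name: str
    feature_class: str
    start: int
    stop: int
    strand: str
    start_codon: str | None = None
    stop_class: str | None = None
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r} for {self.name}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r} for {self.name}")
        if self.start < 1 or self.stop < 1:
            raise ValueError(f"coordinates must be >= 1 in {self.name}")
        if self.feature_class == "CDS":
            if not self.start_codon or not self.stop_class:
                raise ValueError(f"CDS {self.name} requires start_codon and stop_class")
            if self.stop_class not in _STOP_CLASSES:
                raise ValueError(f"unknown stop class {self.stop_class!r} in {self.name}")
        else:
            if self.start_codon or (self.stop_class is not None):
                raise ValueError(f"codon metadata only allowed on CDS features ({self.name})")

    def length(self, genome_length: int | None = None) -> int:
        if self.stop >= self.start:
            return self.stop - self.start + 1
        if genome_length is None:
            raise ValueError(f"{self.name} wraps the origin; genome_length required")
        return feature_length(self.start, self.stop, genome_length)


@dataclass
class Mitogenome:
    """A circular nucleotide sequence with its ordered feature annotation."""

    taxon: str
    sequence: str
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.taxon}: invalid characters {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            if f.start > n or f.stop > n:
                raise ValueError(f"feature {f.name} outside genome of length {n}")
        self.features = sorted(self.features, key=lambda f: f.start)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> FeatureRecord:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def feature_length(start: int, stop: int, genome_length: int) -> int:
    """Length in nucleotides of a 1-based inclusive span on a circular genome.

    A span with ``stop < start`` wraps across the origin:
    ``genome_length - start + 1 + stop``.
    """
    if not (1 <= start <= genome_length and 1 <= stop <= genome_length):
        raise ValueError(f"coordinates ({start}, {stop}) outside [1, {genome_length}]")
    if stop >= start:
        return stop - start + 1
    return genome_length - start + 1 + stop


def intergenic_gap(prev: FeatureRecord, next: FeatureRecord, genome_length: int | None = None) -> int:
    """Nucleotides between two consecutive features; negative means overlap.

    The value belongs on the upstream feature's row. If ``next`` starts before
    ``prev`` in linear coordinates and a genome length is given, the gap is
    computed across the origin (the last row of a circular table wraps back to
    the first feature).
    """
    next_start = next.start
    if next_start < prev.start and genome_length is not None:
        next_start += genome_length
    return next_start - prev.stop - 1


def base_composition(sequence: str) -> dict[str, float]:
    """Fractions of A/C/G/T; N bases are excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return {b: c / total for b, c in counts.items()}


class StopClassificationError(ValueError):
    """The 3' end of a CDS is neither a complete stop nor a valid truncated stop."""


def classify_stop_codon(cds_sequence: str, adjacent_downstream: bool) -> str:
    """Classify the 3' end of a protein-coding sequence.

    Complete triplet ends must read one of the four vertebrate-mito stops.
    Non-triplet ends reading T or TA immediately adjacent to the downstream
    feature are the truncated stops 'T++' and 'TA+' (completed to TAA by
    polyadenylation); anything else signals a misannotation.
    """
    seq = cds_sequence.upper()
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon")
    rem = len(seq) % 3
    if rem == 0:
        last = seq[-3:]
        if VERTEBRATE_MITO.is_stop(last):
            return last
        raise StopClassificationError(f"complete 3' codon {last} is not a stop")
    if rem == 2 and seq.endswith("TA") and adjacent_downstream:
        return "TA+"
    if rem == 1 and seq.endswith("T") and adjacent_downstream:
        return "T++"
    raise StopClassificationError(
        f"non-triplet end (len % 3 = {rem}, tail {seq[-rem:]!r}, "
        f"adjacent={adjacent_downstream}) is not a valid truncated stop"
    )


def extract_feature_seq(genome: Mitogenome, feature: FeatureRecord) -> str:
    """Feature sequence in coding orientation (L-strand features reverse-complemented)."""
    n = genome.length
    if not (1 <= feature.start <= n and 1 <= feature.stop <= n):
        raise ValueError(f"feature {feature.name} outside genome")
    if feature.stop >= feature.start:
        sub = genome.sequence[feature.start - 1 : feature.stop]
    else:  # wraps the origin
        sub = genome.sequence[feature.start - 1 :] + genome.sequence[: feature.stop]
    return reverse_complement(sub) if feature.strand == "L" else sub


def translate_mito(cds: str, code: GeneticCode = VERTEBRATE_MITO) -> str:
    """Translate a CDS under the given code, stopping at the first in-frame stop.

    Truncated terminal codons (1 or 2 trailing bases) are ignored; codons with
    ambiguity characters translate to 'X'. The stop symbol is not returned.
    """
    seq = cds.upper()
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon")
    protein = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = code.amino_acid(seq[i : i + 3])
        if aa == "*":
            break
        protein.append(aa)
    return "".join(protein)


def frameshift_consequence(
    cds: str, deletion_pos: int, code: GeneticCode = VERTEBRATE_MITO
) -> tuple[int | None, int]:
    """Effect of a single-base deletion within a CDS.

    Deletes the base at 1-based ``deletion_pos``, re-translates from position 1
    and returns ``(stop_start, protein_length)`` where ``stop_start`` is the
    1-based position (in post-deletion coordinates) of the first in-frame stop
    codon, or None if translation runs off the end without a stop, and
    ``protein_length`` is the number of amino acids preceding it.
    """
    if not (1 <= deletion_pos <= len(cds)):
        raise ValueError("deletion position outside CDS")
    mutated = cds[: deletion_pos - 1] + cds[deletion_pos:]
    seq = mutated.upper()
    for i in range(0, len(seq) - len(seq) % 3, 3):
        if code.is_stop(seq[i : i + 3]):
            return i + 1, i // 3
    return None, (len(seq) - len(seq) % 3) // 3


@dataclass
class ValidationReport:
    """Recomputed bookkeeping for a genome organisation table."""

    n_features: int
    counts_by_class: dict[str, int]
    counts_by_strand: dict[str, int]
    genome_length: int
    size_mismatches: list[tuple[str, int, int]]
    intergenic_mismatches: list[tuple[str, int, int]]
    cds_total_length: int
    cds_fraction: float
    warnings: list[str]

    @property
    def n_mismatches(self) -> int:
        return len(self.size_mismatches) + len(self.intergenic_mismatches)


def validate_genome_table(
    features: list[FeatureRecord],
    genome_length: int | None = None,
    printed_sizes: dict[str, int] | None = None,
    printed_intergenic: dict[str, int] | None = None,
) -> ValidationReport:
    """Recompute the size and intergenic columns of an organisation table.

    When printed size/intergenic values are supplied (keyed by feature name),
    every recomputed value is compared against them and mismatches are
    flagged. The intergenic value of the last feature wraps back to the first
    one on the circular genome. Structural oddities (unsorted input, overlaps
    beyond 15 nt) produce warnings, not failures.
    """
    warnings: list[str] = []
    if not features:
        raise ValueError("empty feature table")
    if any(b.start < a.start for a, b in zip(features, features[1:])):
        warnings.append("feature table not sorted by start; sorting for validation")
        features = sorted(features, key=lambda f: f.start)
    length = genome_length if genome_length is not None else max(f.stop for f in features)

    size_mismatches: list[tuple[str, int, int]] = []
    inter_mismatches: list[tuple[str, int, int]] = []
    cds_total = 0
    for i, f in enumerate(features):
        size = feature_length(f.start, f.stop, length)
        if f.feature_class == "CDS":
            cds_total += size
        if printed_sizes and f.name in printed_sizes and printed_sizes[f.name] != size:
            size_mismatches.append((f.name, printed_sizes[f.name], size))
        nxt = features[(i + 1) % len(features)]
        gap = intergenic_gap(f, nxt, genome_length=length)
        if gap < -15:
            warnings.append(f"{f.name}/{nxt.name} overlap by {-gap} nt (beyond 15 nt threshold)")
        if printed_intergenic and f.name in printed_intergenic and printed_intergenic[f.name] != gap:
            inter_mismatches.append((f.name, printed_intergenic[f.name], gap))

    by_class: dict[str, int] = {}
    by_strand: dict[str, int] = {}
    for f in features:
        by_class[f.feature_class] = by_class.get(f.feature_class, 0) + 1
        by_strand[f.strand] = by_strand.get(f.strand, 0) + 1

    return ValidationReport(
        n_features=len(features),
        counts_by_class=by_class,
        counts_by_strand=by_strand,
        genome_length=length,
        size_mismatches=size_mismatches,
        intergenic_mismatches=inter_mismatches,
        cds_total_length=cds_total,
        cds_fraction=cds_total / length,
        warnings=warnings,
    )
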