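"""Relative substitution rates by distance regression (the "DR" estimator).

For every gene (or partition) a gap-weighted p-distance table is computed
from its multiple sequence alignment and regressed by least squares against
the corresponding table of a slowly evolving reference gene — by convention
the 12S rRNA. The regression coefficient is the gene's *relative rate*: a
unitless rate ratio. Because the raw p-distance counts gap-vs-base columns
as differences ("fully weighted gaps"), the estimator captures insertion and
deletion divergence that substitution-model-based rate estimators discard —
the reason this approach is used for the indel-rich control region.

Distances may be computed for all unordered taxon pairs (``pairwise``) or
for each taxon against the alignment's plurality consensus
(``vs_consensus``). Regression is through the origin by default: a zero
reference distance implies a zero gene distance under a rate-ratio reading.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genome_model import GeneticCode, VERTEBRATE_MITO

__all__ = [
    "GeneAlignment",
    "DistanceTable",
    "RateEstimate",
    "p_distance",
    "consensus_sequence",
    "gene_distances",
    "codon_position_split",
    "fourfold_degenerate_sites",
    "gap_column_filter",
    "relative_rate_regression",
    "rate_table",
    "group_means",
    "RATE_GROUPS",
]

GAP = "-"
MISSING = {"N", GAP}


@dataclass
class GeneAlignment:
    """A per-gene multiple sequence alignment over {A,C,G,T,N,-}."""

    gene: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment {self.gene}: unequal row lengths {sorted(lengths)}")
        bad = set("".join(self.rows)) - set("ACGTN-")
        if bad:
            raise ValueError(f"alignment {self.gene}: invalid characters {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def subset_taxa(self, taxa: list[str]) -> "GeneAlignment":
        return GeneAlignment(self.gene, list(taxa), [self.row(t) for t in taxa])


@dataclass
class DistanceTable:
    """Gap-weighted p-distances keyed by taxon pair or by taxon."""

    gene: str
    mode: str  # "pairwise" | "vs_consensus"
    entries: dict = field(default_factory=dict)

    def shared_keys(self, other: "DistanceTable") -> list:
        if self.mode != other.mode:
            raise ValueError("distance tables have different modes")
        return [k for k in self.entries if k in other.entries]


@dataclass
class RateEstimate:
    """Regression slope of a gene's distances on the reference gene's."""

    gene_or_partition: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    group: str = ""


class UndefinedDistanceError(ValueError):
    """No alignment columns were countable for a sequence pair."""


def p_distance(row_a: str, row_b: str, gap_mode: str = "full_weight") -> float:
    """Proportion of differing columns between two aligned sequences.

    ``full_weight``: a gap aligned to a base counts as a difference; columns
    where both sequences have a gap carry no signal and are excluded from
    numerator and denominator; N against a base also counts as a difference.
    ``ignore``: any column containing a gap is excluded entirely.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    a = row_a.upper()
    b = row_b.upper()
    diffs = counted = 0
    for ca, cb in zip(a, b):
        if ca == GAP and cb == GAP:
            continue  # shared absence carries no divergence signal
        if ca == "N" and cb == "N":
            continue  # mutual ambiguity attests neither identity nor difference
        if gap_mode == "ignore" and GAP in (ca, cb):
            continue
        counted += 1
        if ca != cb:
            diffs += 1
    if counted == 0:
        raise UndefinedDistanceError("zero countable columns")
    return diffs / counted


def consensus_sequence(alignment: GeneAlignment) -> str:
    """Per-column plurality consensus; the gap competes as an ordinary symbol.

    Column ties are broken toward the symbol most frequent in the whole
    alignment, then alphabetically (with '-' sorting last).
    """
    if len(alignment.rows) < 2:
        raise ValueError("consensus requires at least 2 rows")
    rows = alignment.rows
    overall: dict[str, int] = {}
    for r in rows:
        for c in r:
            overall[c] = overall.get(c, 0) + 1
    order = "ACGTN" + GAP  # alphabetical with gap last
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts, key=lambda c: (counts[c], overall.get(c, 0), -order.index(c)))
        out.append(best)
    return "".join(out)


def gene_distances(alignment: GeneAlignment, mode: str = "pairwise", gap_mode: str = "full_weight") -> DistanceTable:
    """Distance table for an alignment, pairwise or against its consensus."""
    table = DistanceTable(gene=alignment.gene, mode=mode)
    if mode == "pairwise":
        for (i, ti), (j, tj) in itertools.combinations(enumerate(alignment.taxa), 2):
            key = tuple(sorted((ti, tj)))
            table.entries[key] = p_distance(alignment.rows[i], alignment.rows[j], gap_mode)
    elif mode == "vs_consensus":
        cons = consensus_sequence(alignment)
        for taxon, row in zip(alignment.taxa, alignment.rows):
            table.entries[taxon] = p_distance(row, cons, gap_mode)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return table


def codon_position_split(codon_alignment: GeneAlignment) -> tuple[GeneAlignment, GeneAlignment, GeneAlignment]:
    """Split a codon alignment into 1st/2nd/3rd codon-position alignments."""
    L = codon_alignment.n_columns
    if L % 3 != 0:
        raise ValueError(f"alignment length {L} not divisible by 3")
    parts = []
    for pos in range(3):
        rows = [row[pos::3] for row in codon_alignment.rows]
        parts.append(
            GeneAlignment(f"{codon_alignment.gene}_pos{pos + 1}", list(codon_alignment.taxa), rows)
        )
    return tuple(parts)


def fourfold_degenerate_sites(codon_alignment: GeneAlignment, code: GeneticCode = VERTEBRATE_MITO) -> list[int]:
    """0-based third-position column indices that are 4-fold degenerate in every taxon.

    A codon column-triple contributes its third position iff for every taxon
    whose codon there is free of gaps and Ns, the first two bases determine
    the amino acid for all four third bases. Taxa with gap/N codons abstain;
    a site with no qualifying taxon is excluded.
    """
    L = codon_alignment.n_columns
    if L % 3 != 0:
        raise ValueError(f"alignment length {L} not divisible by 3")
    fourfold_prefixes = {
        p for p in ("".join(t) for t in itertools.product("ACGT", repeat=2))
        if len({code.amino_acid(p + b) for b in "ACGT"}) == 1 and code.amino_acid(p + "A") != "*"
    }
    sites = []
    for c in range(0, L, 3):
        n_votes = 0
        ok = True
        for row in codon_alignment.rows:
            codon = row[c : c + 3]
            if set(codon) & MISSING:
                continue
            if codon[:2] not in fourfold_prefixes:
                ok = False
                break
            n_votes += 1
        if ok and n_votes > 0:
            sites.append(c + 2)
    return sites


def gap_column_filter(alignment: GeneAlignment, max_gap_fraction: float = 0.0) -> GeneAlignment:
    """Drop every column whose gap fraction exceeds ``max_gap_fraction``.

    The default (0) removes any column containing a gap — the desk-scale
    stand-in for a stringent alignment-block filter on indel-rich regions.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    n = len(alignment.rows)
    keep = [
        i
        for i, col in enumerate(zip(*alignment.rows))
        if col.count(GAP) / n <= max_gap_fraction
    ]
    if not keep:
        raise ValueError(f"gap filter removed every column of {alignment.gene}")
    rows = ["".join(row[i] for i in keep) for row in alignment.rows]
    return GeneAlignment(alignment.gene + "_gapfiltered", list(alignment.taxa), rows)


def relative_rate_regression(
    y: DistanceTable, x: DistanceTable, through_origin: bool = True
) -> RateEstimate:
    """Least-squares regression of gene distances on reference distances.

    Through the origin (default) the slope is sum(xy)/sum(x^2); otherwise an
    ordinary least-squares slope and intercept are fitted. r^2 is reported on
    the fitted model. Keys (taxa or taxon pairs) are matched by identity.
    """
    keys = y.shared_keys(x)
    if len(keys) < 3:
        raise ValueError(f"insufficient shared keys ({len(keys)}) for regression")
    xv = np.array([x.entries[k] for k in keys], dtype=float)
    yv = np.array([y.entries[k] for k in keys], dtype=float)
    if not np.any(xv):
        raise ValueError("reference distances are all zero")
    if through_origin:
        slope = float(np.sum(xv * yv) / np.sum(xv * xv))
        intercept = 0.0
        fitted = slope * xv
    else:
        if np.var(xv) == 0:
            raise ValueError("zero variance in reference distances with intercept fit")
        slope, intercept = np.polyfit(xv, yv, 1)
        slope, intercept = float(slope), float(intercept)
        fitted = slope * xv + intercept
    ss_res = float(np.sum((yv - fitted) ** 2))
    # uncentered total SS for the through-origin model, centered otherwise
    ss_tot = float(np.sum(yv**2)) if through_origin else float(np.sum((yv - np.mean(yv)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RateEstimate(
        gene_or_partition=y.gene, slope=slope, intercept=intercept,
        r_squared=r2, n_points=len(keys),
    )


RATE_GROUPS = ("4-fold", "3rd", "2nd", "1st", "CDS", "rRNA", "tRNA")


def _group_for(label: str, feature_classes: dict[str, str] | None) -> str:
    if label.endswith("_pos1"):
        return "1st"
    if label.endswith("_pos2"):
        return "2nd"
    if label.endswith("_pos3"):
        return "3rd"
    if label.startswith("4-fold"):
        return "4-fold"
    if label.startswith("D-loop") or label.startswith("CR"):
        return "CR"
    if feature_classes and label in feature_classes:
        return feature_classes[label]
    try:
        from .annotation import feature_class_for_name

        return feature_class_for_name(label)
    except ValueError:
        return "other"


def rate_table(
    alignments: dict[str, GeneAlignment],
    reference_gene: str = "12S",
    mode: str = "pairwise",
    gap_mode: str = "full_weight",
    through_origin: bool = True,
    codon_alignments: set[str] | None = None,
    dloop_gene: str | None = None,
    feature_classes: dict[str, str] | None = None,
    exclude_taxa: set[str] | None = None,
) -> list[RateEstimate]:
    """Relative rates for every gene and standard partition vs the reference.

    Produces one estimate per gene, per codon position of every CDS listed in
    ``codon_alignments`` (default: all genes classified as CDS), one for the
    4-fold degenerate third positions pooled over all those CDS, and — when
    ``dloop_gene`` is given — both the raw and the gap-filtered control
    region. Taxa are intersected across genes; ``exclude_taxa`` (e.g.
    outgroups) are removed first. The reference's own slope is 1 by
    construction.
    """
    if reference_gene not in alignments:
        raise ValueError(f"reference gene {reference_gene!r} missing")
    taxa = None
    for aln in alignments.values():
        ts = set(aln.taxa) - (exclude_taxa or set())
        taxa = ts if taxa is None else taxa & ts
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise ValueError("fewer than 3 shared taxa across genes")

    def dist(aln: GeneAlignment) -> DistanceTable:
        return gene_distances(aln.subset_taxa(taxa), mode=mode, gap_mode=gap_mode)

    ref_table = dist(alignments[reference_gene])

    if codon_alignments is None:
        codon_alignments = {
            g for g in alignments
            if _group_for(g, feature_classes) == "CDS" and alignments[g].n_columns % 3 == 0
        }

    estimates: list[RateEstimate] = []
    fourfold_rows: list[str] | None = None
    for gene, aln in sorted(alignments.items()):
        est = relative_rate_regression(dist(aln), ref_table, through_origin)
        est.group = _group_for(gene, feature_classes)
        estimates.append(est)
        if gene in codon_alignments:
            sub = aln.subset_taxa(taxa)
            for part in codon_position_split(sub):
                e = relative_rate_regression(dist(part), ref_table, through_origin)
                e.group = _group_for(part.gene, None)
                estimates.append(e)
            sites = fourfold_degenerate_sites(sub)
            if sites:
                chunk = ["".join(row[i] for i in sites) for row in sub.rows]
                if fourfold_rows is None:
                    fourfold_rows = chunk
                else:
                    fourfold_rows = [a + b for a, b in zip(fourfold_rows, chunk)]
    if fourfold_rows is not None:
        ff = GeneAlignment("4-fold", taxa, fourfold_rows)
        e = relative_rate_regression(dist(ff), ref_table, through_origin)
        e.group = "4-fold"
        estimates.append(e)
    if dloop_gene and dloop_gene in alignments:
        filtered = gap_column_filter(alignments[dloop_gene].subset_taxa(taxa), 0.0)
        e = relative_rate_regression(dist(filtered), ref_table, through_origin)
        e.group = "CR"
        estimates.append(e)
    return estimates


def group_means(estimates: list[RateEstimate]) -> dict[str, float]:
    """Mean slope per rate group, for the groups that are present."""
    sums: dict[str, list[float]] = {}
    for e in estimates:
        sums.setdefault(e.group, []).append(e.slope)
    return {g: float(np.mean(v)) for g, v in sums.items()}
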