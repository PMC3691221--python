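"""Codon usage analysis: counting, uniform-usage normalisation, clustering.

Usage is expressed relative to a uniform expectation over the 60 sense
codons of the vertebrate mitochondrial code: a value of 1 means the codon
was observed about once per 60 codons, values above/below 1 are enrichment
or depletion factors. Taxa are compared by hierarchical agglomerative
clustering driven by the Lance-Williams recurrence (average linkage by
default; median, single and complete available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_model import GeneticCode, VERTEBRATE_MITO

__all__ = [
    "SENSE_CODONS",
    "CodonUsageMatrix",
    "Merge",
    "count_codons",
    "normalize_usage",
    "usage_distance",
    "lance_williams_cluster",
    "dendrogram_to_newick",
]

#: The 60 sense codons of the vertebrate mitochondrial code, in fixed
#: alphabetical order — the column order of every usage matrix.
SENSE_CODONS = VERTEBRATE_MITO.sense_codons


def count_codons(cds_list: list[str], code: GeneticCode = VERTEBRATE_MITO) -> dict[str, int]:
    """In-frame sense-codon counts pooled over a list of coding sequences.

    Each CDS is read from position 1 in steps of three. Stop codons,
    incomplete terminal codons (the truncated 'TA+'/'T++' ends) and codons
    containing N or '-' are not counted. L-strand genes must already be in
    coding orientation.
    """
    counts = {c: 0 for c in code.sense_codons}
    for cds in cds_list:
        seq = cds.upper()
        if len(seq) < 3:
            raise ValueError("CDS shorter than one codon")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    return counts


def normalize_usage(counts: dict[str, int], code: GeneticCode = VERTEBRATE_MITO) -> dict[str, float]:
    """Normalise counts so that uniform usage over the 60 sense codons = 1.

    value(c) = count(c) / total * 60; the row mean over sense codons is
    exactly 1 whenever the total is positive.
    """
    total = sum(counts.get(c, 0) for c in code.sense_codons)
    if total == 0:
        raise ValueError("no countable codons")
    n = len(code.sense_codons)
    return {c: counts.get(c, 0) / total * n for c in code.sense_codons}


@dataclass
class CodonUsageMatrix:
    """Taxa x 60 sense codons, normalised so uniform usage = 1."""

    taxa: list[str]
    codons: tuple[str, ...]
    values: np.ndarray

    @classmethod
    def from_counts(cls, counts_by_taxon: dict[str, dict[str, int]],
                    code: GeneticCode = VERTEBRATE_MITO) -> "CodonUsageMatrix":
        taxa = list(counts_by_taxon)
        rows = [
            [normalize_usage(counts_by_taxon[t], code)[c] for c in code.sense_codons]
            for t in taxa
        ]
        return cls(taxa=taxa, codons=code.sense_codons, values=np.array(rows, dtype=float))

    def row(self, taxon: str) -> dict[str, float]:
        vals = self.values[self.taxa.index(taxon)]
        return dict(zip(self.codons, vals))

    def distance_matrix(self, metric: str = "euclidean") -> np.ndarray:
        n = len(self.taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = usage_distance(self.values[i], self.values[j], metric)
        return d


def usage_distance(row_a, row_b, metric: str = "euclidean") -> float:
    """Distance between two normalised usage rows (same codon order)."""
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("usage rows differ in length")
    if metric == "euclidean":
        return float(np.sqrt(np.sum((a - b) ** 2)))
    if metric == "manhattan":
        return float(np.sum(np.abs(a - b)))
    raise ValueError(f"unknown metric {metric!r}")


# Lance-Williams coefficients (alpha_i, alpha_j, beta, gamma) as functions of
# the cluster sizes n_i, n_j, n_k.
_LW = {
    "average": lambda ni, nj, nk: (ni / (ni + nj), nj / (ni + nj), 0.0, 0.0),
    "median": lambda ni, nj, nk: (0.5, 0.5, -0.25, 0.0),
    "single": lambda ni, nj, nk: (0.5, 0.5, 0.0, -0.5),
    "complete": lambda ni, nj, nk: (0.5, 0.5, 0.0, 0.5),
}


@dataclass
class Merge:
    """One agglomeration step: clusters ``left`` and ``right`` join at ``height``."""

    left: int
    right: int
    height: float
    size: int


def lance_williams_cluster(dist, method: str = "average") -> list[Merge]:
    """Agglomerative clustering via the Lance-Williams update formula.

    Input is a symmetric zero-diagonal distance matrix; output is a merge
    list in scipy convention: original items are clusters 0..n-1, the i-th
    merge creates cluster n+i. At each step the pair at minimal distance is
    merged, ties broken toward the smallest (i, j) cluster-label pair.
    Average linkage reproduces UPGMA; median linkage may produce height
    inversions, which are reported as-is rather than suppressed.
    """
    if method not in _LW:
        raise ValueError(f"unknown linkage method {method!r}")
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    coeff = _LW[method]

    sizes = {i: 1 for i in range(n)}
    D = d.copy()
    active = list(range(n))
    merges: list[Merge] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = D[ai, aj]
                key = (dij, min(i, j), max(i, j))
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        (dij, _, _), ai, aj = best
        i, j = active[ai], active[aj]
        ni, nj = sizes[i], sizes[j]
        merges.append(Merge(left=min(i, j), right=max(i, j), height=float(dij), size=ni + nj))

        # Lance-Williams update of distances from every other cluster k to i+j
        new_row = np.empty(len(active))
        for ak in range(len(active)):
            if ak in (ai, aj):
                continue
            nk = sizes[active[ak]]
            a_i, a_j, b, g = coeff(ni, nj, nk)
            new_row[ak] = (
                a_i * D[ak, ai] + a_j * D[ak, aj] + b * dij + g * abs(D[ak, ai] - D[ak, aj])
            )
        keep = [ak for ak in range(len(active)) if ak not in (ai, aj)]
        D = D[np.ix_(keep, keep)]
        row = new_row[keep]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = row
        D[:-1, -1] = row
        active = [active[ak] for ak in keep] + [next_id]
        sizes[next_id] = ni + nj
        next_id += 1
    return merges


def dendrogram_to_newick(merges: list[Merge], labels: list[str]) -> str:
    """Render a merge list as a newick string with merge heights as node depths.

    Branch lengths are differences between a cluster's merge height and its
    children's (half-heights, UPGMA-style); negative lengths arising from
    median-linkage inversions are emitted verbatim.
    """
    n = len(labels)
    node: dict[int, str] = {i: labels[i] for i in range(n)}
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    for k, m in enumerate(merges):
        h = m.height / 2.0
        bl_l = h - height[m.left]
        bl_r = h - height[m.right]
        node[n + k] = f"({node[m.left]}:{bl_l:.6g},{node[m.right]}:{bl_r:.6g})"
        height[n + k] = h
    return node[n + len(merges) - 1] + ";"
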