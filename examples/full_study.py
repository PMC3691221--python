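"""Published-scale comparative analysis on downloaded mitogenomes.

The quantitative published-scale numbers (overall nucleotide identity
between the two study species, per-gene relative rates including the
D-loop's, base-composition percentages) require the ~25 deposited genomes,
which are not shipped with the package. This script shows the pipeline to
run once a user has downloaded them:

  genomes/<taxon>.fa           one FASTA per taxon
  genomes/<taxon>.features.tsv feature table per taxon (package dialect)
  alignments/<gene>.fa         one aligned FASTA per gene (MAFFT/MUSCLE upstream)

Run:  python examples/full_study.py genomes/ alignments/
"""

import sys
from pathlib import Path

from mitocomp import GeneAlignment, gene_distances, group_means, p_distance, rate_table
from mitocomp.io import read_fasta

if len(sys.argv) != 3 or not Path(sys.argv[2]).is_dir():
    print(__doc__)
    sys.exit(0)

genome_dir, aln_dir = Path(sys.argv[1]), Path(sys.argv[2])

alignments = {}
for fasta in sorted(aln_dir.glob("*.fa*")):
    records = read_fasta(fasta)
    alignments[fasta.stem] = GeneAlignment(
        fasta.stem, [h.split()[0] for h, _ in records], [s for _, s in records]
    )

# overall identity between the first two taxa of the concatenated alignment
taxa = alignments[next(iter(alignments))].taxa[:2]
rows = ["".join(a.row(t) for a in alignments.values()) for t in taxa]
identity = 100 * (1 - p_distance(rows[0], rows[1]))
print(f"overall identity {taxa[0]} vs {taxa[1]}: {identity:.1f}%")

estimates = rate_table(
    alignments, reference_gene="12S", mode="pairwise",
    dloop_gene="CR" if "CR" in alignments else None,
)
print("partition  slope")
for est in estimates:
    print(f"{est.gene_or_partition:<16} {est.slope:.2f}")
print("group means:", {g: round(m, 2) for g, m in group_means(estimates).items()})
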