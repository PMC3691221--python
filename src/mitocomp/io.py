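"""Readers and writers for the formats the package consumes and produces.

FASTA goes through Bio.SeqIO (sequences are uppercased on read); feature
tables use a tab-separated dialect mirroring a printed mitogenome
organisation table, with optional ``size``/``intergenic`` columns carrying
printed values for validation; GFF3 output is 1-based; trees are newick via
dendropy.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import FeatureRecord, Mitogenome

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genome_fasta",
    "read_feature_table",
    "write_feature_table",
    "write_gff3",
    "read_gff3",
    "read_newick",
    "load_table1_fixture",
    "write_provenance",
]

FEATURE_COLUMNS = ["name", "class", "start", "stop", "strand", "start_codon", "stop_class", "anticodon"]

_GFF_TYPE = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D_loop", "OL": "rep_origin"}
_GFF_TYPE_REV = {v: k for k, v in _GFF_TYPE.items()}


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (identifier, uppercased sequence) pairs."""
    records = [(r.description, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    return records


def write_fasta(records, path) -> None:
    """Write (identifier, sequence) pairs as FASTA wrapped at 70 columns."""
    seqs = [SeqRecord(Seq(seq), id=name.split()[0], description=name) for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(seqs)


def read_genome_fasta(path) -> Mitogenome:
    """Read a single-record genome FASTA; the description is the taxon label."""
    records = read_fasta(path)
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one genome record, found {len(records)}")
    name, seq = records[0]
    return Mitogenome(taxon=name, sequence=seq)


@dataclass
class FeatureTable:
    """Parsed feature table plus any printed size/intergenic columns."""

    features: list[FeatureRecord]
    printed_sizes: dict[str, int]
    printed_intergenic: dict[str, int]


def read_feature_table(path) -> FeatureTable:
    """Read the tab-separated feature-table dialect (header required)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or reader.fieldnames[:8] != FEATURE_COLUMNS:
            raise ValueError(
                f"{path}: header must start with {FEATURE_COLUMNS}, got {reader.fieldnames}"
            )
        features: list[FeatureRecord] = []
        sizes: dict[str, int] = {}
        inter: dict[str, int] = {}
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = FeatureRecord(
                    name=row["name"],
                    feature_class=row["class"],
                    start=int(row["start"]),
                    stop=int(row["stop"]),
                    strand=row["strand"],
                    start_codon=row["start_codon"] or None,
                    stop_class=row["stop_class"] or None,
                    anticodon=row["anticodon"] or None,
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: bad feature row ({exc})") from exc
            features.append(rec)
            if row.get("size"):
                sizes[rec.name] = int(row["size"])
            if row.get("intergenic"):
                inter[rec.name] = int(row["intergenic"])
    return FeatureTable(features=features, printed_sizes=sizes, printed_intergenic=inter)


def write_feature_table(features: list[FeatureRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(FEATURE_COLUMNS)
        for f in features:
            writer.writerow([
                f.name, f.feature_class, f.start, f.stop, f.strand,
                f.start_codon or "", f.stop_class or "", f.anticodon or "",
            ])


def write_gff3(features: list[FeatureRecord], seqid: str, path, source: str = "mitocomp") -> None:
    """Write features as GFF3 (1-based inclusive, as native to this package)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.name}", f"Name={f.name}"]
            if f.start_codon:
                attrs.append(f"start_codon={f.start_codon}")
            if f.stop_class:
                attrs.append(f"stop_class={f.stop_class}")
            if f.anticodon:
                attrs.append(f"anticodon={f.anticodon}")
            strand = "+" if f.strand == "H" else "-"
            fh.write(
                f"{seqid}\t{source}\t{_GFF_TYPE[f.feature_class]}\t{f.start}\t{f.stop}\t.\t{strand}\t.\t{';'.join(attrs)}\n"
            )


def read_gff3(path) -> list[FeatureRecord]:
    """Read GFF3 rows of types CDS/tRNA/rRNA/D_loop/rep_origin back into records."""
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns, got {len(parts)}")
            _, _, ftype, start, stop, _, strand, _, attrs = parts
            if ftype not in _GFF_TYPE_REV:
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            features.append(
                FeatureRecord(
                    name=attr.get("Name", attr.get("ID", f"feature{lineno}")),
                    feature_class=_GFF_TYPE_REV[ftype],
                    start=int(start),
                    stop=int(stop),
                    strand="H" if strand == "+" else "L",
                    start_codon=attr.get("start_codon"),
                    stop_class=attr.get("stop_class"),
                    anticodon=attr.get("anticodon"),
                )
            )
    return features


def read_newick(path_or_string) -> dendropy.Tree:
    """Read a single newick tree, requiring branch lengths on non-root edges."""
    data = str(path_or_string)
    if Path(data).exists():
        data = Path(data).read_text()
    try:
        tree = dendropy.Tree.get(data=data, schema="newick")
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValueError("tree is missing branch lengths, which are required")
    return tree


def load_table1_fixture(species: str) -> FeatureTable:
    """The shipped genome-organisation fixtures: 'PT' or 'TM'."""
    key = species.upper()
    if key not in {"PT", "TM"}:
        raise ValueError("species must be 'PT' or 'TM'")
    ref = importlib.resources.files("mitocomp.data") / f"table1_{key.lower()}.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_feature_table(path)


def write_provenance(path, config: dict, seed: int | None = None) -> None:
    """Machine-readable run record written beside every CLI output."""
    from . import __version__

    record = {"package": "mitocomp", "version": __version__, "seed": seed, "config": config}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
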