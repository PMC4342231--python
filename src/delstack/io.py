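"""Readers and writers for the pipeline's tabular and sequence formats.

Tabular conventions:

* cross tables — CSV with columns ``gene, parent_labels, index, n_screened``
  then one column per detected class (``A,B,D,AB,AD,BD,ABD``); an empty cell
  means the class was not recorded for that cross.
* SNP tables — tab-separated with columns ``sample_id, scaffold_ID, gene_ID,
  ref_position, ref_type, num_variants, allele_variants, frequency,
  coverage``; positions are 1-based on disk, 0-based in memory.
* intactness calls — tab-separated gene x subgenome matrix with values
  intact/deleted/unknown.
* marker panels — CSV ``gene_id, offset_kb, label``.
* homology hits — tab-separated ``query_gene, subject_arm, identity,
  align_length, e_value``.
* scaffolds — CSV ``scaffold_id, length, genes`` (gene ids ';'-separated).

Sequences use FASTA/FASTQ via Biopython; FASTQ qualities are ignored on read
and written as a constant placeholder.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon_caller import AmpliconRead, IntactnessCall, ReferenceSeq, SnpRecord
from .cross_model import DetectedClass, ObservedCrossTable, cross_from_index
from .synteny_map import (
    DeletionInterval,
    Marker,
    MarkerPanel,
    ScaffoldRecord,
    SyntenyHit,
)

CLASS_COLUMNS = ("A", "B", "D", "AB", "AD", "BD", "ABD")

SNP_TABLE_COLUMNS = (
    "sample_id",
    "scaffold_ID",
    "gene_ID",
    "ref_position",
    "ref_type",
    "num_variants",
    "allele_variants",
    "frequency",
    "coverage",
)


def _packaged(name: str):
    return resources.files("delstack.data").joinpath(name)


# ---------------------------------------------------------------- marker panel

def load_marker_panel(path: Optional[str] = None) -> MarkerPanel:
    """Load a marker panel CSV; default is the packaged 21-marker panel."""
    source = Path(path) if path is not None else _packaged("marker_panel.csv")
    with (open(source) if isinstance(source, Path) else source.open()) as fh:
        rows = list(csv.DictReader(fh))
    markers = [
        Marker(r["gene_id"], float(r["offset_kb"]), r.get("label", ""))
        for r in rows
    ]
    return MarkerPanel(markers)


# ---------------------------------------------------------------- cross tables

def _parse_cross_rows(rows: Sequence[dict]) -> List[ObservedCrossTable]:
    tables = []
    for r in rows:
        counts: Dict[DetectedClass, int] = {}
        for col in CLASS_COLUMNS:
            val = (r.get(col) or "").strip()
            if val not in ("", "-"):
                counts[DetectedClass.from_label(col)] = int(val)
        cross = cross_from_index(int(r["index"]), label=r.get("parent_labels", ""))
        tables.append(
            ObservedCrossTable(
                cross=cross,
                n=int(r["n_screened"]),
                counts=counts,
                gene=r.get("gene", ""),
            )
        )
    return tables


def load_cross_tables(path: Optional[str] = None) -> List[ObservedCrossTable]:
    """Load a cross-observation CSV (see module docstring for columns)."""
    if path is None:
        raise ValueError("a cross-table path is required")
    with open(path) as fh:
        return _parse_cross_rows(list(csv.DictReader(fh)))


def load_tetra_crosses() -> List[ObservedCrossTable]:
    """Packaged tetra-production crosses (primary x primary screens)."""
    with _packaged("table1_crosses.csv").open() as fh:
        return _parse_cross_rows(list(csv.DictReader(fh)))


def load_hexa_crosses() -> List[ObservedCrossTable]:
    """Packaged hexa-production crosses (tetra x tetra / tetra x primary)."""
    with _packaged("table2_crosses.csv").open() as fh:
        return _parse_cross_rows(list(csv.DictReader(fh)))


def write_cross_tables(tables: Sequence[ObservedCrossTable], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gene", "parent_labels", "index", "n_screened", *CLASS_COLUMNS])
        for t in tables:
            row = [t.gene, t.cross.label, t.cross.index, t.n]
            for col in CLASS_COLUMNS:
                cls = DetectedClass.from_label(col)
                row.append(t.counts[cls] if cls in t.counts else "")
            writer.writerow(row)


# ------------------------------------------------------------------- sequences

def write_fasta(refs: Sequence[ReferenceSeq], path: str) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.ref_id, description="") for r in refs
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> List[ReferenceSeq]:
    return [
        ReferenceSeq(ref_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(path, "fasta")
    ]


def write_fastq(reads: Sequence[AmpliconRead], path: str) -> None:
    """Write reads as FASTQ with placeholder qualities (Q40 throughout)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_reads(path: str, sample_id: str) -> List[AmpliconRead]:
    """Read FASTQ or FASTA reads; qualities, if any, are ignored."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    return [
        AmpliconRead(read_id=rec.id, sequence=str(rec.seq), sample_id=sample_id)
        for rec in SeqIO.parse(path, fmt)
    ]


# ------------------------------------------------------------------ SNP tables

def write_snp_table(records: Sequence[SnpRecord], sample_id: str, path: str) -> None:
    """Export a per-sample SNP table (1-based positions on disk)."""
    variants_per_pos: Dict[Tuple[str, int], int] = {}
    for r in records:
        k = (r.gene_id, r.ref_position)
        variants_per_pos[k] = variants_per_pos.get(k, 0) + 1
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(SNP_TABLE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    sample_id,
                    r.scaffold_id,
                    r.gene_id,
                    r.ref_position + 1,
                    r.ref_type,
                    variants_per_pos[(r.gene_id, r.ref_position)],
                    r.allele_variant,
                    f"{r.frequency:.2f}",
                    r.coverage,
                ]
            )


def read_snp_table(path: str) -> Tuple[str, List[SnpRecord]]:
    """Read a per-sample SNP table; returns (sample_id, records)."""
    records: List[SnpRecord] = []
    sample_ids = set()
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sample_ids.add(row["sample_id"])
            records.append(
                SnpRecord(
                    scaffold_id=row["scaffold_ID"],
                    gene_id=row["gene_ID"],
                    ref_position=int(row["ref_position"]) - 1,
                    ref_type=row["ref_type"],
                    allele_variant=row["allele_variants"],
                    frequency=float(row["frequency"]),
                    coverage=int(row["coverage"]),
                )
            )
    if len(sample_ids) > 1:
        raise ValueError(f"SNP table {path} mixes samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop() if sample_ids else Path(path).stem
    return sample_id, records


# ------------------------------------------------------------------ call matrix

def write_calls_matrix(
    calls: Mapping[str, Sequence[IntactnessCall]], path: str
) -> None:
    """Gene x (sample, subgenome) intactness matrix, tab-separated.

    ``calls`` maps a sample id to its per-gene calls (all subgenomes mixed).
    """
    columns: List[Tuple[str, str]] = []
    per_cell: Dict[Tuple[str, str, str], str] = {}
    genes: List[str] = []
    for sample, sample_calls in calls.items():
        for c in sample_calls:
            col = (sample, c.subgenome)
            if col not in columns:
                columns.append(col)
            if c.gene_id not in genes:
                genes.append(c.gene_id)
            per_cell[(c.gene_id, sample, c.subgenome)] = c.status
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", *[f"{s}:{sub}" for s, sub in columns]])
        for g in genes:
            writer.writerow(
                [g, *[per_cell.get((g, s, sub), "unknown") for s, sub in columns]]
            )


def read_calls_matrix(path: str) -> Dict[Tuple[str, str], Dict[str, str]]:
    """Returns {(sample_id, subgenome): {gene_id: status}}."""
    out: Dict[Tuple[str, str], Dict[str, str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        keys = []
        for col in header[1:]:
            sample, _, sub = col.rpartition(":")
            keys.append((sample, sub))
            out[(sample, sub)] = {}
        for row in reader:
            gene = row[0]
            for key, val in zip(keys, row[1:]):
                out[key][gene] = val
    return out


# ------------------------------------------------------------------- intervals

def write_intervals(
    intervals: Mapping[Tuple[str, str], DeletionInterval], path: str
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "mutant_id",
                "subgenome",
                "min_size_kb",
                "max_size_kb",
                "up_bound_marker",
                "down_bound_marker",
                "up_open",
                "down_open",
            ]
        )
        for (mutant, sub), iv in intervals.items():
            writer.writerow(
                [
                    mutant,
                    sub,
                    iv.min_size,
                    iv.max_size if iv.max_size is not None else "open",
                    iv.up_bound_marker,
                    iv.down_bound_marker,
                    iv.up_open,
                    iv.down_open,
                ]
            )


# ---------------------------------------------------------- hits and scaffolds

def load_hits_table(path: str) -> Dict[str, List[SyntenyHit]]:
    """Tab-separated homology hits, grouped by query gene."""
    out: Dict[str, List[SyntenyHit]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            hit = SyntenyHit(
                query_gene=row["query_gene"],
                subject_arm=row["subject_arm"],
                identity=float(row["identity"]),
                align_length=int(row["align_length"]),
                e_value=float(row["e_value"]),
            )
            out.setdefault(hit.query_gene, []).append(hit)
    return out


def load_scaffold_table(path: str) -> List[ScaffoldRecord]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            genes = {g for g in row["genes"].split(";") if g}
            out.append(
                ScaffoldRecord(
                    scaffold_id=row["scaffold_id"],
                    length=int(row["length"]),
                    genes=genes,
                )
            )
    return out
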