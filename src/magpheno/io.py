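"""Readers and writers for the plain-text formats the pipeline exchanges.

Count matrices are TSV with features in rows and a header row of sample
ids; metadata is TSV keyed by sample_id; alignment hits use the
BLAST/DIAMOND tabular (outfmt-6) column dialect with a sidecar role map;
gene sets use GMT; sequences use FASTA; gene calls use GFF3 (1-based,
inclusive).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthdata import OUTFMT6_COLUMNS, GenomeRecord

# --- tabular -----------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_meta_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_meta_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_hits_tsv(path: str | Path) -> pd.DataFrame:
    """outfmt-6 dialect: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore (no header)."""
    return pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, header=None)


def write_hits_tsv(hits: pd.DataFrame, path: str | Path) -> None:
    hits[OUTFMT6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_role_map_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_role_map_tsv(refmap: pd.DataFrame, path: str | Path) -> None:
    refmap.to_csv(path, sep="\t", index=False)


def write_bpm_tsv(bpm: pd.DataFrame, path: str | Path) -> None:
    bpm.to_csv(path, sep="\t", index_label="genome")


def read_bpm_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genome")


# --- pathway definitions / truth ---------------------------------------------

def write_pathway_json(pathway_definitions: Mapping[str, list[set[str]]], path: str | Path) -> None:
    payload = {p: [sorted(v) for v in variants] for p, variants in sorted(pathway_definitions.items())}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_pathway_json(path: str | Path) -> dict[str, list[set[str]]]:
    payload = json.loads(Path(path).read_text())
    return {p: [set(v) for v in variants] for p, variants in payload.items()}


def write_truth_json(truth: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True, default=str))


# --- sequence formats --------------------------------------------------------

def write_genome_fasta(genome: GenomeRecord, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description=p.role or "")
        for p in sorted(genome.proteins, key=lambda p: p.protein_id)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_gff3(genome: GenomeRecord, path: str | Path, gene_span: int = 1200) -> None:
    """Gene calls as GFF3 CDS features (1-based, inclusive coordinates).

    Synthetic genomes carry ordinal gene positions; each gene occupies a
    ``gene_span`` window on its contig with nucleotide length 3x the
    protein length.
    """
    lines = ["##gff-version 3"]
    for p in sorted(genome.proteins, key=lambda p: (p.contig, p.position, p.protein_id)):
        start = (p.position - 1) * gene_span + 1
        end = start + 3 * len(p.sequence) - 1
        attrs = f"ID={p.protein_id};family={p.family}"
        if p.role:
            attrs += f";role={p.role}"
        if p.fragment_of:
            attrs += f";fragment_of={p.fragment_of}"
        lines.append(
            "\t".join(
                [p.contig, "magpheno", "CDS", str(start), str(end), ".", "+", "0", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --- gene sets ---------------------------------------------------------------

def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(set(members))]) for name, members in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets[parts[0]] = parts[2:]
    return sets


# --- ranked lists / results --------------------------------------------------

def write_ranked_tsv(ranked: pd.Series, path: str | Path) -> None:
    ranked.rename("metric").to_frame().to_csv(path, sep="\t", index_label="feature")


def read_ranked_tsv(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col="feature")
    return frame["metric"]


def write_table_tsv(table: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    table.to_csv(path, sep="\t", index_label=index_label)
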