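"""Sequence and table IO helpers (FASTA/FASTQ via Biopython, plain or gzip)."""

from __future__ import annotations

import csv
import gzip
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return path.open()


def _fmt_for(path: Path) -> str:
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    ext = Path(name).suffix.lower()
    if ext in (".fq", ".fastq"):
        return "fastq"
    if ext in (".fa", ".fna", ".fasta", ".ffn"):
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path.name!r}")


def read_seqs(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (record_id, sequence) from a FASTA/FASTQ file, gzip-aware.

    Quality values are ignored; only composition matters downstream.
    """
    path = Path(path)
    fmt = _fmt_for(path)
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, fmt):
            yield record.id, str(record.seq)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_tsv(
    truth: Mapping[str, str],
    tree,
    path: str | Path,
    representation_status: Mapping[str, str] | None = None,
) -> None:
    """read_id, source genome, true leaf taxon, and representation status."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("read_id", "genome_id", "taxon_id", "representation_status"))
        for rid in sorted(truth):
            gid = truth[rid]
            status = "known" if representation_status is None else representation_status.get(rid, "known")
            writer.writerow((rid, gid, tree.genome_to_taxon[gid], status))


def read_truth_tsv(path: str | Path) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Inverse of :func:`write_truth_tsv`: (read->genome, read->taxon, read->status)."""
    genomes: dict[str, str] = {}
    taxa: dict[str, str] = {}
    status: dict[str, str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            genomes[row["read_id"]] = row["genome_id"]
            taxa[row["read_id"]] = row["taxon_id"]
            status[row["read_id"]] = row.get("representation_status", "known")
    return genomes, taxa, status
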