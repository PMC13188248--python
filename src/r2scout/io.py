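"""File I/O: FASTA/FASTQ via Biopython, GFF3 and TSV writers.

Internal coordinates are 0-based half-open throughout the package; GFF3 is
1-based inclusive per the standard, and :func:`to_gff_interval` is the one
audited converter between the two conventions.
"""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "to_gff_interval",
    "write_gff3",
]


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with _open(path, "wt") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            out.append((rec.description, str(rec.seq).upper(), qual))
    return out


def write_fastq(reads, path) -> None:
    with _open(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def to_gff_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (the only place this
    conversion happens)."""
    if not (0 <= start < end):
        raise ValueError(f"invalid interval [{start}, {end})")
    return start + 1, end


def write_gff3(features, path, source: str = "r2scout") -> None:
    """Write features as GFF3.

    Each feature is a mapping with keys: contig_id, start, end (0-based
    half-open), strand, type, score (optional), attributes (dict).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            g_start, g_end = to_gff_interval(int(f["start"]), int(f["end"]))
            attrs = ";".join(f"{k}={v}" for k, v in f.get("attributes", {}).items())
            score = f.get("score")
            fh.write(
                "\t".join(
                    [
                        str(f["contig_id"]),
                        source,
                        f.get("type", "mobile_genetic_element"),
                        str(g_start),
                        str(g_end),
                        "." if score is None else f"{score:g}",
                        f.get("strand", "+"),
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )
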