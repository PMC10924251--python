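"""Standard-format I/O: FASTA, FASTQ (plain or gzip), and annotated TSV.

Every table written by the pipeline carries ``#``-prefixed metadata header
lines (tool version, seed, parameters) so artifacts are self-describing and
diffable; readers skip those lines transparently.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed FASTA/FASTQ/TSV input."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: upper-case sequence}`` map.

    Duplicate record ids are an error; sequences are normalized to upper case.
    """
    records: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with _open_text(path, "wt") as fh:
        SeqIO.write(seqs, fh, "fasta")


# ---------------------------------------------------------------- FASTQ


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream ``(id, sequence, quality)`` from a Phred+33 FASTQ, gzip-transparent.

    A truncated or inconsistent record raises :class:`FormatError` with the
    offending record number.
    """
    with _open_text(path) as fh:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                if len(seq) != len(qual):
                    raise FormatError(
                        f"{path}: record {n} ({title.split()[0]}): sequence and "
                        f"quality lengths differ ({len(seq)} vs {len(qual)})"
                    )
                yield title.split()[0], seq, qual
        except ValueError as exc:  # Biopython parse failure
            raise FormatError(f"{path}: malformed FASTQ near record {n + 1}: {exc}") from exc


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> int:
    """Write 4-line Phred+33 FASTQ records; ``.gz`` suffix enables gzip."""
    n = 0
    with _open_text(path, "wt") as fh:
        buf = io.StringIO()
        for name, seq, qual in reads:
            if len(seq) != len(qual):
                raise FormatError(f"record {name}: sequence/quality length mismatch")
            buf.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
            if buf.tell() > 1 << 20:
                fh.write(buf.getvalue())
                buf = io.StringIO()
        fh.write(buf.getvalue())
    return n


# ---------------------------------------------------------------- TSV


def write_tsv(path: str | Path, df: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write a TSV with ``#key: value`` metadata header lines."""
    with _open_text(path, "wt") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"#{key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_tsv`; returns (table, metadata)."""
    metadata: dict[str, str] = {}
    with _open_text(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].partition(":")
            metadata[key.strip()] = value.strip()
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    return df, metadata
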