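"""File format helpers: FASTA, FASTQ (Phred+33), taxonomy TSV, small writers."""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO

VALID_BASES = set("ACGTN")


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred scores."""

    id: str
    bases: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases vs "
                f"{len(self.qualities)} quality scores"
            )


def _open_text(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; sequences uppercased and validated as A/C/G/T/N."""
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"{path}: record {rec.id!r} has invalid bases {sorted(bad)}")
            records.append((rec.id, seq))
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[ReadRecord]:
    """Parse Phred+33 FASTQ; malformed records raise naming the record number."""
    with _open_text(path) as fh:
        yield from parse_fastq(fh, name=str(path))


def parse_fastq(lines: Iterable[str], name: str = "<stream>") -> Iterator[ReadRecord]:
    it = iter(lines)
    n = 0
    while True:
        header = next(it, None)
        if header is None:
            return
        header = header.rstrip("\n")
        if not header:  # trailing blank line(s)
            for extra in it:
                if extra.strip():
                    raise ValueError(f"{name}: junk after record {n}")
            return
        n += 1
        if not header.startswith("@"):
            raise ValueError(f"{name}: record {n}: header does not start with '@'")
        try:
            bases = next(it).rstrip("\n")
            plus = next(it).rstrip("\n")
            quals = next(it).rstrip("\n")
        except StopIteration:
            raise ValueError(f"{name}: record {n}: truncated record") from None
        if not plus.startswith("+"):
            raise ValueError(f"{name}: record {n}: missing '+' separator line")
        if len(bases) != len(quals):
            raise ValueError(
                f"{name}: record {n}: sequence and quality lengths differ"
            )
        bases = bases.upper()
        if set(bases) - VALID_BASES:
            raise ValueError(f"{name}: record {n}: invalid bases in sequence")
        yield ReadRecord(header[1:].split()[0] if header[1:] else f"read{n}",
                         bases, [ord(c) - 33 for c in quals])


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, bases, quality-string) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, bases, quals in reads:
            fh.write(f"@{rid}\n{bases}\n+\n{quals}\n")


def write_tsv(path, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path) -> tuple[list[str], list[list[str]]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return [], []
    header = lines[0].split("\t")
    return header, [ln.split("\t") for ln in lines[1:]]
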