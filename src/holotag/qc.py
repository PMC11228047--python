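"""Read quality filtering and sequenced-tag extraction.

Filters (applied in order, first failure wins):
  1. any ambiguous base call (N)
  2. a single-base run longer than 10 bp
  3. more than 20% of bases with quality score below 10
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .enzyme import EnzymeSpec, canonicalize, match_iupac, revcomp
from .io import ReadRecord

REASON_N = "N"
REASON_HOMOPOLYMER = "homopolymer"
REASON_LOW_QUALITY = "low_quality"

MAX_HOMOPOLYMER = 10        # runs strictly longer are rejected
LOW_Q = 10                  # a base is low quality when Q < 10
MAX_LOW_Q_FRACTION = 0.20   # strictly more than 20% low-Q bases rejects


def longest_run(bases: str) -> int:
    best = run = 1 if bases else 0
    for a, b in zip(bases, bases[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def filter_read(read: ReadRecord) -> tuple[bool, Optional[str]]:
    """(keep, reason) — reason is None when kept, else the first failing rule."""
    if len(read.bases) != len(read.qualities):
        raise ValueError(f"read {read.id!r}: base/quality length mismatch")
    if "N" in read.bases:
        return False, REASON_N
    if longest_run(read.bases) > MAX_HOMOPOLYMER:
        return False, REASON_HOMOPOLYMER
    n_low = sum(1 for q in read.qualities if q < LOW_Q)
    if read.bases and n_low / len(read.bases) > MAX_LOW_Q_FRACTION:
        return False, REASON_LOW_QUALITY
    return True, None


def extract_sequenced_tag(read: ReadRecord, enzyme: EnzymeSpec) -> Optional[str]:
    """Canonical tag of the leftmost full-length tag window in the read.

    Both strands are scanned; a placement is valid when the recognition span
    plus both flanks fit inside the read.  The leftmost window start on the
    forward orientation wins (``+`` before ``-`` on ties).
    """
    seq = read.bases
    m = len(enzyme.recognition)
    rc_pattern = revcomp(enzyme.recognition)
    candidates: list[tuple[int, int, str]] = []  # (window start, strand order, window)
    for s in range(len(seq) - m + 1):
        window = seq[s : s + m]
        if match_iupac(enzyme.recognition, window):
            start, end = s - enzyme.flank5, s + m + enzyme.flank3
            if start >= 0 and end <= len(seq):
                candidates.append((start, 0, seq[start:end]))
        if match_iupac(rc_pattern, window):
            start, end = s - enzyme.flank3, s + m + enzyme.flank5
            if start >= 0 and end <= len(seq):
                candidates.append((start, 1, seq[start:end]))
    candidates = [c for c in candidates if "N" not in c[2]]
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]))
    return canonicalize(candidates[0][2])


@dataclass
class QCStats:
    raw_reads: int = 0
    hq_reads: int = 0
    tags_with_site: int = 0
    no_site: int = 0
    rejections: dict = field(default_factory=lambda: {
        REASON_N: 0, REASON_HOMOPOLYMER: 0, REASON_LOW_QUALITY: 0,
    })
    rate_undefined: bool = False

    @property
    def hq_rate(self) -> float:
        """High-quality read percentage to 2 decimals (0.00, flagged, if no reads)."""
        if self.raw_reads == 0:
            return 0.00
        return round(100.0 * self.hq_reads / self.raw_reads, 2)

    def validate(self) -> None:
        assert self.hq_reads + sum(self.rejections.values()) == self.raw_reads
        assert self.tags_with_site + self.no_site == self.hq_reads

    def to_dict(self) -> dict:
        self.validate()
        return {
            "raw_reads": self.raw_reads,
            "hq_reads": self.hq_reads,
            "hq_rate": self.hq_rate,
            "rate_undefined": self.rate_undefined,
            "tags_with_site": self.tags_with_site,
            "no_site": self.no_site,
            "rejections": dict(self.rejections),
        }


def hq_rate(raw: int, hq: int) -> float:
    """High-quality read rate in percent, rounded to 2 decimals."""
    if raw <= 0:
        raise ValueError("raw read count must be positive")
    if hq > raw:
        raise ValueError("hq reads exceed raw reads")
    return round(100.0 * hq / raw, 2)


def process_reads(
    reads: Iterable[ReadRecord], enzyme: EnzymeSpec, stats: Optional[QCStats] = None
) -> Iterator[tuple[str, str]]:
    """Yield (read id, canonical tag) for surviving reads, tallying into stats."""
    if stats is None:
        stats = QCStats()
    for read in reads:
        stats.raw_reads += 1
        keep, reason = filter_read(read)
        if not keep:
            stats.rejections[reason] += 1
            continue
        stats.hq_reads += 1
        tag = extract_sequenced_tag(read, enzyme)
        if tag is None:
            stats.no_site += 1
            continue
        stats.tags_with_site += 1
        yield read.id, tag


def process_fastq(reads: Iterable[ReadRecord], enzyme: EnzymeSpec) -> tuple[list[tuple[str, str]], QCStats]:
    """Materialized variant of :func:`process_reads` returning (tags, stats)."""
    stats = QCStats()
    tags = list(process_reads(reads, enzyme, stats))
    if stats.raw_reads == 0:
        stats.rate_undefined = True
    stats.validate()
    return tags, stats
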