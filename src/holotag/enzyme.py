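"""Type IIB restriction enzyme model and in-silico digestion.

A type IIB enzyme cuts on both sides of a (possibly degenerate) recognition
site and excises a fixed-length fragment — the tag.  Tags are identified by
their *canonical* sequence, the lexicographic minimum of the sequence and its
reverse complement, so that the same locus sequenced from either strand maps
to one key.

Coordinates are 0-based, half-open, on the forward strand of the source
sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "IUPAC",
    "EnzymeSpec",
    "TagLocus",
    "BSAXI",
    "ENZYMES",
    "revcomp",
    "canonicalize",
    "match_iupac",
    "find_recognition_sites",
    "extract_tags",
]

#: IUPAC nucleotide codes -> the set of concrete bases each code stands for.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement; accepts IUPAC codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(sequence: str) -> str:
    """Strand-normalized key: min(sequence, reverse complement).

    Idempotent, and invariant under reverse complement of the input.
    Only concrete A/C/G/T sequences have a canonical form.
    """
    if not sequence or any(b not in "ACGT" for b in sequence):
        raise ValueError(f"non-ACGT character in sequence {sequence!r}")
    rc = revcomp(sequence)
    return sequence if sequence <= rc else rc


def match_iupac(pattern: str, window: str) -> bool:
    """True iff every window base lies in the IUPAC class of the pattern base.

    A window base of N matches nothing (ambiguous genome positions never
    produce a site).
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window)}"
        )
    for p, b in zip(pattern, window):
        if b not in "ACGTN":
            raise ValueError(f"invalid base {b!r} in window")
        if b not in IUPAC[p]:
            return False
    return True


@dataclass(frozen=True)
class EnzymeSpec:
    """A type IIB enzyme: bipartite IUPAC recognition plus retained flanks.

    ``flank5``/``flank3`` are the number of bases retained 5'/3' of the
    recognition span *on the tag's source strand*; the excised tag length is
    ``flank5 + len(recognition) + flank3``.
    """

    name: str
    recognition: str
    flank5: int
    flank3: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("empty recognition pattern")
        bad = [c for c in self.recognition if c not in IUPAC]
        if bad:
            raise ValueError(f"non-IUPAC characters in recognition: {bad}")
        if self.flank5 < 0 or self.flank3 < 0:
            raise ValueError("flank lengths must be non-negative")

    @property
    def tag_length(self) -> int:
        return self.flank5 + len(self.recognition) + self.flank3

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "recognition": self.recognition,
            "flank5": self.flank5,
            "flank3": self.flank3,
            "tag_length": self.tag_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnzymeSpec":
        spec = cls(d["name"], d["recognition"], int(d["flank5"]), int(d["flank3"]))
        if "tag_length" in d and int(d["tag_length"]) != spec.tag_length:
            raise ValueError(
                f"tag_length {d['tag_length']} inconsistent with "
                f"flank5 + |recognition| + flank3 = {spec.tag_length}"
            )
        return spec


#: Default enzyme. Offsets from REBASE; the excised duplex footprint spans
#: 12 nt 5' and 10 nt 3' of the AC(N5)CTCC recognition span (33 bp tag).
BSAXI = EnzymeSpec("BsaXI", "ACNNNNNCTCC", 12, 10)

ENZYMES: dict[str, EnzymeSpec] = {"BsaXI": BSAXI}


@dataclass(frozen=True)
class TagLocus:
    """One excised tag: forward-strand coordinates plus strand-local sequence."""

    source_id: str
    start: int
    end: int
    strand: str
    sequence: str  # as read on `strand`
    canonical: str = field(default="")

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.canonical:
            object.__setattr__(self, "canonical", canonicalize(self.sequence))


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping sites are all reported
    body = "".join(
        IUPAC[c] if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in pattern
    )
    return re.compile(f"(?=({body}))")


def find_recognition_sites(seq: str, enzyme: EnzymeSpec) -> list[tuple[int, str]]:
    """All recognition-site starts on either strand, as forward coordinates.

    A palindromic span matching both strands is reported once, as ``+``.
    Sorted by start (``+`` before ``-`` at equal start).
    """
    if not seq:
        raise ValueError("empty sequence")
    fwd = {m.start() for m in _pattern_regex(enzyme.recognition).finditer(seq)}
    rev = {m.start() for m in _pattern_regex(revcomp(enzyme.recognition)).finditer(seq)}
    sites = [(s, "+") for s in fwd]
    sites += [(s, "-") for s in rev if s not in fwd]
    return sorted(sites)


def extract_tags(seq: str, enzyme: EnzymeSpec, source_id: str = "seq") -> list[TagLocus]:
    """Excise one fixed-length tag per recognition site.

    Sites whose flanks run off either end are skipped, as are tags containing
    N.  The returned sequence is read on the site's strand, so the recognition
    pattern always matches at offset ``flank5`` of the tag itself.
    """
    if not seq:
        return []
    m = len(enzyme.recognition)
    out: list[TagLocus] = []
    for s, strand in find_recognition_sites(seq, enzyme):
        if strand == "+":
            start, end = s - enzyme.flank5, s + m + enzyme.flank3
        else:
            start, end = s - enzyme.flank3, s + m + enzyme.flank5
        if start < 0 or end > len(seq):
            continue
        window = seq[start:end]
        if "N" in window:
            continue
        sequence = window if strand == "+" else revcomp(window)
        out.append(TagLocus(source_id, start, end, strand, sequence))
    return out
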