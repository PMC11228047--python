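"""Shared fixtures: toy enzymes with hand-checkable offsets, db builders."""

from __future__ import annotations

import pytest

from holotag.classify import PartitionResult
from holotag.database import (
    HoloDB,
    RANKS,
    RemovalReport,
    TaxonomyTable,
)
from holotag.enzyme import EnzymeSpec, match_iupac, revcomp


@pytest.fixture
def toy() -> EnzymeSpec:
    """recognition ACGT (self-reverse-complementary), flanks 2/2, tag length 8."""
    return EnzymeSpec("Toy", "ACGT", 2, 2)


@pytest.fixture
def toy_degenerate() -> EnzymeSpec:
    """recognition ACNNTT (not palindromic), flanks 1/1, tag length 8."""
    return EnzymeSpec("ToyDeg", "ACNNTT", 1, 1)


def naive_extract(seq: str, enz: EnzymeSpec) -> list[tuple[int, int, str, str]]:
    """Brute-force O(n*m) double-strand scanner: (start, end, strand, sequence)."""
    m = len(enz.recognition)
    out = []
    for s in range(max(len(seq) - m + 1, 0)):
        win = seq[s : s + m]
        fwd = match_iupac(enz.recognition, win)
        rev = match_iupac(revcomp(enz.recognition), win)
        if fwd:
            start, end = s - enz.flank5, s + m + enz.flank3
            if 0 <= start and end <= len(seq) and "N" not in seq[start:end]:
                out.append((start, end, "+", seq[start:end]))
        elif rev:
            start, end = s - enz.flank3, s + m + enz.flank5
            if 0 <= start and end <= len(seq) and "N" not in seq[start:end]:
                out.append((start, end, "-", revcomp(seq[start:end])))
    return out


def empty_report() -> RemovalReport:
    zeros = {rk: (0, 0.0) for rk in RANKS}
    return RemovalReport(0, 0.0, 0, 0.0, dict(zeros), dict(zeros))


def make_db(
    enzyme: EnzymeSpec,
    host_tags: set[str] = frozenset(),
    markers: dict[str, str] | None = None,
) -> HoloDB:
    """Hand-built HoloDB; tags must already be canonical and of tag length."""
    markers = dict(markers or {})
    taxon_markers: dict[str, set[str]] = {}
    for tag, sp in markers.items():
        taxon_markers.setdefault(sp, set()).add(tag)
    lineages = {
        sp: ("Bacteria", "p0", "c0", "o0", "f0", "g0", sp) for sp in taxon_markers
    }
    return HoloDB(
        host_tags=set(host_tags),
        host_loci={},
        markers=markers,
        taxon_markers=taxon_markers,
        lineages=lineages,
        rank="species",
        enzyme=enzyme,
        report=empty_report(),
    )


def make_partition(
    species_hits: dict[str, dict[str, int]], n_host: int = 0, n_unassigned: int = 0
) -> PartitionResult:
    """PartitionResult from {species: {marker: reads}}."""
    part = PartitionResult()
    part.n_host = n_host
    part.n_unassigned = n_unassigned
    for sp, hits in species_hits.items():
        for marker, n in hits.items():
            part.species_reads[sp] += n
            part.species_marker_hits[sp][marker] += n
    return part


def simple_taxonomy(
    species_of: dict[str, str], genus_of: dict[str, str] | None = None
) -> TaxonomyTable:
    """One-kingdom taxonomy; genus defaults to 'genus_<species>'."""
    genus_of = genus_of or {}
    lineages = {}
    for gid, sp in species_of.items():
        genus = genus_of.get(sp, f"genus_{sp}")
        lineages[gid] = ("Bacteria", "p0", "c0", "o0", "f0", genus, sp)
    return TaxonomyTable(lineages)
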