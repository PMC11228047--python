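"""Partition sequenced tags against a hologenome database and profile species.

Assignment is exact canonical matching by default; a small mismatch radius is
available to emulate alignment-style tolerance.  Mapping rates are reported
over *assigned* tags only, so host% + microbe% = 100.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .database import HoloDB
from .enzyme import revcomp

HOST = "host"
MICROBE = "microbe"
UNASSIGNED = "unassigned"

DEFAULT_MIN_MARKERS_HIT = 5
DEFAULT_MIN_G_SCORE = 5.0


def hamming(a: str, b: str, limit: int | None = None) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d


@dataclass(frozen=True)
class Assignment:
    kind: str                      # HOST | MICROBE | UNASSIGNED
    label: Optional[str] = None    # species label when kind == MICROBE
    entry: Optional[str] = None    # matched db canonical tag
    distance: Optional[int] = None


def assign_tag(tag: str, db: HoloDB, max_mismatch: int = 0) -> Assignment:
    """Assign one canonical tag to host, a species, or unassigned.

    Exact canonical matches decide immediately.  With ``max_mismatch > 0`` the
    tag goes to the unique closest db entry within the radius (both
    orientations considered); ties across entries with *different*
    assignments are declared unassigned.
    """
    if len(tag) != db.tag_length:
        raise ValueError(f"tag length {len(tag)} != db tag length {db.tag_length}")
    if tag in db.host_tags:
        return Assignment(HOST, entry=tag, distance=0)
    if tag in db.markers:
        return Assignment(MICROBE, db.markers[tag], entry=tag, distance=0)
    if max_mismatch <= 0:
        return Assignment(UNASSIGNED)

    rc = revcomp(tag)
    best_d = max_mismatch + 1
    hits: list[tuple[str, Optional[str], str]] = []  # (kind, label, entry)
    for entry in db.host_tags:
        d = min(hamming(tag, entry, best_d), hamming(rc, entry, best_d))
        if d < best_d:
            best_d, hits = d, [(HOST, None, entry)]
        elif d == best_d and d <= max_mismatch:
            hits.append((HOST, None, entry))
    for entry, label in db.markers.items():
        d = min(hamming(tag, entry, best_d), hamming(rc, entry, best_d))
        if d < best_d:
            best_d, hits = d, [(MICROBE, label, entry)]
        elif d == best_d and d <= max_mismatch:
            hits.append((MICROBE, label, entry))
    if best_d > max_mismatch or not hits:
        return Assignment(UNASSIGNED)
    assignments = {(k, l) for k, l, _ in hits}
    if len(assignments) > 1:
        return Assignment(UNASSIGNED)  # ambiguous across assignments
    kind, label, entry = hits[0]
    return Assignment(kind, label, entry=entry, distance=best_d)


@dataclass
class PartitionResult:
    """Per-sample tag partition with Table-1-style mapping rates."""

    n_host: int = 0
    n_unassigned: int = 0
    species_reads: Counter = field(default_factory=Counter)
    species_marker_hits: dict = field(default_factory=lambda: defaultdict(Counter))
    host_tag_reads: Counter = field(default_factory=Counter)  # matched host entry -> reads

    @property
    def n_microbial(self) -> int:
        return sum(self.species_reads.values())

    @property
    def total(self) -> int:
        return self.n_host + self.n_microbial + self.n_unassigned

    @property
    def n_assigned(self) -> int:
        return self.n_host + self.n_microbial

    @property
    def rates_defined(self) -> bool:
        return self.n_assigned > 0

    @property
    def host_rate(self) -> Optional[float]:
        if not self.rates_defined:
            return None
        return round(100.0 * self.n_host / self.n_assigned, 2)

    @property
    def microbial_rate(self) -> Optional[float]:
        if not self.rates_defined:
            return None
        return round(100.0 * self.n_microbial / self.n_assigned, 2)

    def to_dict(self) -> dict:
        return {
            "total_tags": self.total,
            "host": self.n_host,
            "microbial": self.n_microbial,
            "unassigned": self.n_unassigned,
            "host_rate": self.host_rate,
            "microbial_rate": self.microbial_rate,
            "rates_defined": self.rates_defined,
        }


def partition_sample(
    tags: Iterable[tuple[str, str]], db: HoloDB, max_mismatch: int = 0
) -> PartitionResult:
    """Tally (read id, canonical tag) pairs into a PartitionResult."""
    part = PartitionResult()
    for _, tag in tags:
        a = assign_tag(tag, db, max_mismatch)
        if a.kind == HOST:
            part.n_host += 1
            part.host_tag_reads[a.entry] += 1
        elif a.kind == MICROBE:
            part.species_reads[a.label] += 1
            part.species_marker_hits[a.label][a.entry] += 1
        else:
            part.n_unassigned += 1
    assert part.n_host + part.n_microbial + part.n_unassigned == part.total
    return part


@dataclass
class SpeciesAbundance:
    species: str
    reads_on_markers: int
    distinct_markers_hit: int
    theoretical_markers: int
    g_score: float
    retained: bool
    relative_abundance: float


@dataclass
class AbundanceProfile:
    """Species-level profile; abundances of retained species sum to 1."""

    rows: dict[str, SpeciesAbundance]

    def abundance(self, species: str) -> float:
        row = self.rows.get(species)
        return row.relative_abundance if row is not None else 0.0

    def retained_species(self) -> list[str]:
        return sorted(s for s, r in self.rows.items() if r.retained)

    def abundances(self) -> dict[str, float]:
        return {s: self.rows[s].relative_abundance for s in self.retained_species()}


def profile_abundance(
    partition: PartitionResult,
    db: HoloDB,
    min_markers_hit: int = DEFAULT_MIN_MARKERS_HIT,
    min_g_score: float = DEFAULT_MIN_G_SCORE,
) -> AbundanceProfile:
    """Marker-hit density profile with a G-score false-positive filter.

    Raw density d_s = reads_on_markers / theoretical_markers; a species is
    retained iff it hits at least ``min_markers_hit`` distinct markers and
    G = sqrt(reads_on_markers * distinct_markers_hit) >= ``min_g_score``.
    Relative abundance is the retained-density fraction.
    """
    rows: dict[str, SpeciesAbundance] = {}
    densities: dict[str, float] = {}
    for species, reads in sorted(partition.species_reads.items()):
        markers_hit = len(partition.species_marker_hits[species])
        theoretical = db.theoretical_markers(species)
        assert theoretical > 0, f"species {species!r} has no markers in db"
        g = math.sqrt(reads * markers_hit)
        retained = markers_hit >= min_markers_hit and g >= min_g_score
        rows[species] = SpeciesAbundance(
            species, reads, markers_hit, theoretical, g, retained, 0.0
        )
        if retained:
            densities[species] = reads / theoretical
    total = sum(densities.values())
    if total > 0:
        for species, d in densities.items():
            rows[species].relative_abundance = d / total
        assert abs(sum(r.relative_abundance for r in rows.values()) - 1.0) < 1e-9
    return AbundanceProfile(rows)


def write_profile(profile: AbundanceProfile, db: HoloDB, path) -> None:
    from . import io as htio

    rows = []
    for species in sorted(profile.rows):
        r = profile.rows[species]
        lineage = ";".join(db.lineages.get(species, (species,)))
        rows.append((
            species, lineage, r.reads_on_markers, r.distinct_markers_hit,
            r.theoretical_markers, f"{r.g_score:.4f}", int(r.retained),
            f"{r.relative_abundance:.10g}",
        ))
    htio.write_tsv(path, ["species", "lineage", "reads_on_markers",
                          "distinct_markers_hit", "theoretical_markers",
                          "g_score", "retained", "relative_abundance"], rows)


def read_profile(path) -> AbundanceProfile:
    from . import io as htio

    _, rows = htio.read_tsv(path)
    out = {}
    for row in rows:
        out[row[0]] = SpeciesAbundance(
            row[0], int(row[2]), int(row[3]), int(row[4]),
            float(row[5]), bool(int(row[6])), float(row[7]),
        )
    return AbundanceProfile(out)


def profile_correlation(p1: AbundanceProfile, p2: AbundanceProfile) -> Optional[float]:
    """Pearson r of the two abundance vectors over the union of retained species.

    None (undefined) when the union holds fewer than 2 species or either
    vector is constant.
    """
    union = sorted(set(p1.retained_species()) | set(p2.retained_species()))
    if len(union) < 2:
        return None
    x = np.array([p1.abundance(s) for s in union])
    y = np.array([p2.abundance(s) for s in union])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])
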