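"""Hologenome database construction.

Pipeline: digest the host genome into tags and keep the genome-wide
single-copy ("unique") ones; digest every microbial genome and keep
taxon-specific single-copy markers at the target rank; then remove the
cross-redundancy between the two sides and report its impact.
"""

from __future__ import annotations

import json
import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import io as htio
from .enzyme import EnzymeSpec, TagLocus, extract_tags

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class TaxonomyTable:
    """genome_id -> complete 7-rank lineage (kingdom..species)."""

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self._lineages: dict[str, tuple[str, ...]] = {}
        for gid, lineage in lineages.items():
            lineage = tuple(lineage)
            if len(lineage) != len(RANKS) or any(not x for x in lineage):
                raise ValueError(f"genome {gid!r}: lineage must have {len(RANKS)} non-empty ranks")
            self._lineages[gid] = lineage

    def __contains__(self, gid: str) -> bool:
        return gid in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def genomes(self) -> list[str]:
        return sorted(self._lineages)

    def lineage(self, gid: str) -> tuple[str, ...]:
        return self._lineages[gid]

    def taxon(self, gid: str, rank: str) -> str:
        return self._lineages[gid][RANKS.index(rank)]

    def ancestor(self, species: str, rank: str) -> str:
        """Rank-R label of a species taxon (consistent lineages assumed)."""
        i = RANKS.index(rank)
        for lineage in self._lineages.values():
            if lineage[-1] == species:
                return lineage[i]
        raise KeyError(species)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        header, rows = htio.read_tsv(path)
        expected = ["genome_id", *RANKS]
        if [h.lower() for h in header] != expected:
            raise ValueError(f"{path}: expected columns {expected}, got {header}")
        return cls({r[0]: r[1:] for r in rows})

    def to_tsv(self, path) -> None:
        htio.write_tsv(path, ["genome_id", *RANKS],
                       ((g, *self._lineages[g]) for g in self.genomes()))


@dataclass
class HostTagSet:
    """All host tag loci plus the distinct and genome-wide single-copy sets."""

    all_loci: list[TagLocus]
    distinct: set[str]
    unique: set[str]
    enzyme: EnzymeSpec

    def __post_init__(self) -> None:
        assert self.unique <= self.distinct
        assert len(self.all_loci) >= len(self.distinct) >= len(self.unique)


def build_host_tagset(genome: Sequence[tuple[str, str]], enzyme: EnzymeSpec) -> HostTagSet:
    """Digest all records of the host genome; unique = copy number exactly 1.

    Copy number is counted on canonical sequences across both strands.
    """
    if not genome:
        raise ValueError("empty host genome")
    loci: list[TagLocus] = []
    for rid, seq in genome:
        loci.extend(extract_tags(seq, enzyme, source_id=rid))
    counts = Counter(t.canonical for t in loci)
    distinct = set(counts)
    unique = {t for t, n in counts.items() if n == 1}
    return HostTagSet(loci, distinct, unique, enzyme)


@dataclass
class MarkerDB:
    """Rank-specific single-copy markers with per-genome/per-taxon bookkeeping."""

    rank: str
    markers: dict[str, str]                      # canonical tag -> taxon label
    genome_markers: dict[str, set[str]]          # genome -> its marker tags
    taxon_markers: dict[str, set[str]]           # taxon -> marker tags
    genome_stats: dict[str, tuple[int, int, int]]  # genome -> (loci, distinct, single-copy)
    taxonomy: TaxonomyTable
    enzyme: EnzymeSpec

    def theoretical_markers(self, taxon: str) -> int:
        return len(self.taxon_markers.get(taxon, ()))


def build_marker_db(
    genomes: Mapping[str, Sequence[tuple[str, str]]],
    taxonomy: TaxonomyTable,
    enzyme: EnzymeSpec,
    rank: str = "species",
) -> MarkerDB:
    """Find rank-specific markers.

    A canonical tag is a marker for taxon T iff it is single-copy in every
    genome carrying it and all carrier genomes belong to T at the chosen rank.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    for gid in genomes:
        if gid not in taxonomy:
            raise ValueError(f"genome {gid!r} missing from taxonomy table")

    per_genome_counts: dict[str, Counter] = {}
    genome_stats: dict[str, tuple[int, int, int]] = {}
    for gid in sorted(genomes):
        loci: list[TagLocus] = []
        for rid, seq in genomes[gid]:
            loci.extend(extract_tags(seq, enzyme, source_id=rid))
        counts = Counter(t.canonical for t in loci)
        per_genome_counts[gid] = counts
        single = sum(1 for n in counts.values() if n == 1)
        genome_stats[gid] = (len(loci), len(counts), single)

    carriers: dict[str, list[str]] = defaultdict(list)
    for gid, counts in per_genome_counts.items():
        for tag in counts:
            carriers[tag].append(gid)

    markers: dict[str, str] = {}
    genome_markers: dict[str, set[str]] = {g: set() for g in genomes}
    taxon_markers: dict[str, set[str]] = defaultdict(set)
    for tag, gids in carriers.items():
        if any(per_genome_counts[g][tag] != 1 for g in gids):
            continue
        taxa = {taxonomy.taxon(g, rank) for g in gids}
        if len(taxa) != 1:
            continue
        taxon = taxa.pop()
        markers[tag] = taxon
        taxon_markers[taxon].add(tag)
        for g in gids:
            genome_markers[g].add(tag)

    return MarkerDB(rank, markers, genome_markers, dict(taxon_markers),
                    genome_stats, taxonomy, enzyme)


@dataclass
class RemovalReport:
    """Impact of the host-vs-microbe cross-redundancy removal."""

    host_tags_removed: int
    host_fraction: float               # over distinct (non-redundant) host tags
    genomes_removed: int
    genome_fraction: float
    rank_affected: dict[str, tuple[int, float]]  # rank -> (taxa losing >=1 marker, fraction)
    rank_removed: dict[str, tuple[int, float]]   # rank -> (taxa losing all markers, fraction)

    def __post_init__(self) -> None:
        for rk in self.rank_affected:
            assert self.rank_removed[rk][0] <= self.rank_affected[rk][0]


@dataclass
class HoloDB:
    """Merged database: host-unique tags + microbial markers, disjoint."""

    host_tags: set[str]
    host_loci: dict[str, list[str]]    # canonical -> "source:start-end(strand)" labels
    markers: dict[str, str]            # canonical -> species (rank) label
    taxon_markers: dict[str, set[str]]
    lineages: dict[str, tuple[str, ...]]   # taxon label -> full lineage
    rank: str
    enzyme: EnzymeSpec
    report: RemovalReport
    genome_stats: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert not (self.host_tags & set(self.markers)), "host/microbe overlap"

    @property
    def tag_length(self) -> int:
        return self.enzyme.tag_length

    def theoretical_markers(self, taxon: str) -> int:
        return len(self.taxon_markers.get(taxon, ()))


def merge_holodb(host: HostTagSet, microbial: MarkerDB) -> HoloDB:
    """Merge the two sides, deleting shared canonical tags from both.

    The host comparison set is the *unique* tag set; the removed-tag fraction
    is reported against the distinct (non-redundant) set.
    """
    if host.enzyme != microbial.enzyme:
        raise ValueError(
            f"enzyme mismatch: host digested with {host.enzyme.name}, "
            f"microbes with {microbial.enzyme.name}"
        )
    overlap = host.unique & set(microbial.markers)

    host_tags = host.unique - overlap
    markers = {t: s for t, s in microbial.markers.items() if t not in overlap}
    taxon_markers = {
        tx: tags - overlap for tx, tags in microbial.taxon_markers.items()
    }

    genomes_removed = sum(
        1 for g, tags in microbial.genome_markers.items()
        if tags and not (tags - overlap)
    )
    n_genomes = len(microbial.genome_markers)

    taxonomy = microbial.taxonomy
    lineages: dict[str, tuple[str, ...]] = {}
    rank_idx = RANKS.index(microbial.rank)
    for gid in taxonomy.genomes():
        lineage = taxonomy.lineage(gid)
        lineages.setdefault(lineage[rank_idx], lineage)

    rank_affected: dict[str, tuple[int, float]] = {}
    rank_removed: dict[str, tuple[int, float]] = {}
    for rk in RANKS:
        idx = RANKS.index(rk)
        pre: dict[str, int] = defaultdict(int)
        lost: dict[str, int] = defaultdict(int)
        for tag, taxon in microbial.markers.items():
            label = lineages[taxon][idx]
            pre[label] += 1
            if tag in overlap:
                lost[label] += 1
        n_taxa = len(pre)
        affected = sum(1 for t in lost if lost[t] > 0)
        removed = sum(1 for t in lost if lost[t] == pre[t])
        rank_affected[rk] = (affected, affected / n_taxa if n_taxa else 0.0)
        rank_removed[rk] = (removed, removed / n_taxa if n_taxa else 0.0)

    report = RemovalReport(
        host_tags_removed=len(overlap),
        host_fraction=len(overlap) / len(host.distinct) if host.distinct else 0.0,
        genomes_removed=genomes_removed,
        genome_fraction=genomes_removed / n_genomes if n_genomes else 0.0,
        rank_affected=rank_affected,
        rank_removed=rank_removed,
    )

    host_loci: dict[str, list[str]] = defaultdict(list)
    for locus in host.all_loci:
        if locus.canonical in host_tags:
            host_loci[locus.canonical].append(
                f"{locus.source_id}:{locus.start}-{locus.end}({locus.strand})"
            )

    return HoloDB(host_tags, dict(host_loci), markers, taxon_markers, lineages,
                  microbial.rank, host.enzyme, report, microbial.genome_stats)


def db_summary(db: HoloDB) -> dict:
    """Per-rank marker/taxon counts plus per-genome digestion statistics."""
    rank_rows = []
    for rk in RANKS:
        idx = RANKS.index(rk)
        per_label: dict[str, int] = defaultdict(int)
        for taxon, tags in db.taxon_markers.items():
            if not tags:
                continue
            label = db.lineages[taxon][idx]
            per_label[label] += len(tags)
        rank_rows.append({
            "rank": rk,
            "taxa_with_markers": len(per_label),
            "markers": sum(per_label.values()),
        })
    total_loci = sum(s[0] for s in db.genome_stats.values())
    total_single = sum(s[2] for s in db.genome_stats.values())
    n_genomes = len(db.genome_stats)
    summary = {
        "rank_table": rank_rows,
        "n_genomes": n_genomes,
        "mean_tags_per_genome": total_loci / n_genomes if n_genomes else 0.0,
        "single_copy_fraction": total_single / total_loci if total_loci else 0.0,
        "host_tags": len(db.host_tags),
        "species_markers": len(db.markers),
    }
    for row in rank_rows:
        assert 0 <= summary["single_copy_fraction"] <= 1
    return summary


# ---------------------------------------------------------------- serialization

def save_holodb(db: HoloDB, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for tag in sorted(db.host_tags):
        rows.append((tag, "host", "host", ";".join(db.host_loci.get(tag, []))))
    for tag in sorted(db.markers):
        taxon = db.markers[tag]
        rows.append((tag, "microbe", taxon, ";".join(db.lineages[taxon])))
    htio.write_tsv(os.path.join(outdir, "holodb.tsv"),
                   ["canonical_tag", "kind", "label", "detail"], rows)

    rep = db.report
    meta = {
        "enzyme": db.enzyme.to_dict(),
        "rank": db.rank,
        "host_tags": len(db.host_tags),
        "markers": len(db.markers),
        "removal_report": {
            "host_tags_removed": rep.host_tags_removed,
            "host_fraction": rep.host_fraction,
            "genomes_removed": rep.genomes_removed,
            "genome_fraction": rep.genome_fraction,
            "rank_affected": {k: list(v) for k, v in rep.rank_affected.items()},
            "rank_removed": {k: list(v) for k, v in rep.rank_removed.items()},
        },
        "genome_stats": {g: list(v) for g, v in db.genome_stats.items()},
    }
    with open(os.path.join(outdir, "holodb.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)

    htio.write_tsv(
        os.path.join(outdir, "removal_report.tsv"),
        ["rank", "taxa_affected", "fraction_affected", "taxa_removed", "fraction_removed"],
        ((rk, rep.rank_affected[rk][0], f"{rep.rank_affected[rk][1]:.6f}",
          rep.rank_removed[rk][0], f"{rep.rank_removed[rk][1]:.6f}") for rk in RANKS),
    )
    summary = db_summary(db)
    htio.write_tsv(
        os.path.join(outdir, "rank_summary.tsv"),
        ["rank", "taxa_with_markers", "markers"],
        ((r["rank"], r["taxa_with_markers"], r["markers"]) for r in summary["rank_table"]),
    )


def load_holodb(dbdir) -> HoloDB:
    meta_path = os.path.join(dbdir, "holodb.json")
    if not os.path.exists(meta_path):
        raise FileNotFoundError(
            f"no hologenome database at {dbdir!r}; build one with "
            f"'holotag build-db --host ... --microbes ... --taxonomy ...'"
        )
    with open(meta_path) as fh:
        meta = json.load(fh)
    enzyme = EnzymeSpec.from_dict(meta["enzyme"])
    _, rows = htio.read_tsv(os.path.join(dbdir, "holodb.tsv"))
    host_tags: set[str] = set()
    host_loci: dict[str, list[str]] = {}
    markers: dict[str, str] = {}
    taxon_markers: dict[str, set[str]] = defaultdict(set)
    lineages: dict[str, tuple[str, ...]] = {}
    for row in rows:
        tag, kind, label = row[0], row[1], row[2]
        detail = row[3] if len(row) > 3 else ""
        if kind == "host":
            host_tags.add(tag)
            host_loci[tag] = detail.split(";") if detail else []
        else:
            markers[tag] = label
            taxon_markers[label].add(tag)
            lineages.setdefault(label, tuple(detail.split(";")))
    rr = meta["removal_report"]
    report = RemovalReport(
        rr["host_tags_removed"], rr["host_fraction"],
        rr["genomes_removed"], rr["genome_fraction"],
        {k: tuple(v) for k, v in rr["rank_affected"].items()},
        {k: tuple(v) for k, v in rr["rank_removed"].items()},
    )
    return HoloDB(host_tags, host_loci, markers, dict(taxon_markers), lineages,
                  meta["rank"], enzyme, report,
                  {g: tuple(v) for g, v in meta.get("genome_stats", {}).items()})
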