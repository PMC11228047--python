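"""Synthetic holobiont experiments with full truth bookkeeping.

Generates a diploid host genome with planted restriction sites and SNPs, a
microbial community of known composition, optional deliberate tag sharing
(across species and with the host), and error-bearing FASTQ reads whose ids
carry their source labels.  Every downstream stage has an exact recovery
oracle against the returned TruthSet.

All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import io as htio
from .database import RANKS, TaxonomyTable
from .enzyme import (
    BSAXI,
    IUPAC,
    EnzymeSpec,
    TagLocus,
    canonicalize,
    extract_tags,
    find_recognition_sites,
    revcomp,
)

_MAX_RUN = 8  # keep simulated sequences clear of the >10 bp homopolymer filter


@dataclass
class SimConfig:
    seed: int = 0
    enzyme: EnzymeSpec = field(default_factory=lambda: BSAXI)
    host_length: int = 20000
    host_sites: int = 40
    host_snps: int = 20
    het_fraction: float = 0.5
    n_species: int = 10
    genomes_per_species: int = 1
    genome_length: int = 4000
    sites_per_genome: int = 10
    cross_species_shared: int = 0   # tags copied between genomes of two species
    host_shared: int = 0            # host tags copied into microbe genomes
    abundances: Optional[list[float]] = None  # None -> Dirichlet(1,...,1)
    microbial_fraction: float = 0.5
    reads: int = 20000
    error_rate: float = 0.0
    read_length: Optional[int] = None  # None -> tag length; larger pads the read
    quality: int = 35

    def __post_init__(self) -> None:
        if self.abundances is not None:
            if len(self.abundances) != self.n_species:
                raise ValueError("abundance vector length != n_species")
            if abs(sum(self.abundances) - 1.0) > 1e-9 or min(self.abundances) < 0:
                raise ValueError("abundances must be non-negative and sum to 1")
        for frac in (self.het_fraction, self.microbial_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error rate must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "enzyme" in raw and isinstance(raw["enzyme"], dict):
            raw["enzyme"] = EnzymeSpec.from_dict(raw["enzyme"])
        elif isinstance(raw.get("enzyme"), str):
            from .enzyme import ENZYMES

            raw["enzyme"] = ENZYMES[raw["enzyme"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enzyme"] = self.enzyme.to_dict()
        return d


@dataclass
class TruthSet:
    enzyme: EnzymeSpec
    host_reference: str
    haplotypes: tuple[str, str]
    host_sites: list[int]                      # forward recognition starts
    host_tags: list[TagLocus]                  # reference tag loci, site order
    snps: list[dict]                           # site_index/offset/ref/alt/het/...
    host_genotypes: dict                       # (canonical, canonical offset) -> alleles
    genomes: dict[str, str]                    # genome id -> sequence
    taxonomy: TaxonomyTable
    species_markers: dict[str, list[str]]      # species -> canonical markers
    marker_seqs: dict[str, str]                # canonical -> planted forward sequence
    shared_cross: set[str]
    shared_with_host: set[str]
    abundances: dict[str, float]

    def expected_genotype(self, canonical: str, offset: int) -> tuple[str, str]:
        """Planted diploid genotype at a (canonical tag, offset) locus."""
        key = (canonical, offset)
        if key in self.host_genotypes:
            return self.host_genotypes[key]
        return (canonical[offset], canonical[offset])


# ----------------------------------------------------------------- primitives

def _random_dna(n: int, rng: np.random.Generator) -> list[str]:
    seq = list(rng.choice(list("ACGT"), size=n))
    _break_runs(seq, rng, protected=set())
    return seq

def _break_runs(seq: list[str], rng: np.random.Generator, protected: set[int]) -> None:
    run_start = 0
    i = 1
    while i <= len(seq):
        if i == len(seq) or seq[i] != seq[run_start]:
            if i - run_start > _MAX_RUN:
                for pos in range(run_start + _MAX_RUN, i, _MAX_RUN):
                    if pos in protected:
                        continue
                    choices = [b for b in "ACGT" if b != seq[pos]]
                    seq[pos] = choices[rng.integers(len(choices))]
            run_start = i
        i += 1


def _concretize(pattern: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in pattern)


def _scrub(
    seq: list[str],
    enzyme: EnzymeSpec,
    rng: np.random.Generator,
    keep: set[tuple[int, str]],
    protected: set[int],
) -> None:
    """Mutate until the recognition-site set equals ``keep`` exactly."""
    for _ in range(500):
        sites = set(find_recognition_sites("".join(seq), enzyme))
        extra = sites - keep
        if not extra and keep <= sites:
            _break_runs(seq, rng, protected)
            if set(find_recognition_sites("".join(seq), enzyme)) == keep:
                return
            continue
        if keep - sites:
            raise RuntimeError("scrub destroyed a planted site")  # pragma: no cover
        for s, _strand in extra:
            span = [p for p in range(s, s + len(enzyme.recognition)) if p not in protected]
            if not span:  # pragma: no cover - overlapping planted spans
                raise RuntimeError("unexpected site entirely inside planted span")
            pos = span[rng.integers(len(span))]
            choices = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
    raise RuntimeError("could not scrub sequence to the planted site set")


def _plant_genome(
    length: int, n_sites: int, enzyme: EnzymeSpec, rng: np.random.Generator
) -> tuple[list[str], list[int]]:
    """Random background with exactly ``n_sites`` forward recognition sites."""
    m = len(enzyme.recognition)
    tag_len = enzyme.tag_length
    margin = max(enzyme.flank5, enzyme.flank3) + 2
    usable = length - 2 * margin - m
    if n_sites <= 0:
        seq = _random_dna(length, rng)
        _scrub(seq, enzyme, rng, set(), set())
        return seq, []
    spacing = usable // n_sites
    if spacing < tag_len + 4:
        raise ValueError(
            f"infeasible config: {n_sites} sites do not fit in length {length}"
        )
    seq = _random_dna(length, rng)
    starts = []
    for i in range(n_sites):
        jitter = int(rng.integers(0, max(spacing - tag_len - 2, 1)))
        starts.append(margin + i * spacing + jitter)
    protected: set[int] = set()
    for s in starts:
        concrete = _concretize(enzyme.recognition, rng)
        seq[s : s + m] = list(concrete)
        protected.update(range(s, s + m))
    _scrub(seq, enzyme, rng, {(s, "+") for s in starts}, protected)
    return seq, starts


def _tag_window(site: int, enzyme: EnzymeSpec) -> tuple[int, int]:
    return site - enzyme.flank5, site + len(enzyme.recognition) + enzyme.flank3


# -------------------------------------------------------------------- genomes

def simulate_genomes(cfg: SimConfig) -> TruthSet:
    rng = np.random.default_rng(cfg.seed)
    enzyme = cfg.enzyme

    for attempt in range(10):
        truth = _try_simulate_genomes(cfg, enzyme, rng)
        if truth is not None:
            return truth
    raise RuntimeError("could not generate a collision-free holobiome")


def _try_simulate_genomes(
    cfg: SimConfig, enzyme: EnzymeSpec, rng: np.random.Generator
) -> Optional[TruthSet]:
    # ---- host with diploid SNPs
    host_seq, host_sites = _plant_genome(cfg.host_length, cfg.host_sites, enzyme, rng)
    host_ref = "".join(host_seq)
    ref_tags = extract_tags(host_ref, enzyme, source_id="host")
    if len(ref_tags) != cfg.host_sites:
        return None
    canon = [t.canonical for t in ref_tags]
    if len(set(canon)) != len(canon):
        return None

    if cfg.host_snps > cfg.host_sites:
        raise ValueError("infeasible config: more SNPs than host tags")
    m = len(enzyme.recognition)
    snp_sites = sorted(rng.choice(cfg.host_sites, size=cfg.host_snps, replace=False))
    hap1, hap2 = list(host_seq), list(host_seq)
    snps: list[dict] = []
    genotypes: dict[tuple[str, int], tuple[str, str]] = {}
    for idx in snp_sites:
        site = host_sites[idx]
        start, end = _tag_window(site, enzyme)
        # offsets free to vary: flanks plus unconstrained recognition positions
        offsets = [
            o for o in range(end - start)
            if not (enzyme.flank5 <= o < enzyme.flank5 + m
                    and enzyme.recognition[o - enzyme.flank5] != "N")
        ]
        off = int(offsets[rng.integers(len(offsets))])
        pos = start + off
        ref_base = host_ref[pos]
        alt = [b for b in "ACGT" if b != ref_base][rng.integers(3)]
        het = bool(rng.random() < cfg.het_fraction)
        hap2[pos] = alt
        if not het:
            hap1[pos] = alt
        tag = ref_tags[idx]
        if tag.canonical == tag.sequence:
            off_c, ref_c, alt_c = off, ref_base, alt
        else:
            off_c = enzyme.tag_length - 1 - off
            comp = str.maketrans("ACGT", "TGCA")
            ref_c, alt_c = ref_base.translate(comp), alt.translate(comp)
        alleles = tuple(sorted((ref_c, alt_c))) if het else (alt_c, alt_c)
        genotypes[(tag.canonical, off_c)] = alleles
        snps.append({
            "site_index": int(idx), "offset": off, "ref": ref_base, "alt": alt,
            "het": het, "canonical": tag.canonical, "canonical_offset": off_c,
            "alleles": alleles,
        })
    h1, h2 = "".join(hap1), "".join(hap2)
    for hap in (h1, h2):
        if len(extract_tags(hap, enzyme)) != cfg.host_sites:
            return None

    # ---- microbial genomes + taxonomy
    genomes: dict[str, list[str]] = {}
    genome_sites: dict[str, list[int]] = {}
    genome_species: dict[str, str] = {}
    lineages: dict[str, list[str]] = {}
    species_labels = [f"sp{i:02d}" for i in range(cfg.n_species)]
    for i, sp in enumerate(species_labels):
        lineage = [
            "Bacteria", f"phylum{i // 32:02d}", f"class{i // 16:02d}",
            f"order{i // 8:02d}", f"family{i // 4:02d}", f"genus{i // 2:02d}", sp,
        ]
        for k in range(cfg.genomes_per_species):
            gid = f"g{i:02d}_{k}"
            seq, sites = _plant_genome(cfg.genome_length, cfg.sites_per_genome, enzyme, rng)
            genomes[gid] = seq
            genome_sites[gid] = sites
            genome_species[gid] = sp
            lineages[gid] = lineage

    # ---- deliberate sharing: cross-species and with the host
    shared_cross: set[str] = set()
    shared_with_host: set[str] = set()
    gids = sorted(genomes)
    if cfg.cross_species_shared and cfg.n_species < 2:
        raise ValueError("cross-species sharing needs at least 2 species")
    for _ in range(cfg.cross_species_shared):
        ga, gb = (gids[i] for i in rng.choice(len(gids), size=2, replace=False))
        while genome_species[ga] == genome_species[gb]:
            ga, gb = (gids[i] for i in rng.choice(len(gids), size=2, replace=False))
        donor_site = genome_sites[ga][rng.integers(len(genome_sites[ga]))]
        ds, de = _tag_window(donor_site, enzyme)
        window = "".join(genomes[ga][ds:de])
        target_site = genome_sites[gb][rng.integers(len(genome_sites[gb]))]
        ts, te = _tag_window(target_site, enzyme)
        genomes[gb][ts:te] = list(window)
        shared_cross.add(canonicalize(window))
    non_snp = [i for i in range(cfg.host_sites) if i not in set(snp_sites)]
    if cfg.host_shared > len(non_snp):
        raise ValueError("infeasible config: not enough SNP-free host tags to share")
    for j in range(cfg.host_shared):
        tag = ref_tags[non_snp[j]]
        gb = gids[int(rng.integers(len(gids)))]
        target_site = genome_sites[gb][rng.integers(len(genome_sites[gb]))]
        ts, te = _tag_window(target_site, enzyme)
        genomes[gb][ts:te] = list(tag.sequence)
        shared_with_host.add(tag.canonical)

    # re-scrub mutated genomes and freeze sequences
    genome_seqs: dict[str, str] = {}
    for gid in gids:
        seq = genomes[gid]
        m_len = len(enzyme.recognition)
        protected = {
            p for s in genome_sites[gid] for p in range(s, s + m_len)
        }
        _scrub(seq, enzyme, rng, {(s, "+") for s in genome_sites[gid]}, protected)
        genome_seqs[gid] = "".join(seq)

    # ---- truth marker lists
    carrier_count: dict[str, set[str]] = {}
    planted: dict[str, list[tuple[str, str]]] = {gid: [] for gid in gids}  # (canonical, fwd seq)
    for gid in gids:
        tags = extract_tags(genome_seqs[gid], enzyme, source_id=gid)
        if len(tags) != cfg.sites_per_genome:
            return None
        for t in tags:
            planted[gid].append((t.canonical, t.sequence))
            carrier_count.setdefault(t.canonical, set()).add(genome_species[gid])

    species_markers: dict[str, list[str]] = {sp: [] for sp in species_labels}
    marker_seqs: dict[str, str] = {}
    host_unique = set(canon)
    for gid in gids:
        sp = genome_species[gid]
        for c, fwd in planted[gid]:
            if len(carrier_count[c]) > 1 or c in shared_with_host or c in host_unique:
                continue
            if c in marker_seqs:  # same-species duplicate carrier: still single list entry
                continue
            species_markers[sp].append(c)
            marker_seqs[c] = fwd
    # accidental collisions between independently generated tags: retry
    all_planted = [c for gid in gids for c, _ in planted[gid]]
    deliberate = shared_cross | shared_with_host
    from collections import Counter

    dup = {c for c, n in Counter(all_planted).items() if n > 1}
    if dup - deliberate:
        return None
    if set(canon) & set(all_planted) - shared_with_host:
        return None

    if cfg.abundances is not None:
        ab = np.array(cfg.abundances, dtype=float)
    else:
        ab = rng.dirichlet(np.ones(cfg.n_species))
    abundances = {sp: float(a) for sp, a in zip(species_labels, ab)}

    taxonomy = TaxonomyTable(lineages)
    return TruthSet(
        enzyme=enzyme,
        host_reference=host_ref,
        haplotypes=(h1, h2),
        host_sites=host_sites,
        host_tags=ref_tags,
        snps=snps,
        host_genotypes=genotypes,
        genomes=genome_seqs,
        taxonomy=taxonomy,
        species_markers=species_markers,
        marker_seqs=marker_seqs,
        shared_cross=shared_cross,
        shared_with_host=shared_with_host,
        abundances=abundances,
    )


# ---------------------------------------------------------------------- reads

def simulate_reads(
    cfg: SimConfig,
    truth: TruthSet,
    sample_id: str,
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """One library of (read id, bases, quality string) triples.

    Host reads sample a haplotype tag uniformly; microbial reads sample a
    species proportional to abundance x marker count, then a marker uniformly.
    Substitution errors are applied independently per base.  Read ids carry
    the source label.
    """
    enzyme = truth.enzyme
    tag_len = enzyme.tag_length
    read_len = cfg.read_length or tag_len
    if read_len < tag_len:
        raise ValueError("read_length shorter than tag length")
    qual = chr(33 + cfg.quality) * read_len

    species = sorted(truth.species_markers)
    weights = np.array(
        [truth.abundances[sp] * len(truth.species_markers[sp]) for sp in species]
    )
    if weights.sum() <= 0:
        raise ValueError("no species markers to sample reads from")
    weights = weights / weights.sum()

    hap_windows: list[list[str]] = []
    for hap in truth.haplotypes:
        windows = []
        for site in truth.host_sites:
            s, e = _tag_window(site, enzyme)
            windows.append(hap[s:e])
        hap_windows.append(windows)

    out: list[tuple[str, str, str]] = []
    for i in range(cfg.reads):
        if rng.random() < cfg.microbial_fraction:
            sp = species[int(rng.choice(len(species), p=weights))]
            markers = truth.species_markers[sp]
            canonical = markers[int(rng.integers(len(markers)))]
            seq = truth.marker_seqs[canonical]
            rid = f"{sample_id}:{i}|microbe|{sp}"
        else:
            hap = int(rng.integers(2))
            site_idx = int(rng.integers(len(truth.host_sites)))
            seq = hap_windows[hap][site_idx]
            rid = f"{sample_id}:{i}|host|{site_idx}|hap{hap}"
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if read_len > tag_len:
            seq = _pad_read(seq, read_len, enzyme, rng)
        seq = _apply_errors(seq, cfg.error_rate, rng)
        out.append((rid, seq, qual))
    return out


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    bases = list(seq)
    hits = np.nonzero(rng.random(len(bases)) < rate)[0]
    for p in hits:
        choices = [b for b in "ACGT" if b != bases[p]]
        bases[p] = choices[rng.integers(3)]
    return "".join(bases)


def _pad_read(
    tag_seq: str, read_len: int, enzyme: EnzymeSpec, rng: np.random.Generator
) -> str:
    """Embed the tag in a longer read whose leftmost tag window is the tag."""
    from .io import ReadRecord
    from .qc import extract_sequenced_tag

    want = canonicalize(tag_seq)
    pad_total = read_len - len(tag_seq)
    for _ in range(50):
        left = int(rng.integers(pad_total + 1))
        lpad = "".join(rng.choice(list("ACGT"), size=left))
        rpad = "".join(rng.choice(list("ACGT"), size=pad_total - left))
        read = lpad + tag_seq + rpad
        probe = ReadRecord("probe", read, [40] * len(read))
        if extract_sequenced_tag(probe, enzyme) == want:
            return read
    raise RuntimeError("could not pad read without spurious sites")  # pragma: no cover


# --------------------------------------------------------------------- output

def write_experiment(cfg: SimConfig, truth: TruthSet, outdir,
                     samples: dict[str, list[tuple[str, str, str]]]) -> None:
    """Write FASTA genomes, taxonomy, truth files, and per-sample FASTQ."""
    os.makedirs(outdir, exist_ok=True)
    htio.write_fasta(os.path.join(outdir, "host.fa"), [("host", truth.host_reference)])
    microdir = os.path.join(outdir, "microbes")
    os.makedirs(microdir, exist_ok=True)
    for gid in sorted(truth.genomes):
        htio.write_fasta(os.path.join(microdir, f"{gid}.fa"), [(gid, truth.genomes[gid])])
    truth.taxonomy.to_tsv(os.path.join(outdir, "taxonomy.tsv"))
    for name, reads in samples.items():
        htio.write_fastq(os.path.join(outdir, f"{name}.fq"), reads)

    truth_doc = {
        "config": cfg.to_dict(),
        "abundances": truth.abundances,
        "host_sites": truth.host_sites,
        "snps": truth.snps,
        "species_markers": {k: sorted(v) for k, v in truth.species_markers.items()},
        "shared_cross": sorted(truth.shared_cross),
        "shared_with_host": sorted(truth.shared_with_host),
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
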