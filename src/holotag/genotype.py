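"""Diploid genotyping of host-assigned tags.

Reads are piled up against the reference host tags (mismatch-tolerant,
ambiguous reads discarded), then each tag offset is called with a binomial
maximum-likelihood codominant model.  Loci below the reliable depth
(default 5, i.e. "coverage greater than 4x") are reported unknown.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .classify import hamming
from .enzyme import revcomp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_ERROR_RATE = 0.01
DEFAULT_RELIABLE_DEPTH = 5
DEFAULT_PILEUP_MISMATCH = 3


@dataclass
class TagPileup:
    """Per-offset base counts for one reference tag."""

    tag: str                 # reference canonical sequence (also the locus id prefix)
    counts: np.ndarray       # shape (tag_length, 4), A/C/G/T
    depth: int               # reads stacked on this tag

    def validate(self) -> None:
        sums = self.counts.sum(axis=1)
        assert (sums == self.depth).all(), "offset counts must sum to depth"


def pileup_host_tags(
    reads: Iterable[str],
    reference_tags: Sequence[str],
    max_mismatch: int = DEFAULT_PILEUP_MISMATCH,
) -> dict[str, TagPileup]:
    """Stack read sequences onto their best-matching reference tag.

    Each read (tag-length, ACGT) is compared to every reference tag in both
    orientations; it is added to the unique best match within
    ``max_mismatch``, in the reference orientation.  Reads equidistant from
    two or more reference tags are discarded as ambiguous.
    """
    refs = list(reference_tags)
    pileups: dict[str, TagPileup] = {}
    length = len(refs[0]) if refs else 0
    for read in reads:
        best_d = max_mismatch + 1
        best: list[tuple[str, str]] = []  # (ref, oriented read)
        rc = revcomp(read)
        for ref in refs:
            for oriented in (read, rc):
                d = hamming(oriented, ref, best_d)
                if d < best_d:
                    best_d, best = d, [(ref, oriented)]
                elif d == best_d and d <= max_mismatch:
                    best.append((ref, oriented))
        if best_d > max_mismatch:
            continue
        if len({ref for ref, _ in best}) != 1:
            continue  # ambiguous between reference tags
        ref, oriented = best[0]
        if ref not in pileups:
            pileups[ref] = TagPileup(ref, np.zeros((length, 4), dtype=np.int64), 0)
        p = pileups[ref]
        for i, b in enumerate(oriented):
            p.counts[i, BASE_INDEX[b]] += 1
        p.depth += 1
    for p in pileups.values():
        p.validate()
    return pileups


@dataclass(frozen=True)
class GenotypeCall:
    """Call at one (tag, offset) locus; ``alleles`` is None for unknown."""

    locus: str                        # "<tag>:<offset>"
    alleles: Optional[tuple[str, str]]  # sorted pair, e.g. ("A", "A") / ("A", "T")
    depth: int
    likelihood: float = 0.0

    @property
    def known(self) -> bool:
        return self.alleles is not None

    @property
    def homozygous(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]


def call_genotype(
    pileup: TagPileup,
    offset: int,
    error_rate: float = DEFAULT_ERROR_RATE,
    reliable_depth: int = DEFAULT_RELIABLE_DEPTH,
) -> GenotypeCall:
    """ML diploid call at one offset under a binomial error model.

    With counts (n1, n2) of the two most frequent bases the three candidate
    likelihoods are hom-1 (minority reads are errors at ``error_rate``),
    hom-2 symmetric, and het (each allele sampled with probability 0.5).
    Depth below ``reliable_depth`` or a non-negligible third allele gives
    unknown.
    """
    locus = f"{pileup.tag}:{offset}"
    col = pileup.counts[offset]
    depth = int(col.sum())
    if depth == 0:
        raise ValueError(f"no coverage at {locus}")
    if depth < reliable_depth:
        return GenotypeCall(locus, None, depth)
    order = np.argsort(col)[::-1]
    n1, n2 = int(col[order[0]]), int(col[order[1]])
    n_rest = depth - n1 - n2
    if n_rest > error_rate * depth * 3:  # third allele too strong: unreliable
        return GenotypeCall(locus, None, depth)
    b1, b2 = BASES[order[0]], BASES[order[1]]
    n = n1 + n2
    l_hom1 = float(binom.pmf(n2, n, error_rate))
    l_hom2 = float(binom.pmf(n1, n, error_rate))
    l_het = float(binom.pmf(n1, n, 0.5))
    best = max((l_hom1, 0), (l_hom2, 1), (l_het, 2))
    if best[1] == 0:
        alleles = (b1, b1)
    elif best[1] == 1:
        alleles = (b2, b2)
    else:
        alleles = tuple(sorted((b1, b2)))
    return GenotypeCall(locus, alleles, depth, best[0])


def genotype_sample(
    pileups: Mapping[str, TagPileup],
    error_rate: float = DEFAULT_ERROR_RATE,
    reliable_depth: int = DEFAULT_RELIABLE_DEPTH,
) -> dict[str, GenotypeCall]:
    """Call every covered offset of every pileup; keys are locus ids."""
    calls: dict[str, GenotypeCall] = {}
    for tag in sorted(pileups):
        p = pileups[tag]
        for offset in range(p.counts.shape[0]):
            if p.counts[offset].sum() == 0:
                continue
            call = call_genotype(p, offset, error_rate, reliable_depth)
            calls[call.locus] = call
    return calls


class GenotypeMatrix:
    """samples x loci grid of GenotypeCall; missing loci are unknown."""

    def __init__(self) -> None:
        self.columns: dict[str, dict[str, GenotypeCall]] = {}

    def add_sample(self, name: str, calls: Mapping[str, GenotypeCall]) -> None:
        if name in self.columns:
            raise ValueError(f"duplicate sample {name!r}")
        self.columns[name] = dict(calls)

    @property
    def samples(self) -> list[str]:
        return list(self.columns)

    @property
    def loci(self) -> list[str]:
        universe: set[str] = set()
        for col in self.columns.values():
            universe.update(col)
        return sorted(universe)

    def call(self, sample: str, locus: str) -> Optional[GenotypeCall]:
        return self.columns[sample].get(locus)


@dataclass
class AgreementRow:
    genotyped: int
    same: int

    @property
    def different(self) -> int:
        return self.genotyped - self.same

    @property
    def agreement(self) -> Optional[float]:
        if self.genotyped == 0:
            return None
        return agreement_percent(self.genotyped, self.same)


def agreement_percent(genotyped: int, same: int) -> float:
    """Agreement percentage, rounded to 2 decimals."""
    if genotyped <= 0:
        raise ValueError("genotyped count must be positive")
    if same > genotyped:
        raise ValueError("same-genotype count exceeds genotyped count")
    return round(100.0 * same / genotyped, 2)


@dataclass
class AgreementReport:
    """Replicate agreement stratified by replicate 1's call class."""

    homozygote: AgreementRow
    heterozygote: AgreementRow
    all: AgreementRow

    def validate(self) -> None:
        assert self.all.genotyped == self.homozygote.genotyped + self.heterozygote.genotyped
        assert self.all.same == self.homozygote.same + self.heterozygote.same
        for row in (self.homozygote, self.heterozygote, self.all):
            assert row.same + row.different == row.genotyped


def compare_replicates(
    g1: Mapping[str, GenotypeCall], g2: Mapping[str, GenotypeCall]
) -> AgreementReport:
    """Agreement over loci called (non-unknown) in both replicates.

    Hom/het stratification follows the class of replicate 1's call.
    """
    hom = AgreementRow(0, 0)
    het = AgreementRow(0, 0)
    for locus, c1 in g1.items():
        if not c1.known:
            continue
        c2 = g2.get(locus)
        if c2 is None or not c2.known:
            continue
        row = hom if c1.homozygous else het
        row.genotyped += 1
        if c1.alleles == c2.alleles:
            row.same += 1
    report = AgreementReport(
        hom, het, AgreementRow(hom.genotyped + het.genotyped, hom.same + het.same)
    )
    report.validate()
    return report


def genotype_distance(gm: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Allele-sharing distance matrix over samples.

    Per locus called in both samples the contribution is
    1 - (shared alleles, counting multiplicity) / 2, averaged over comparable
    loci.  Pairs with no comparable loci are NaN.
    """
    samples = gm.samples
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    n = len(samples)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            col_i, col_j = gm.columns[samples[i]], gm.columns[samples[j]]
            total, count = 0.0, 0
            for locus, ci in col_i.items():
                if not ci.known:
                    continue
                cj = col_j.get(locus)
                if cj is None or not cj.known:
                    continue
                shared = _shared_alleles(ci.alleles, cj.alleles)
                total += 1.0 - shared / 2.0
                count += 1
            dm[i, j] = dm[j, i] = total / count if count else np.nan
    return samples, dm


def _shared_alleles(a: tuple[str, str], b: tuple[str, str]) -> int:
    remaining = list(b)
    shared = 0
    for allele in a:
        if allele in remaining:
            remaining.remove(allele)
            shared += 1
    return shared


def write_calls(calls: Mapping[str, GenotypeCall], path) -> None:
    """Genotype TSV: locus, diploid call ("AT", "NN" for unknown), depth."""
    from . import io as htio

    rows = []
    for locus in sorted(calls):
        c = calls[locus]
        geno = "".join(c.alleles) if c.known else "NN"
        rows.append((locus, geno, c.depth))
    htio.write_tsv(path, ["locus", "genotype", "depth"], rows)


def read_calls(path) -> dict[str, GenotypeCall]:
    from . import io as htio

    _, rows = htio.read_tsv(path)
    out: dict[str, GenotypeCall] = {}
    for locus, geno, depth in rows:
        alleles = None if geno == "NN" else (geno[0], geno[1])
        out[locus] = GenotypeCall(locus, alleles, int(depth))
    return out


def write_phylip(path, labels: Sequence[str], dm: np.ndarray) -> None:
    """PHYLIP square distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for i, label in enumerate(labels):
            row = " ".join(f"{dm[i, j]:.6f}" for j in range(len(labels)))
            fh.write(f"{label:<10s} {row}\n")


def read_phylip(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return labels, np.array(rows)
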