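"""Alpha/beta diversity, classical PCoA, and neighbor-joining trees."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "AlphaDiversity",
    "alpha_diversity",
    "bray_curtis",
    "beta_matrix",
    "pcoa",
    "nj_tree",
]


@dataclass(frozen=True)
class AlphaDiversity:
    shannon: float   # natural log
    simpson: float   # 1 - sum(p^2)
    richness: int


def alpha_diversity(abundances: Mapping[str, float] | Sequence[float]) -> AlphaDiversity:
    """Shannon (-sum p ln p, natural log; 0*ln0 := 0) and Simpson (1 - sum p^2)."""
    if isinstance(abundances, Mapping):
        p = np.array(list(abundances.values()), dtype=float)
    else:
        p = np.asarray(abundances, dtype=float)
    p = p[p > 0]
    if p.size == 0 or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("abundances must be positive and sum to 1")
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    richness = int(p.size)
    assert -1e-12 <= shannon <= np.log(richness) + 1e-9
    assert -1e-12 <= simpson <= 1 - 1 / richness + 1e-9
    return AlphaDiversity(max(shannon, 0.0), max(simpson, 0.0), richness)


def bray_curtis(
    p1: Mapping[str, float], p2: Mapping[str, float]
) -> float:
    """Bray-Curtis dissimilarity over the union of species."""
    union = set(p1) | set(p2)
    if not union:
        raise ValueError("both profiles empty: Bray-Curtis undefined")
    num = sum(abs(p1.get(s, 0.0) - p2.get(s, 0.0)) for s in union)
    den = sum(p1.get(s, 0.0) + p2.get(s, 0.0) for s in union)
    if den == 0:
        raise ValueError("both profiles all-zero: Bray-Curtis undefined")
    bc = num / den
    assert -1e-12 <= bc <= 1 + 1e-12
    return min(max(bc, 0.0), 1.0)


def beta_matrix(profiles: Mapping[str, Mapping[str, float]]) -> tuple[list[str], np.ndarray]:
    """Pairwise Bray-Curtis matrix over samples (sorted sample order)."""
    names = sorted(profiles)
    n = len(names)
    bm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            bm[i, j] = bm[j, i] = bray_curtis(profiles[names[i]], profiles[names[j]])
    return names, bm


def pcoa(dm: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical metric scaling.

    Double-centers -0.5*D^2, takes the top-k eigenvectors scaled by
    sqrt(eigenvalue).  Negative eigenvalues are dropped from the
    explained-variance denominator.  Returns (coordinates n x k', explained
    fractions), k' <= k (truncated with a warning when fewer positive
    eigenvalues exist).
    """
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    n = dm.shape[0]
    a = -0.5 * dm**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals).max(), 1.0)
    positive = eigvals > scale * 1e-12
    n_pos = int(positive.sum())
    if n_pos == 0:
        return np.zeros((n, k)), np.zeros(k)
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating from k={k}",
            stacklevel=2,
        )
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    total = eigvals[positive].sum()
    explained = eigvals[:k] / total if total > 0 else np.zeros(k)
    return coords, explained


# ------------------------------------------------------------- neighbor joining

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[list[tuple["_Node", float]]] = None):
        self.label = label
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{length:.12g}" for c, length in self.children)
        return f"({inner})"


def nj_tree(dm: np.ndarray, labels: Sequence[str]) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string.

    Ties in the Q criterion resolve to the lexicographically smallest label
    pair.  Negative branch lengths are clamped to 0 with the deficit moved to
    the sibling branch.  Exact on additive distance matrices.
    """
    dm = np.asarray(dm, dtype=float)
    if dm.shape[0] != dm.shape[1] or dm.shape[0] != len(labels):
        raise ValueError("labels must match a square matrix")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[_Node] = [_Node(label=str(l)) for l in labels]
    names: list[str] = [str(l) for l in labels]
    d = dm.copy()

    if n == 2:
        half = d[0, 1] / 2.0
        root = _Node(children=[(nodes[0], half), (nodes[1], half)])
        return root.newick() + ";"

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best: Optional[tuple[float, str, str, int, int]] = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((names[i], names[j])))
                key = (q, pair[0], pair[1])
                if best is None or key < (best[0], best[1], best[2]):
                    best = (q, pair[0], pair[1], i, j)
        _, _, _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to all others
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for kk in active:
            if kk in (i, j):
                continue
            d[new_idx, kk] = d[kk, new_idx] = (d[i, kk] + d[j, kk] - d[i, j]) / 2.0
        nodes.append(new)
        names.append(min(names[i], names[j]))  # deterministic internal name
        active = [a for a in active if a not in (i, j)] + [new_idx]

    i, j, k = active
    # final three-way join at an unrooted center node
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    root = _Node(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return root.newick() + ";"


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)
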