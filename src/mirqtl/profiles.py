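"""Significance profiles across the wavenumber axis and locus clustering.

A locus's profile is its -log10(p) vector over all wavenumber traits,
scaled to sum to one so that loci with very different significance
magnitudes can be compared by shape. Pairs of profiles are compared by
Euclidean distance over the wavenumbers unmasked in both, and loci are
grouped by complete-linkage (largest pairwise dissimilarity) agglomerative
clustering with a deterministic lexicographic tie rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidates import CandidateCall, ld_r2
from .dataio import GenotypeMatrix
from .eqtl import ColocCall


def select_representative(gene: str, candidate_calls: list[CandidateCall],
                          coloc_calls: list[ColocCall],
                          genotypes: GenotypeMatrix | None = None) -> str:
    """Representative tag variant for a gene implicated at one or more loci.

    PIV links take precedence over eQTL links; among several, the link in
    highest LD wins; ties break by smaller tag p, then position.
    """
    scored: list[tuple[int, float, float, int, str]] = []
    for c in candidate_calls:
        if c.gene == gene:
            scored.append((0, -c.r2, c.tag.p, c.tag.pos, c.tag.vid))
    for c in coloc_calls:
        if c.gene == gene:
            scored.append((1, -c.r2, c.tag.p, c.tag.pos, c.tag.vid))
    if not scored:
        raise KeyError(f"gene {gene} has no candidate or co-localization call")
    scored.sort()
    return scored[0][4]


@dataclass
class SignificanceProfile:
    label: str  # "gene:vid"
    vid: str
    raw: np.ndarray  # -log10 p per wavenumber trait
    scaled: np.ndarray  # raw / sum(raw) over unmasked entries
    mask: np.ndarray  # True where the wavenumber trait is excluded


def build_profile(vid: str, neglog10p: np.ndarray,
                  mask: np.ndarray | None = None,
                  label: str | None = None) -> SignificanceProfile:
    """Scale a locus's per-wavenumber -log10(p) vector to sum to one.

    ``mask`` marks wavenumber traits excluded from profiles (e.g. traits
    whose GWAS did not converge); masked entries are zeroed and the scaling
    runs over the remainder.
    """
    raw = np.asarray(neglog10p, dtype=float).copy()
    if mask is None:
        mask = ~np.isfinite(raw)
    else:
        mask = np.asarray(mask, dtype=bool) | ~np.isfinite(raw)
    raw[mask] = 0.0
    if np.any(raw < 0):
        raise ValueError("-log10 p must be non-negative")
    total = raw.sum()
    if total <= 0:
        raise ValueError("no signal to scale: all -log10 p are zero or masked")
    scaled = raw / total
    return SignificanceProfile(
        label=label or vid, vid=vid, raw=raw, scaled=scaled, mask=mask,
    )


def profile_distance_matrix(profiles: list[SignificanceProfile]) -> np.ndarray:
    """Pairwise Euclidean distances over wavenumbers unmasked in both."""
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(profiles[i].mask | profiles[j].mask)
            d = float(
                np.sqrt(np.sum((profiles[i].scaled[ok] - profiles[j].scaled[ok]) ** 2))
            )
            D[i, j] = D[j, i] = d
    return D


@dataclass
class Dendrogram:
    """Complete-linkage merge history over n leaves (n - 1 merges)."""

    labels: list[str]
    merges: list[tuple[int, int, float]]  # (node_a, node_b, height)
    # node ids: 0..n-1 leaves, then n, n+1, ... for merged clusters

    def __post_init__(self) -> None:
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("dendrogram heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (0..k-1) from cutting the tree into k clusters."""
        n = self.n_leaves
        parent = list(range(n + len(self.merges)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for t, (a, b, _) in enumerate(self.merges[: n - k]):
            new = n + t
            parent[find(a)] = new
            parent[find(b)] = new
        roots = {}
        out = np.empty(n, dtype=int)
        for i in range(n):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots)
            out[i] = roots[r]
        return out

    def to_newick(self) -> str:
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for t, (a, b, h) in enumerate(self.merges):
            new = n + t
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[new] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[new] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return node[root] + ";"

    def merge_table(self) -> list[dict]:
        return [
            {"node_a": a, "node_b": b, "height": h} for a, b, h in self.merges
        ]


def complete_linkage_cluster(distance_matrix: np.ndarray,
                             labels: list[str] | None = None) -> Dendrogram:
    """Agglomerative clustering with largest-pairwise-dissimilarity linkage.

    Ties in the next merge break on the lexicographically smallest pair of
    cluster ids, so the result is platform-independent.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(D < -1e-12):
        raise ValueError("distances must be non-negative")
    labels = labels or [str(i) for i in range(n)]
    # current clusters: id -> member leaf set; inter-cluster distance = max
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                key = (min(a, b), max(a, b))
                d = dist[key]
                if best is None or d < best[0] - 1e-15 or (
                    abs(d - best[0]) <= 1e-15 and key < best[1]
                ):
                    best = (d, key)
        d, (a, b) = best
        merges.append((a, b, d))
        for c in active:
            if c in (a, b):
                continue
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            dist[(min(c, next_id), max(c, next_id))] = max(dist[ka], dist[kb])
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(labels=labels, merges=merges)
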