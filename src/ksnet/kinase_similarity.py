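"""Substrate-overlap kinase similarity, UPGMA clustering, and enrichment.

Kinase pairs are compared through the Jaccard index of their predicted
substrate sets (edges with probability strictly greater than 0.5); 1 - J is
the distance fed to UPGMA average-linkage clustering, whose ultrametric
merge heights equal half the inter-cluster distance. High-overlap clusters
(J > 0.5 components) group kinases with near-identical substrate repertoires
and can transfer functional annotation onto understudied members via
Fisher's-exact gene-set enrichment of their substrate proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ProbabilisticNetwork, parse_site_id


@dataclass
class SimilarityMatrix:
    """Symmetric Jaccard matrix J with its 1 - J distance companion."""

    J: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.J.index.equals(self.J.columns):
            raise ValueError("similarity matrix must be square and aligned")
        arr = self.J.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(arr), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")

    @property
    def D(self) -> pd.DataFrame:
        return 1.0 - self.J

    @property
    def ids(self) -> list[str]:
        return list(self.J.index)


@dataclass
class Dendrogram:
    """UPGMA merge list; heights are ultrametric node heights (d/2)."""

    leaves: list[str]
    # (left child id, right child id, height, size); cluster ids: 0..n-1 are
    # leaves, n + i is the cluster created by merge i.
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a dendrogram over n leaves needs n - 1 merges")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing (ultrametric)")

    def cophenetic(self) -> pd.DataFrame:
        """Implied leaf-pair distances (2x merge height of the join)."""
        n = len(self.leaves)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        out = np.zeros((n, n))
        for i, (a, b, h, _) in enumerate(self.merges):
            for x in members[a]:
                for y in members[b]:
                    out[x, y] = out[y, x] = 2 * h
            members[n + i] = members.pop(a) + members.pop(b)
        return pd.DataFrame(out, index=self.leaves, columns=self.leaves)

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences."""
        n = len(self.leaves)
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        text: dict[int, str] = {i: self.leaves[i] for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.merges):
            la, lb = h - height[a], h - height[b]
            text[n + i] = f"({text[a]}:{la:.6f},{text[b]}:{lb:.6f})"
            height[n + i] = h
        return text[n + len(self.merges) - 1] + ";"


def substrate_sets_above(
    net: ProbabilisticNetwork, cutoff: float = 0.5
) -> dict[str, set[str]]:
    kept = net.edges_above(cutoff, strict=True)
    out: dict[str, set[str]] = {}
    for k, s in zip(kept["kinase_id"], kept["site_id"]):
        out.setdefault(k, set()).add(s)
    return out


def jaccard_from_sets(sets: dict[str, frozenset | set]) -> SimilarityMatrix:
    ids = sorted(sets)
    n = len(ids)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sets[ids[i]], sets[ids[j]]
            union = len(a | b)
            J[i, j] = J[j, i] = len(a & b) / union if union else 0.0
    return SimilarityMatrix(pd.DataFrame(J, index=ids, columns=ids))


def substrate_jaccard(
    net: ProbabilisticNetwork, cutoff: float = 0.5
) -> tuple[SimilarityMatrix, list[str]]:
    """Jaccard similarity of per-kinase substrate sets above ``cutoff``.

    Kinases with empty sets are excluded and returned in the report list.
    """
    sets = substrate_sets_above(net, cutoff)
    all_kinases = sorted(net.edges["kinase_id"].unique())
    excluded = [k for k in all_kinases if k not in sets]
    if len(sets) < 2:
        raise ValueError("need >= 2 kinases with non-empty substrate sets")
    return jaccard_from_sets(sets), excluded


def upgma(D: pd.DataFrame) -> Dendrogram:
    """UPGMA clustering of a symmetric distance matrix.

    Repeatedly merges the closest pair of clusters; the distance from the
    merged cluster to any other is the size-weighted arithmetic mean of its
    members' distances, and the merge height is half the merged distance.
    Equal minimum distances resolve to the lexicographically smallest
    cluster-id pair for determinism.
    """
    arr = D.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(arr) != 0):
        raise ValueError("distance matrix must have zero diagonal")
    if np.any(arr < 0):
        raise ValueError("distances must be non-negative")
    leaves = list(D.index.astype(str))
    n = len(leaves)
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(arr[i, j])
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        (a, b), d = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        size = active[a] + active[b]
        merges.append((a, b, d / 2.0, size))
        for other in active:
            if other in (a, b):
                continue
            da = dist[(min(a, other), max(a, other))]
            db = dist[(min(b, other), max(b, other))]
            dnew = (active[a] * da + active[b] * db) / size
            dist[(other, next_id)] = dnew
        for key in [k for k in dist if a in k or b in k]:
            del dist[key]
        del active[a], active[b]
        active[next_id] = size
        next_id += 1
    return Dendrogram(leaves, merges)


def overlap_clusters(
    sim: SimilarityMatrix, threshold: float = 0.5
) -> list[list[str]]:
    """Connected components of the kinase graph with edges where J > threshold.

    Singletons are omitted; clusters are sorted by size (desc) then by their
    smallest member for determinism.
    """
    g = nx.Graph()
    ids = sim.ids
    g.add_nodes_from(ids)
    arr = sim.J.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if arr[i, j] > threshold:
                g.add_edge(ids[i], ids[j])
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
    return sorted(comps, key=lambda c: (-len(c), c[0]))


def substrate_proteins(
    net: ProbabilisticNetwork, kinase_id: str, cutoff: float = 0.5
) -> set[str]:
    """Substrate *proteins* of a kinase: any site above cutoff includes it."""
    sets = substrate_sets_above(net, cutoff)
    return {parse_site_id(s)[0] for s in sets.get(kinase_id, set())}


def set_enrichment(
    substrates: set[str],
    gene_sets: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of substrate proteins per gene set.

    Returns the sets with BH-adjusted p < alpha, with odds ratios and both
    raw and adjusted p-values, sorted by adjusted p.
    """
    if not gene_sets:
        raise ValueError("gene set collection is empty")
    offenders = sorted(substrates - background)
    if offenders:
        raise ValueError(f"substrates absent from background: {offenders[:5]}")
    n_bg = len(background)
    n_sub = len(substrates)
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & background
        a = len(substrates & members)
        b = n_sub - a
        c = len(members) - a
        d = n_bg - n_sub - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"set": name, "n_overlap": a, "n_set": len(members),
             "odds_ratio": float(odds), "pvalue": float(p)}
        )
    table = pd.DataFrame(rows)
    _, adj, _, _ = multipletests(table["pvalue"], method="fdr_bh")
    table["adjusted_p"] = adj
    hits = table[table["adjusted_p"] < alpha].sort_values(
        ["adjusted_p", "set"], kind="stable"
    )
    return hits.reset_index(drop=True)


def annotation_similarity(
    enriched_terms: dict[str, set[str]]
) -> SimilarityMatrix:
    """Jaccard similarity over per-kinase significantly enriched term sets."""
    usable = {k: v for k, v in enriched_terms.items() if v}
    if len(usable) < 2:
        raise ValueError("need >= 2 kinases with >= 1 significant term")
    return jaccard_from_sets(usable)
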