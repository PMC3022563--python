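"""Exact all-pairs scan via MST-incremental contingency tables (TEAM).

Setting: binary trait, any genotype alphabet, larger samples.  A minimum
spanning tree is built over the SNPs with Hamming-distance edge weights
(the number of individuals at which two SNP rows differ); each tree edge
stores the diff list of those individuals.  For an anchor SNP *i* the full
case/control joint table against the tree root is counted once in O(n);
walking the tree depth-first then updates the table along each edge by
touching only the differing individuals, and restores it on backtrack.
Every pair's table — hence its statistic — is exact, and every pair is
recorded, which is what makes both FWER and FDR control available
downstream.

The tree depends only on genotypes, so it is built once per dataset and
reused across all phenotype permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core_data import BINARY_TRAIT, GenotypeMatrix, PhenotypeVector, ScanResult
from .stats import CONTINGENCY_TESTS, ContingencyTable


def hamming_distance(xu: np.ndarray, xv: np.ndarray) -> int:
    xu = np.asarray(xu)
    xv = np.asarray(xv)
    if xu.shape != xv.shape:
        raise ValueError("genotype rows of unequal length")
    return int((xu != xv).sum())


@dataclass
class DiffList:
    """Individuals at which two SNP rows differ, with both codes."""

    idx: np.ndarray  # individual indices
    code_u: np.ndarray
    code_v: np.ndarray

    @property
    def weight(self) -> int:
        return self.idx.size


@dataclass
class SpanningTree:
    m: int
    root: int
    edges: list[tuple[int, int, DiffList]]

    @property
    def total_weight(self) -> int:
        return sum(d.weight for _, _, d in self.edges)

    def adjacency(self) -> list[list[tuple[int, DiffList, bool]]]:
        """Per node: (neighbor, diff, forward?) — forward means the diff is
        stored in this traversal direction (u -> v)."""
        adj: list[list[tuple[int, DiffList, bool]]] = [[] for _ in range(self.m)]
        for u, v, d in self.edges:
            adj[u].append((v, d, True))
            adj[v].append((u, d, False))
        return adj


def _diff_list(xu: np.ndarray, xv: np.ndarray) -> DiffList:
    idx = np.nonzero(xu != xv)[0]
    return DiffList(idx, xu[idx].copy(), xv[idx].copy())


def build_mst(G: GenotypeMatrix) -> SpanningTree:
    """Prim's algorithm over the complete Hamming graph, rooted at SNP 0.

    Deterministic tie-breaking: among equal-weight candidate cut edges the
    one with the smallest (min endpoint, max endpoint) is chosen, so two
    builds of the same matrix yield identical edge sets.
    """
    m = G.m
    codes = G.codes
    dist = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
    in_tree = np.zeros(m, dtype=bool)
    in_tree[0] = True
    # best known cut edge to each outside node, as (weight, min_ep, max_ep, u)
    best = [(int(dist[0, v]), min(0, v), max(0, v), 0) for v in range(m)]
    edges: list[tuple[int, int, DiffList]] = []
    for _ in range(m - 1):
        pick, key = -1, None
        for v in range(m):
            if in_tree[v]:
                continue
            w, a, b, _ = best[v]
            if key is None or (w, a, b) < key:
                key, pick = (w, a, b), v
        u = best[pick][3]
        in_tree[pick] = True
        edges.append((u, pick, _diff_list(codes[u], codes[pick])))
        for v in range(m):
            if in_tree[v]:
                continue
            w = int(dist[pick, v])
            cand = (w, min(pick, v), max(pick, v), pick)
            if cand[:3] < best[v][:3]:
                best[v] = cand
    return SpanningTree(m=m, root=0, edges=edges)


def apply_diff(
    table: np.ndarray,
    diff: DiffList,
    xi: np.ndarray,
    y: np.ndarray,
    direction: str = "forward",
    counter: list | None = None,
) -> None:
    """Move the anchor-i joint table along a tree edge in place.

    ``table`` has shape (card_i, card_j, 2) indexed by (anchor code,
    partner code, phenotype class); ``forward`` re-labels each differing
    individual from code_u to code_v (``backward`` reverses), touching only
    ``diff.weight`` individuals.  A count driven below zero means the
    traversal state is corrupted.
    """
    if diff.weight == 0:
        return
    old, new = (
        (diff.code_u, diff.code_v)
        if direction == "forward"
        else (diff.code_v, diff.code_u)
    )
    a = xi[diff.idx]
    c = y[diff.idx]
    np.subtract.at(table, (a, old, c), 1)
    np.add.at(table, (a, new, c), 1)
    if counter is not None:
        counter[0] += diff.weight
    if (table[a, old, c] < 0).any():
        raise RuntimeError("contingency count below zero: corrupted traversal")


def _base_table(xi: np.ndarray, xroot: np.ndarray, y: np.ndarray, card: int) -> np.ndarray:
    flat = (xi.astype(np.int64) * card + xroot) * 2 + y
    return np.bincount(flat, minlength=card * card * 2).reshape(card, card, 2)


def iter_anchor_tables(
    G: GenotypeMatrix,
    y: np.ndarray,
    anchor: int,
    tree: SpanningTree,
    adj=None,
    counter: list | None = None,
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield ``(j, table)`` for every SNP j visited by the DFS, where
    ``table`` is the live (card, card, 2) joint table of pair (anchor, j).

    The yielded array is the mutable traversal state — callers who keep a
    table must copy it.  Yields the root first, then nodes in DFS order;
    the anchor itself is yielded too (its table is the anchor-vs-anchor
    joint count, skipped by the scan).
    """
    card = G.card
    xi = G.codes[anchor]
    yv = np.asarray(y, dtype=np.int64)
    table = _base_table(xi, G.codes[tree.root], yv, card)
    if counter is not None:
        counter[0] += yv.size
    if adj is None:
        adj = tree.adjacency()
    yield tree.root, table
    # iterative DFS with explicit undo on backtrack
    stack: list = [(tree.root, -1, iter(adj[tree.root]), None, None)]
    while stack:
        node, parent, it, in_diff, in_fwd = stack[-1]
        advanced = False
        for nbr, diff, fwd in it:
            if nbr == parent:
                continue
            apply_diff(table, diff, xi, yv, "forward" if fwd else "backward", counter)
            yield nbr, table
            stack.append((nbr, node, iter(adj[nbr]), diff, fwd))
            advanced = True
            break
        if not advanced:
            stack.pop()
            if in_diff is not None:
                apply_diff(
                    table, in_diff, xi, yv, "backward" if in_fwd else "forward", counter
                )


def _table_statistic(table: np.ndarray, card: int, func) -> tuple[float, int]:
    flat = table.reshape(card * card, 2)
    occupied = flat.sum(axis=1) > 0
    k = int(occupied.sum())
    if k < 2:
        return 0.0, k
    counts = np.vstack([flat[occupied, 1], flat[occupied, 0]])  # rows: case, control
    return func(ContingencyTable(counts, np.nonzero(occupied)[0])), k


def team_scan(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    test: str = "chi2",
    tree: SpanningTree | None = None,
    counters: dict | None = None,
) -> ScanResult:
    """Exact statistics for all ``m (m-1) / 2`` pairs via the MST walk.

    ``counters['individuals_touched']`` (if a dict is supplied) receives the
    instrumentation total: each anchor costs one O(n) base count plus twice
    the tree weight in diff updates.
    """
    if y.kind != BINARY_TRAIT:
        raise ValueError("TEAM requires a binary trait")
    if test not in CONTINGENCY_TESTS:
        raise ValueError(f"unknown test {test!r}")
    if G.n != y.n:
        raise ValueError("genotype and phenotype sample sizes differ")
    func = CONTINGENCY_TESTS[test]
    if tree is None:
        tree = build_mst(G)
    adj = tree.adjacency()
    touch = [0]
    pairs = []
    for i in range(G.m):
        for j, table in iter_anchor_tables(G, y.values, i, tree, adj, touch):
            if j > i:
                stat, k = _table_statistic(table, G.card, func)
                pairs.append((i, j, stat, k))
    if counters is not None:
        counters["individuals_touched"] = touch[0]
    return ScanResult.from_pairs(
        pairs,
        G.snp_ids,
        metadata={"engine": "team", "test": test, "pairs_total": len(pairs)},
    )
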