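"""Exhaustive two-locus ANOVA scan with upper-bound pruning (FastANOVA).

Setting: quantitative trait, binary genotypes (homozygous designs, small
samples).  For an anchor SNP *i* the individuals split into groups
A = {Xi = 0} and B = {Xi = 1}.  Pairing *i* with a partner *j* refines each
group by Xj, and the two-locus between-group sum of squares decomposes as

    SS_b(i, j) = SS_b(i) + gain_A + gain_B,

where splitting a group of size ``n_g`` with phenotype sum ``T_g`` into a
subgroup of size ``n_1`` with sum ``T_1`` yields

    gain = (n_g T_1 - n_1 T_g)^2 / (n_g n_1 (n_g - n_1)).

The gain is a convex quadratic in ``T_1``, and ``T_1`` is a sum of ``n_1``
of the group's phenotype values, so it lies between the sum of the ``n_1``
smallest and the ``n_1`` largest values.  Evaluating the quadratic at those
two extremes gives an upper bound on the gain — the permutation-dependent
term — while the subgroup sizes ``(n_A1, n_B1)`` depend only on genotypes.

Partners of an anchor are therefore indexed by ``(n_A1, n_B1)`` in a 2-D
array built once per dataset and reused across all phenotype permutations;
every partner in an entry shares the same upper bound, and the number of
entries is at most ``(n_A + 1)(n_B + 1)``.  Only entries whose F bound
reaches the threshold are tested exactly, and the exact test is the same
routine the brute-force oracle uses, so the scan returns exactly the pairs
a full scan would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import BINARY, QUANTITATIVE, GenotypeMatrix, PhenotypeVector, ScanResult
from .stats import anova_f, joint_group_labels

# relative slack when comparing a bound to the pruning threshold: the bound
# and the exact statistic are computed by different algebraic routes, so a
# pair whose exact F equals theta must not be lost to rounding
_SLACK = 1e-9


@dataclass
class AnchorIndex:
    """Per-anchor 2-D grouping of partner SNPs by genotype overlap.

    ``entries[(n_A1, n_B1)]`` lists the partners *j* with
    ``n_A1 = #{Xi=0 and Xj=1}`` and ``n_B1 = #{Xi=1 and Xj=1}``.
    Depends only on genotypes — identical before and after any phenotype
    permutation.
    """

    anchor: int
    n_a: int
    n_b: int
    entries: dict[tuple[int, int], list[int]] = field(default_factory=dict)


def build_anchor_index(
    G: GenotypeMatrix, i: int, partners=None
) -> AnchorIndex:
    if G.alphabet != BINARY:
        raise ValueError("FastANOVA index requires binary genotypes")
    xi = G.codes[i]
    mask_a = xi == 0
    mask_b = ~mask_a
    if partners is None:
        partners = [j for j in range(G.m) if j != i]
    else:
        partners = list(partners)
    index = AnchorIndex(anchor=i, n_a=int(mask_a.sum()), n_b=int(mask_b.sum()))
    if partners:
        xs = G.codes[partners]
        na1 = xs[:, mask_a].sum(axis=1)
        nb1 = xs[:, mask_b].sum(axis=1)
        for j, a1, b1 in zip(partners, na1, nb1):
            index.entries.setdefault((int(a1), int(b1)), []).append(j)
    return index


@dataclass
class GroupPrefix:
    """Sorted phenotype values of one anchor group with extremal prefix
    sums: ``low[r]`` / ``high[r]`` are the sums of the r smallest / largest
    values; ``low[size] = high[size] = total``."""

    sorted_values: np.ndarray
    low: np.ndarray
    high: np.ndarray
    total: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "GroupPrefix":
        s = np.sort(np.asarray(values, dtype=float))
        low = np.concatenate([[0.0], np.cumsum(s)])
        high = np.concatenate([[0.0], np.cumsum(s[::-1])])
        return cls(s, low, high, float(s.sum()))


def group_prefix_sums(
    values: np.ndarray, anchor_row: np.ndarray
) -> tuple[GroupPrefix, GroupPrefix]:
    """Prefix structures for groups A (Xi=0) and B (Xi=1); recomputed per
    permutation in O(n log n)."""
    values = np.asarray(values, dtype=float)
    mask_a = np.asarray(anchor_row) == 0
    return (
        GroupPrefix.from_values(values[mask_a]),
        GroupPrefix.from_values(values[~mask_a]),
    )


def delta_bound(n_g: int, n_1: int, t_g: float, low: np.ndarray, high: np.ndarray) -> float:
    """Upper bound on the between-group SS gain from splitting a group of
    size ``n_g`` (sum ``t_g``) into subgroups of sizes ``n_1, n_g - n_1``.

    Zero when the split is trivial; otherwise the convex quadratic
    ``(n_g T_1 - n_1 t_g)^2 / (n_g n_1 (n_g - n_1))`` evaluated at the
    extremal feasible subgroup sums ``low[n_1]`` and ``high[n_1]``.
    """
    if n_1 < 0 or n_1 > n_g:
        raise ValueError("subgroup size out of range")
    if n_1 == 0 or n_1 == n_g:
        return 0.0
    denom = n_g * n_1 * (n_g - n_1)
    best = 0.0
    for t1 in (low[n_1], high[n_1]):
        best = max(best, (n_g * t1 - n_1 * t_g) ** 2 / denom)
    return best


def entry_k(n_a: int, n_b: int, n_a1: int, n_b1: int) -> int:
    """Non-empty joint-genotype cells determined by an index entry."""
    cells = (n_a - n_a1, n_a1, n_b - n_b1, n_b1)
    return sum(1 for c in cells if c > 0)


def entry_upper_bound(
    n_a1: int,
    n_b1: int,
    index: AnchorIndex,
    pref_a: GroupPrefix,
    pref_b: GroupPrefix,
    ss_b_single: float,
    ss_total: float,
    n: int,
) -> float:
    """F upper bound shared by every pair in one index entry.

    Sum of the anchor's single-locus between-group SS and the two extremal
    split gains, clamped to the total SS; converted to an F bound with the
    entry's exact group count ``k`` (the entry fixes which joint cells are
    empty).  Degenerate entries (k < 2 or n <= k) bound the conventional
    statistic 0.
    """
    k = entry_k(index.n_a, index.n_b, n_a1, n_b1)
    if k < 2 or n <= k:
        return 0.0
    ub = ss_b_single
    ub += delta_bound(index.n_a, n_a1, pref_a.total, pref_a.low, pref_a.high)
    ub += delta_bound(index.n_b, n_b1, pref_b.total, pref_b.low, pref_b.high)
    ub = min(ub, ss_total)
    if ss_total - ub <= 0.0:
        return float("inf") if ub > 0 else 0.0
    return (ub / (k - 1)) / ((ss_total - ub) / (n - k))


def _single_locus_ssb(values: np.ndarray, anchor_row: np.ndarray) -> float:
    mask_a = np.asarray(anchor_row) == 0
    n = values.size
    t = float(values.sum())
    ssb = -t * t / n
    for mask in (mask_a, ~mask_a):
        ng = int(mask.sum())
        if ng:
            tg = float(values[mask].sum())
            ssb += tg * tg / ng
    return max(ssb, 0.0)


def fastanova_scan(
    G: GenotypeMatrix, y: PhenotypeVector, theta: float
) -> ScanResult:
    """Return exactly the pairs whose exact two-locus F is >= ``theta``.

    Per anchor: build the genotype-only partner index, refresh the
    phenotype-dependent prefix structures, bound whole entries at once and
    run the exact ANOVA only inside entries whose bound reaches the
    threshold.  Ties at the threshold are included.
    """
    if G.alphabet != BINARY:
        raise ValueError("FastANOVA requires binary genotypes")
    if y.kind != QUANTITATIVE:
        raise ValueError("FastANOVA requires a quantitative trait")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if G.n != y.n:
        raise ValueError("genotype and phenotype sample sizes differ")
    values = y.values
    n = values.size
    t = float(values.sum())
    ss_total = max(float(values @ values) - t * t / n, 0.0)
    cut = theta - _SLACK * max(1.0, abs(theta))
    pairs = []
    candidates = 0
    for i in range(G.m - 1):
        xi = G.codes[i]
        index = build_anchor_index(G, i, partners=range(i + 1, G.m))
        pref_a, pref_b = group_prefix_sums(values, xi)
        ssb1 = _single_locus_ssb(values, xi)
        for (na1, nb1), js in index.entries.items():
            bound = entry_upper_bound(
                na1, nb1, index, pref_a, pref_b, ssb1, ss_total, n
            )
            if bound >= cut:
                candidates += len(js)
                for j in js:
                    labels, k = joint_group_labels(xi, G.codes[j], 2)
                    if k < 2 or n <= k:
                        stat = 0.0
                    else:
                        stat = anova_f(values, labels).f
                    if stat >= theta:
                        pairs.append((i, j, stat, k))
    total = G.m * (G.m - 1) // 2
    return ScanResult.from_pairs(
        pairs,
        G.snp_ids,
        metadata={
            "engine": "fastanova",
            "test": "anova",
            "theta": theta,
            "pairs_total": total,
            "pairs_tested": candidates,
        },
    )
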