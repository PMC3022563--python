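"""Exact single- and two-locus test statistics, and the brute-force oracle.

Quantitative traits are tested with one-way ANOVA over joint-genotype
groups; binary traits with contingency-table statistics (Pearson chi-square,
likelihood-ratio G, mutual information in nats) on the 2 x k table of
phenotype class by joint-genotype group.  Degenerate-case conventions (the
max-statistic over permutations must always be well defined):

* ANOVA: ``F = +inf`` when the within-group sum of squares is zero but the
  between-group one is positive (perfect separation); ``F = 0`` when the
  between-group sum of squares is zero;
* a pair whose test is undefined (fewer than 2 non-empty groups, or no
  residual degrees of freedom for ANOVA) scores 0, with its group count
  ``k`` still reported.

No asymptotic p-values are computed anywhere — significance comes only
from the permutation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import (
    BINARY_TRAIT,
    QUANTITATIVE,
    GenotypeMatrix,
    PhenotypeVector,
    ScanResult,
)


@dataclass
class AnovaResult:
    """One-way ANOVA decomposition over non-empty groups."""

    ss_between: float
    ss_within: float
    ss_total: float
    k: int
    f: float


def anova_f(values: np.ndarray, labels: np.ndarray) -> AnovaResult:
    """One-way ANOVA of ``values`` grouped by ``labels``.

    ``SS_between = sum_g T_g^2 / n_g - T^2 / n`` over non-empty groups;
    ``SS_within = SS_total - SS_between``.

    Raises
    ------
    ValueError
        ``"monomorphic split"`` if fewer than 2 non-empty groups;
        ``"no residual degrees of freedom"`` if ``n <= k``.
    """
    values = np.asarray(values, dtype=float)
    _, inv = np.unique(np.asarray(labels), return_inverse=True)
    k = int(inv.max()) + 1
    n = values.size
    if k < 2:
        raise ValueError("monomorphic split")
    if n <= k:
        raise ValueError("no residual degrees of freedom")
    n_g = np.bincount(inv, minlength=k)
    t_g = np.bincount(inv, weights=values, minlength=k)
    t = float(values.sum())
    ss_total = float(values @ values) - t * t / n
    ss_total = max(ss_total, 0.0)
    ss_between = float((t_g * t_g / n_g).sum()) - t * t / n
    ss_between = min(max(ss_between, 0.0), ss_total) if ss_total > 0 else 0.0
    ss_within = ss_total - ss_between
    if ss_between <= 0.0:
        f = 0.0
    elif ss_within <= 0.0:
        f = float("inf")
    else:
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return AnovaResult(ss_between, ss_within, ss_total, k, f)


def joint_group_labels(xi: np.ndarray, xj: np.ndarray, card: int) -> tuple[np.ndarray, int]:
    """Joint-genotype code ``xi * card + xj`` per individual, and the number
    of distinct observed codes (non-empty joint groups)."""
    xi = np.asarray(xi)
    xj = np.asarray(xj)
    if xi.shape != xj.shape:
        raise ValueError("genotype rows of unequal length")
    labels = xi.astype(np.int64) * card + xj
    return labels, int(np.unique(labels).size)


@dataclass
class ContingencyTable:
    """2 x k table of phenotype class (row 0 = case, row 1 = control) by
    non-empty joint-genotype group, columns in ascending joint-code order."""

    counts: np.ndarray
    joint_codes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.joint_codes = np.asarray(self.joint_codes, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2:
            raise ValueError("contingency table must be 2 x k")
        if (self.counts < 0).any():
            raise ValueError("negative count")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("empty genotype column")

    @property
    def k(self) -> int:
        return self.counts.shape[1]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def contingency_table(
    xi: np.ndarray, xj: np.ndarray, y: np.ndarray, card: int
) -> ContingencyTable:
    """Count the 2 x k case/control by joint-genotype table for one pair."""
    labels, _ = joint_group_labels(xi, xj, card)
    y = np.asarray(y).astype(np.int64)
    ncodes = card * card
    case = np.bincount(labels[y == 1], minlength=ncodes)
    ctrl = np.bincount(labels[y == 0], minlength=ncodes)
    total = case + ctrl
    keep = total > 0
    return ContingencyTable(
        np.vstack([case[keep], ctrl[keep]]), np.nonzero(keep)[0]
    )


def _expected(t: ContingencyTable) -> np.ndarray:
    rows = t.row_margins
    if rows[0] == 0 or rows[1] == 0:
        raise ValueError("single-class phenotype")
    return np.outer(rows, t.col_margins) / t.n


def chi_square(t: ContingencyTable) -> float:
    """Pearson chi-square; empty columns were dropped so every E > 0."""
    e = _expected(t)
    return float((((t.counts - e) ** 2) / e).sum())


def g_statistic(t: ContingencyTable) -> float:
    """Likelihood-ratio G = 2 sum O ln(O/E), with 0 ln 0 = 0, in nats."""
    e = _expected(t)
    o = t.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    return float(2.0 * terms.sum())


def mutual_information(t: ContingencyTable) -> float:
    """Mutual information (nats) between phenotype class and joint group,
    from the empirical joint distribution; satisfies ``G = 2 N MI``."""
    rows = t.row_margins
    if rows[0] == 0 or rows[1] == 0:
        raise ValueError("single-class phenotype")
    n = t.n
    p = t.counts / n
    pc = rows / n
    pg = t.col_margins / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / np.outer(pc, pg)), 0.0)
    return float(terms.sum())


CONTINGENCY_TESTS = {
    "chi2": chi_square,
    "gtest": g_statistic,
    "mi": mutual_information,
}

ALL_TESTS = ("anova", "chi2", "gtest", "mi")


def check_test_compatible(test: str, kind: str) -> None:
    if test == "anova":
        if kind != QUANTITATIVE:
            raise ValueError("ANOVA requires a quantitative phenotype")
    elif test in CONTINGENCY_TESTS:
        if kind != BINARY_TRAIT:
            raise ValueError(f"{test} requires a binary phenotype")
    else:
        raise ValueError(f"unknown test {test!r}")


def pair_statistic(
    G: GenotypeMatrix, y: PhenotypeVector, i: int, j: int, test: str
) -> tuple[float, int]:
    """Exact statistic and group count for one pair (degenerate -> 0)."""
    xi, xj = G.codes[i], G.codes[j]
    if test == "anova":
        labels, k = joint_group_labels(xi, xj, G.card)
        try:
            return anova_f(y.values, labels).f, k
        except ValueError:
            return 0.0, k
    t = contingency_table(xi, xj, y.values, G.card)
    if t.k < 2:
        return 0.0, t.k
    return CONTINGENCY_TESTS[test](t), t.k


def brute_force_scan(G: GenotypeMatrix, y: PhenotypeVector, test: str) -> ScanResult:
    """Direct all-pairs scan: the oracle every pruning engine is checked
    against.  Emits all ``m (m-1) / 2`` pairs; undefined pairs score 0."""
    check_test_compatible(test, y.kind)
    if G.n != y.n:
        raise ValueError("genotype and phenotype sample sizes differ")
    pairs = []
    for i in range(G.m - 1):
        for j in range(i + 1, G.m):
            stat, k = pair_statistic(G, y, i, j, test)
            pairs.append((i, j, stat, k))
    return ScanResult.from_pairs(
        pairs, G.snp_ids, metadata={"engine": "brute", "test": test}
    )


def pair_stats_for_phenotypes(
    G: GenotypeMatrix,
    Y: np.ndarray,
    test: str,
    pair_chunk: int = 512,
) -> np.ndarray:
    """Exact statistics of all pairs for many binary phenotypes at once.

    ``Y`` is an ``(n, K)`` 0/1 matrix whose columns are phenotype
    assignments sharing the genotype matrix (typically permutations of one
    observed phenotype).  Returns a ``(P, K)`` array over the ``P = m(m-1)/2``
    pairs in (i, j) lexicographic order; values agree with
    :func:`brute_force_scan` / the TEAM engine to floating-point accuracy.

    This shared-genotype path is what makes dense permutation nulls cheap:
    the joint-group membership masks are built once and reused for every
    permutation column.
    """
    if test not in CONTINGENCY_TESTS:
        raise ValueError(f"{test!r} is not a contingency-table test")
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim != 2 or Y.shape[0] != G.n:
        raise ValueError("Y must be (n, K)")
    n, K = Y.shape
    card = G.card
    ncodes = card * card
    iu, ju = np.triu_indices(G.m, k=1)
    P = iu.size
    M = Y.sum(axis=0)  # cases per phenotype column
    out = np.empty((P, K))
    codes = G.codes.astype(np.int64)
    for lo in range(0, P, pair_chunk):
        hi = min(lo + pair_chunk, P)
        lab = codes[iu[lo:hi]] * card + codes[ju[lo:hi]]  # (C, n)
        C = hi - lo
        col = np.empty((C, ncodes))
        case = np.empty((C, ncodes, K))
        for g in range(ncodes):
            mask = lab == g
            col[:, g] = mask.sum(axis=1)
            case[:, g, :] = mask @ Y
        colg = col[:, :, None]
        occupied = colg > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            e1 = colg * (M / n)
            e0 = colg - e1
            o1 = case
            o0 = colg - o1
            if test == "chi2":
                terms = np.where(occupied, (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0, 0.0)
                stat = terms.sum(axis=1)
            else:
                t1 = np.where(o1 > 0, o1 * np.log(o1 / e1), 0.0)
                t0 = np.where(o0 > 0, o0 * np.log(o0 / e0), 0.0)
                g2 = 2.0 * np.where(occupied, t1 + t0, 0.0).sum(axis=1)
                stat = g2 if test == "gtest" else g2 / (2.0 * n)
        # pairs with a single occupied joint group are degenerate -> 0
        k_pair = (col > 0).sum(axis=1)
        stat[k_pair < 2, :] = 0.0
        out[lo:hi] = stat
    return out
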