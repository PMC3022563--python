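"""Exhaustive two-locus scan with convex upper bounds (COE).

Setting: binary trait, binary genotypes.  For a pair (Xi, Xj) the 2 x 4
case/control by joint-genotype table is pinned down, given the joint cell
sizes and the single-locus case margins, by a single free integer

    t = number of cases in the (Xi=0, Xj=0) cell,

whose feasible range [L, U] follows from requiring every cell count to be
non-negative and no larger than its cell size.  The contingency-table
statistics used here (Pearson chi-square, likelihood-ratio G, mutual
information) are convex functions of t on that interval, so their maximum
over feasible tables is attained at an endpoint: ``max(stat(L), stat(U))``
upper-bounds the statistic of the true table, which corresponds to some
t in [L, U].

The joint cell sizes are genotype-only (reused from the FastANOVA anchor
index, whose entry key ``(n_A1, n_B1)`` is a bijection of the cell sizes
given anchor group sizes), while the case margins refresh in O(m) per
phenotype permutation.  Only candidates whose bound reaches the threshold
are tested exactly, with the same statistic routine the brute-force oracle
uses.

Any user statistic declared convex may be registered; registration runs a
grid-dominance self-check (endpoint max vs every interior integer t) on
random tables before accepting it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .core_data import BINARY, BINARY_TRAIT, GenotypeMatrix, PhenotypeVector, ScanResult
from .fastanova import build_anchor_index
from .stats import CONTINGENCY_TESTS, ContingencyTable, contingency_table

_SLACK = 1e-9


class PairGenotypeCounts(NamedTuple):
    """Joint genotype cell sizes for (Xi, Xj) in {0,1}^2."""

    n_00: int
    n_01: int
    n_10: int
    n_11: int

    @property
    def n(self) -> int:
        return sum(self)


class CaseMargins(NamedTuple):
    """Single-locus case counts; permutation-dependent, O(m) to refresh."""

    c_i0: int
    c_i1: int
    c_j0: int
    c_j1: int
    m_cases: int


class FeasibleInterval(NamedTuple):
    low: int
    high: int


def feasible_interval(counts: PairGenotypeCounts, margins: CaseMargins) -> FeasibleInterval:
    """Integer range of t = cases in joint cell (0,0) consistent with the
    cell sizes and case margins.  L > U cannot occur for tables counted
    from real data and signals a caller bug."""
    low = max(
        0,
        margins.c_i0 - counts.n_01,
        margins.c_j0 - counts.n_10,
        margins.c_j0 - margins.c_i1,
    )
    high = min(
        counts.n_00,
        margins.c_i0,
        margins.c_j0,
        counts.n_11 + margins.c_j0 - margins.c_i1,
    )
    if low > high:
        raise ValueError("inconsistent margins")
    return FeasibleInterval(low, high)


def table_at(
    t: int, counts: PairGenotypeCounts, margins: CaseMargins
) -> ContingencyTable:
    """Materialize the 2 x k table with ``t`` cases in cell (0,0); empty
    genotype columns are dropped (joint codes 0..3 = 00,01,10,11)."""
    case = np.array(
        [
            t,
            margins.c_i0 - t,
            margins.c_j0 - t,
            margins.c_i1 - margins.c_j0 + t,
        ],
        dtype=np.int64,
    )
    sizes = np.array(counts, dtype=np.int64)
    if (case < 0).any() or (case > sizes).any():
        raise ValueError("t outside the feasible interval")
    keep = sizes > 0
    return ContingencyTable(
        np.vstack([case[keep], (sizes - case)[keep]]), np.nonzero(keep)[0]
    )


def _stat_of(table: ContingencyTable, func: Callable[[ContingencyTable], float]) -> float:
    return 0.0 if table.k < 2 else func(table)


def convex_upper_bound(
    counts: PairGenotypeCounts, margins: CaseMargins, test: str
) -> float:
    """Endpoint maximum of the statistic over the feasible interval —
    an upper bound on the statistic of the true table."""
    func = get_convex_statistic(test)
    n = counts.n
    if margins.m_cases == 0 or margins.m_cases == n:
        return 0.0
    low, high = feasible_interval(counts, margins)
    bound = _stat_of(table_at(low, counts, margins), func)
    if high != low:
        bound = max(bound, _stat_of(table_at(high, counts, margins), func))
    return bound


# ---------------------------------------------------------------------------
# convex-statistic registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable[[ContingencyTable], float]] = dict(CONTINGENCY_TESTS)


def get_convex_statistic(name: str) -> Callable[[ContingencyTable], float]:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown convex statistic {name!r}") from None


def random_counts_margins(rng: np.random.Generator, n_max: int = 40):
    """Draw a random consistent (counts, margins) pair by simulating data."""
    n = int(rng.integers(4, n_max + 1))
    cells = rng.multinomial(n, [0.25] * 4)
    counts = PairGenotypeCounts(*(int(c) for c in cells))
    is_case = rng.random(n) < rng.uniform(0.2, 0.8)
    cell_of = np.repeat(np.arange(4), cells)
    case_in = np.bincount(cell_of[is_case], minlength=4)
    margins = CaseMargins(
        c_i0=int(case_in[0] + case_in[1]),
        c_i1=int(case_in[2] + case_in[3]),
        c_j0=int(case_in[0] + case_in[2]),
        c_j1=int(case_in[1] + case_in[3]),
        m_cases=int(is_case.sum()),
    )
    return counts, margins


def register_convex_statistic(
    name: str,
    func: Callable[[ContingencyTable], float],
    n_checks: int = 100,
    seed: int = 0,
) -> None:
    """Register a user statistic after a grid-dominance self-check: on
    random tables the endpoint maximum must dominate the statistic at every
    interior integer t (the signature of convexity the bound relies on)."""
    rng = np.random.default_rng(seed)
    checked = 0
    while checked < n_checks:
        counts, margins = random_counts_margins(rng)
        if margins.m_cases in (0, counts.n):
            continue
        low, high = feasible_interval(counts, margins)
        vals = [_stat_of(table_at(t, counts, margins), func) for t in range(low, high + 1)]
        endpoint = max(vals[0], vals[-1])
        if any(v > endpoint * (1 + 1e-9) + 1e-9 for v in vals):
            raise ValueError(
                f"statistic {name!r} failed the convexity self-check: "
                "an interior table exceeds the endpoint maximum"
            )
        checked += 1
    _REGISTRY[name] = func


def coe_scan(
    G: GenotypeMatrix, y: PhenotypeVector, theta: float, test: str = "chi2"
) -> ScanResult:
    """Return exactly the pairs whose exact statistic is >= ``theta``."""
    if G.alphabet != BINARY:
        raise ValueError("COE requires binary genotypes")
    if y.kind != BINARY_TRAIT:
        raise ValueError("COE requires a binary trait")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if G.n != y.n:
        raise ValueError("genotype and phenotype sample sizes differ")
    func = get_convex_statistic(test)
    yv = y.values.astype(np.int64)
    m_cases = int(yv.sum())
    n = yv.size
    c1 = G.codes.astype(np.int64) @ yv  # cases with code 1, per SNP
    cut = theta - _SLACK * max(1.0, abs(theta))
    pairs = []
    candidates = 0
    for i in range(G.m - 1):
        xi = G.codes[i]
        index = build_anchor_index(G, i, partners=range(i + 1, G.m))
        ci1 = int(c1[i])
        ci0 = m_cases - ci1
        for (na1, nb1), js in index.entries.items():
            counts = PairGenotypeCounts(
                index.n_a - na1, na1, index.n_b - nb1, nb1
            )
            by_margin: dict[int, list[int]] = {}
            for j in js:
                by_margin.setdefault(int(c1[j]), []).append(j)
            for cj1, jlist in by_margin.items():
                margins = CaseMargins(ci0, ci1, m_cases - cj1, cj1, m_cases)
                bound = convex_upper_bound(counts, margins, test)
                if bound >= cut:
                    candidates += len(jlist)
                    for j in jlist:
                        table = contingency_table(xi, G.codes[j], yv, 2)
                        stat = _stat_of(table, func)
                        if stat >= theta:
                            pairs.append((i, j, stat, table.k))
    total = G.m * (G.m - 1) // 2
    return ScanResult.from_pairs(
        pairs,
        G.snp_ids,
        metadata={
            "engine": "coe",
            "test": test,
            "theta": theta,
            "pairs_total": total,
            "pairs_tested": candidates,
        },
    )
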