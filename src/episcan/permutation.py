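"""Permutation-based error control for two-locus scans.

The null distribution is built by shuffling the phenotype across all
individuals (exchangeability under the global null) and re-scanning.
Family-wise error rate (FWER) control uses the per-permutation maximum
pair statistic: the adjusted p-value of an observed statistic s is the
finite-sample-valid add-one estimator

    p_adj(s) = (1 + #{k : max_k >= s}) / (K + 1),

and a pair is declared significant when p_adj <= alpha.  False discovery
rate (FDR) control — available for TEAM, which records every pair's
statistic — estimates, for a candidate threshold t,

    FDR_hat(t) = min(1, mean_k #{null stats in perm k >= t}
                        / max(1, #{observed >= t})),

with step-up monotone q-values.

For the pruning engines (FastANOVA, COE) the per-permutation maxima are
computed threshold-aware: the first ceil(alpha (K+1)) permutations are
scanned exactly, after which the running ceil(alpha (K+1))-th largest
exact maximum theta is maintained and a permutation whose pruned scan at
theta returns nothing is recorded as *certified below theta* — its exact
value cannot affect any quantile at or above theta, which is all FWER
control needs.  TEAM maxima are always exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import coe, fastanova, team
from .core_data import (
    BINARY,
    BINARY_TRAIT,
    QUANTITATIVE,
    GenotypeMatrix,
    PhenotypeVector,
    ScanResult,
    ScanRow,
)
from .stats import brute_force_scan, check_test_compatible, pair_stats_for_phenotypes

ENGINES = ("fastanova", "coe", "team", "brute")


@dataclass
class PermutationPlan:
    """K phenotype permutations drawn sequentially from one seeded RNG;
    regeneration from (n, K, seed) is bit-identical."""

    n: int
    K: int
    seed: int
    permutations: np.ndarray  # (K, n) index arrays

    def __post_init__(self) -> None:
        expected = np.arange(self.n)
        for perm in self.permutations:
            if not np.array_equal(np.sort(perm), expected):
                raise ValueError("invalid permutation array")


def make_plan(n: int, K: int, seed: int) -> PermutationPlan:
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(K)])
    return PermutationPlan(n=n, K=K, seed=seed, permutations=perms)


def permute_phenotype(y: PhenotypeVector, perm: np.ndarray) -> PhenotypeVector:
    """Reassign values: position s receives ``y.values[perm[s]]``."""
    perm = np.asarray(perm)
    if not np.array_equal(np.sort(perm), np.arange(y.n)):
        raise ValueError("invalid permutation array")
    return PhenotypeVector(y.values[perm], y.kind, y.individual_ids)


@dataclass
class NullMaxima:
    """Per-permutation maximum pair statistics.

    ``exact[k]`` marks values reproducible by brute force on the permuted
    phenotype; non-exact entries are certified below ``threshold[k]`` (the
    pruning threshold in force when permutation k was processed), and
    ``values[k]`` then stores that threshold as a safe upper bound.
    """

    values: np.ndarray
    exact: np.ndarray
    threshold: np.ndarray

    @property
    def K(self) -> int:
        return self.values.size

    def kth_largest_exact(self, rank: int) -> float:
        ev = np.sort(self.values[self.exact])[::-1]
        if rank > ev.size:
            return float("-inf")
        return float(ev[rank - 1])


def _exceed_rank(alpha: float, K: int) -> int:
    """ceil(alpha (K+1)), capped at K: the rank of the critical value."""
    return min(int(math.ceil(alpha * (K + 1) - 1e-12)), K)


def _engine_scan(engine: str, G, y, theta: float, test: str) -> ScanResult:
    if engine == "fastanova":
        return fastanova.fastanova_scan(G, y, theta)
    if engine == "coe":
        return coe.coe_scan(G, y, theta, test)
    raise ValueError(f"unknown pruning engine {engine!r}")


def check_engine_compatible(engine: str, G: GenotypeMatrix, y: PhenotypeVector, test: str) -> None:
    """Enforce the applicability matrix: FastANOVA = quantitative trait +
    binary genotype (ANOVA); COE = binary trait + binary genotype (convex
    tests); TEAM = binary trait, any genotype."""
    if engine == "fastanova":
        if y.kind != QUANTITATIVE or G.alphabet != BINARY:
            raise ValueError(
                "FastANOVA requires a quantitative trait and binary genotypes"
            )
        if test != "anova":
            raise ValueError("FastANOVA supports only the ANOVA test")
    elif engine == "coe":
        if y.kind != BINARY_TRAIT or G.alphabet != BINARY:
            raise ValueError("COE requires binary trait and binary genotype")
        if test == "anova":
            raise ValueError("COE supports convex contingency-table tests only")
    elif engine == "team":
        if y.kind != BINARY_TRAIT:
            raise ValueError("TEAM requires a binary trait")
        if test == "anova":
            raise ValueError("TEAM supports contingency-table tests only")
    elif engine == "brute":
        check_test_compatible(test, y.kind)
    else:
        raise ValueError(f"unknown engine {engine!r}")


def permutation_maxima(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    plan: PermutationPlan,
    engine: str,
    test: str,
    alpha: float | None = None,
) -> NullMaxima:
    """Maximum pair statistic per permutation.

    TEAM and the brute oracle compute every maximum exactly (TEAM via the
    shared-genotype vectorized contingency path, which matches the MST walk
    to floating-point accuracy).  The pruning engines use the running
    threshold protocol described in the module docstring when ``alpha`` is
    given, otherwise all maxima are exact.
    """
    check_engine_compatible(engine, G, y, test)
    K = plan.K
    values = np.empty(K)
    exact = np.ones(K, dtype=bool)
    threshold = np.full(K, float("-inf"))
    if engine == "team":
        Y = y.values[plan.permutations].T.astype(np.int64)  # (n, K)
        stats = pair_stats_for_phenotypes(G, Y, test)
        values[:] = stats.max(axis=0)
        return NullMaxima(values, exact, threshold)
    if engine == "brute":
        for k in range(K):
            res = brute_force_scan(G, permute_phenotype(y, plan.permutations[k]), test)
            values[k] = res.rows[0].statistic
        return NullMaxima(values, exact, threshold)
    # pruning engines
    n_exact_head = K if alpha is None else _exceed_rank(alpha, K)
    exact_seen: list[float] = []
    theta = float("-inf")
    for k in range(K):
        yk = permute_phenotype(y, plan.permutations[k])
        if k < n_exact_head or not math.isfinite(theta):
            res = _engine_scan(engine, G, yk, 0.0, test)
            values[k] = res.rows[0].statistic
            exact_seen.append(values[k])
        else:
            res = _engine_scan(engine, G, yk, theta, test)
            if len(res):
                values[k] = res.rows[0].statistic
                exact_seen.append(values[k])
            else:
                values[k] = theta
                exact[k] = False
                threshold[k] = theta
        if alpha is not None and len(exact_seen) >= n_exact_head:
            theta = sorted(exact_seen, reverse=True)[n_exact_head - 1]
    return NullMaxima(values, exact, threshold)


def fwer_adjusted_pvalues(observed: ScanResult, maxima: NullMaxima) -> ScanResult:
    """Attach add-one FWER-adjusted p-values to every observed row.

    Requires each adjusted statistic to be at or above every certification
    threshold, so certified-below permutations verifiably do not reach it.
    """
    K = maxima.K
    cert = maxima.threshold[~maxima.exact]
    rows = []
    for r in observed.rows:
        s = r.statistic
        if cert.size and (cert > s).any():
            raise ValueError(
                "statistic below certification threshold; increase exactness threshold"
            )
        count = int((maxima.values[maxima.exact] >= s).sum())
        p = (1 + count) / (K + 1)
        rows.append(ScanRow(r.snp_a, r.snp_b, s, r.k, p, "fwer_adjusted_p"))
    meta = dict(observed.metadata)
    meta["K"] = K
    return ScanResult(rows=rows, metadata=meta)


def fdr_threshold(
    observed_stats: np.ndarray, null_stats: np.ndarray, q: float
) -> tuple[float | None, np.ndarray]:
    """Permutation FDR over the grid of observed statistics.

    ``null_stats`` is (P, K): all pair statistics for each permutation.
    Returns the smallest observed threshold t* with FDR_hat(t*) <= q (None
    if no threshold qualifies) and the step-up q-value of every observed
    statistic (min of FDR_hat over thresholds at or below it).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    observed_stats = np.asarray(observed_stats, dtype=float)
    K = null_stats.shape[1]
    pooled = np.sort(null_stats.ravel())
    grid = np.unique(observed_stats)  # ascending candidate thresholds
    null_ge = pooled.size - np.searchsorted(pooled, grid, side="left")
    obs_sorted = np.sort(observed_stats)
    obs_ge = observed_stats.size - np.searchsorted(obs_sorted, grid, side="left")
    fdr_hat = np.minimum(1.0, (null_ge / K) / np.maximum(1, obs_ge))
    qvals_grid = np.minimum.accumulate(fdr_hat)  # step-up from below
    ok = qvals_grid <= q
    t_star = float(grid[np.argmax(ok)]) if ok.any() else None
    pos = np.searchsorted(grid, observed_stats, side="left")
    return t_star, qvals_grid[pos]


def scan_with_error_control(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    engine: str,
    test: str,
    K: int,
    seed: int,
    alpha: float | None = None,
    fdr: float | None = None,
) -> ScanResult:
    """Full pipeline: permutation null, observed scan, significant pairs.

    Exactly one of ``alpha`` (FWER level) and ``fdr`` (target FDR, TEAM
    only) must be given.  The returned result holds only the significant
    pairs, with metadata recording engine, test, K, seed and the level.
    """
    if (alpha is None) == (fdr is None):
        raise ValueError("exactly one of alpha and fdr must be set")
    if fdr is not None and engine != "team":
        raise ValueError("FDR control is available only with TEAM")
    check_engine_compatible(engine, G, y, test)
    if G.n != y.n:
        raise ValueError("genotype and phenotype sample sizes differ")
    plan = make_plan(G.n, K, seed)
    meta = {
        "engine": engine,
        "test": test,
        "K": K,
        "seed": seed,
        "m": G.m,
        "n": G.n,
    }
    if alpha is not None:
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        maxima = permutation_maxima(G, y, plan, engine, test, alpha=alpha)
        rank = _exceed_rank(alpha, K)
        f_alpha = maxima.kth_largest_exact(rank)
        if engine == "team":
            observed = team.team_scan(G, y, test)
            observed.rows = [r for r in observed.rows if r.statistic >= f_alpha]
        elif engine == "brute":
            observed = brute_force_scan(G, y, test)
            observed.rows = [r for r in observed.rows if r.statistic >= f_alpha]
        else:
            observed = _engine_scan(engine, G, y, max(f_alpha, 0.0), test)
        adjusted = fwer_adjusted_pvalues(observed, maxima)
        adjusted.rows = [r for r in adjusted.rows if r.significance <= alpha]
        meta["alpha"] = alpha
        meta["critical_value"] = "%.10g" % f_alpha
        adjusted.metadata = {**meta, **{
            k: v for k, v in observed.metadata.items() if k in ("pairs_tested", "pairs_total")
        }}
        return adjusted
    # FDR path (team)
    observed = team.team_scan(G, y, test)
    Y = y.values[plan.permutations].T.astype(np.int64)
    null_stats = pair_stats_for_phenotypes(G, Y, test)
    obs_stats = np.array([r.statistic for r in observed.rows])
    t_star, qvals = fdr_threshold(obs_stats, null_stats, fdr)
    rows = []
    for r, qv in zip(observed.rows, qvals):
        if t_star is not None and r.statistic >= t_star:
            rows.append(ScanRow(r.snp_a, r.snp_b, r.statistic, r.k, float(qv), "fdr_q"))
    meta["fdr"] = fdr
    meta["threshold"] = "NA" if t_star is None else "%.10g" % t_star
    return ScanResult(rows=rows, metadata=meta)
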