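# Methods

## Problem setting

Given m SNPs over n individuals (complete genotypes, coded {0,1} for
homozygous designs or {0,1,2} additively for human panels) and one
phenotype (quantitative or binary case/control), the task is to score every
unordered SNP pair for association between the phenotype and the pair's
joint genotype, and to report the pairs that survive permutation-based
multiple-testing control. The package's defining contract is *exhaustive
exactness*: every pruning engine must return exactly the set of pairs a
direct all-pairs scan returns above the working threshold, with identical
statistics. All engine-vs-oracle guarantees in the test suite are stated at
1e-9 relative tolerance.

## Test statistics and degenerate-case conventions

Quantitative traits use one-way ANOVA over the non-empty joint-genotype
groups; binary traits use Pearson χ², the likelihood-ratio G statistic
(natural log, so its asymptotics are the usual χ² ones), or mutual
information in nats, on the 2×k case/control-by-group table with empty
groups dropped. G = 2·N·MI holds identically and is enforced as a test.

The permutation machinery needs a total order on pair scores, so degenerate
cases get fixed conventions rather than errors at scan level:

* F = +inf when SS_within = 0 with SS_between > 0 (perfect separation —
  such pairs genuinely dominate any finite score);
* F = 0 when SS_between = 0;
* pairs whose test is undefined (k < 2 groups; for ANOVA also n ≤ k) score
  0 and keep their k, so all engines and the oracle agree on row counts.

Ties at a threshold are kept (≥, not >). Result rows sort by statistic
descending with index-order tie-breaks, making output files deterministic.

## FastANOVA: entry-wise upper bound

For anchor SNP i, individuals split into A = {Xi=0}, B = {Xi=1}. Pairing
with j refines each side by Xj, and

SS_B(i,j) = SS_B(i) + gain_A + gain_B, where splitting a group of size
n_g and phenotype sum T_g into a subgroup of size n_1 with sum T_1 yields
gain = (n_g·T_1 − n_1·T_g)² / (n_g·n_1·(n_g−n_1)).

The gain is a convex quadratic in T_1, and T_1 — a sum of n_1 of the
group's values — lies between the prefix sums of the n_1 smallest and n_1
largest values. Evaluating at those extremes bounds the gain. The subgroup
sizes (n_A1, n_B1) depend only on genotypes, so partners are indexed by
that key in a 2-D array built once per dataset (at most
(n_A+1)(n_B+1) entries) and reused for every permutation; everything
phenotype-dependent (sorted prefix sums, single-locus SS) refreshes in
O(n log n) per anchor per permutation. All partners in an entry share one
bound, and the entry key also fixes exactly which joint cells are empty,
so the F bound uses the entry's true k rather than a worst case.

A bound-vs-threshold comparison carries a 1e-9 relative slack: the bound
and the exact statistic travel different floating-point routes, and a pair
whose exact F equals the threshold must never be lost to rounding. The
slack can only admit extra candidates (they are then tested exactly), never
drop one.

## COE: vertex bound on the feasible table interval

With binary genotypes and a binary trait, fixing the four joint cell sizes
(genotype-only, recovered from the FastANOVA index key) and the single-locus
case margins leaves one free integer t = cases in cell (0,0); feasibility
of all eight cells gives an interval [L, U] containing the true t. The
statistics above are convex in t, so max(stat(L), stat(U)) bounds the true
table's statistic. Margins refresh in O(m) per permutation. The registry
accepts user statistics declared convex but validates each at registration
by grid enumeration (endpoint max must dominate every interior t on 100
random tables) — convexity is enforced empirically, not assumed.

Candidates are bounded per (entry × partner case margin); this makes the
bound per-pair-cheap rather than per-group-cheap, which is acceptable at
the small sample sizes this engine targets, and keeps the implementation
transparent.

## TEAM: MST-incremental exact tables

A minimum spanning tree over SNPs with Hamming-distance weights is built
once per dataset by Prim's algorithm (O(m²) with the full distance matrix;
ties broken deterministically by smallest (min endpoint, max endpoint), so
rebuilds are bit-identical). Each tree edge stores the diff list of
individuals where its endpoints differ. Per anchor, the joint table against
the root costs one O(n) count; a depth-first walk then moves the table
along each edge by touching only the differing individuals, and reverses
the diff on backtrack — n + 2·(tree weight) individual touches per anchor,
verified by an instrumentation counter. Every pair's statistic is exact and
recorded, which is what makes FDR (not just FWER) estimable.

Across permutations the per-dataset structures (tree, diff lists) are
reused; the permutation null itself is computed by a vectorized
shared-genotype contingency path that evaluates all pairs for a whole block
of permuted phenotypes at once and is tested equal to the MST walk
per phenotype. Re-deriving each permutation's statistics from the shared
genotype masks keeps the dense null affordable without giving up exactness.

## Permutation error control

Permutations shuffle the phenotype across all individuals (exchangeability
under the global null; no stratification). K index arrays are drawn
sequentially from one seeded PCG64 generator, so a plan regenerates
bit-identically from (n, K, seed).

* **FWER** — add-one estimator p_adj(s) = (1 + #{maxima ≥ s}) / (K+1),
  finite-sample valid; significant set = {p_adj ≤ α}.
* **Threshold-aware maxima for pruning engines** — the first
  E = ⌈α(K+1)⌉ permutations are scanned exactly; afterwards θ tracks the
  E-th largest exact maximum (non-decreasing), and a permutation whose
  pruned scan at θ returns nothing is recorded as *certified below θ*.
  Since every certified value lies below every later θ, the E-th largest
  overall equals the E-th largest exact value, and adjusted p-values of
  reported pairs (all ≥ the critical value) are unaffected — a property the
  suite checks against per-permutation brute force.
* **FDR (TEAM)** — FDR̂(t) = min(1, mean_k #{null ≥ t} / max(1, #{obs ≥ t}))
  on the grid of observed statistics, q-values forced monotone by a
  step-up minimum from below; the reporting threshold is the smallest
  observed statistic with FDR̂ ≤ q.

## Synthetic data

The generator draws SNP 0 i.i.d. (binary: Bernoulli(maf); triallelic:
Hardy–Weinberg class probabilities), and each subsequent SNP copies its
predecessor per individual with probability `ld_rho`, else redraws — a
Markov chain whose adjacent expected Hamming distance is (1−ld_rho) times
the independent value, chosen over haplotype-block models for analytic
tractability. Monomorphic rows are redrawn (≤100 attempts).

Planted interactions are single-cell indicators: the effect applies only to
individuals whose planted pair lies in one target joint cell, keeping
marginal effects weak while the pairwise signal is strong — the scenario
that motivates exhaustive pair scans in the first place. Quantitative
traits add N(0, σ²) noise; binary traits are Bernoulli with logistic link,
the intercept solved (Brent) so the expected case fraction is 0.5.

Reference scenarios fix the study conditions used by the recovery checks:
m=20, n=200 binary SNPs with effect 2σ (quantitative), and m=20, n=500
triallelic SNPs with logistic effect 2.0, both targeting cell (1,1) at
maf 0.5. m=20 is a deliberate small-panel choice: large enough for 190
competing pairs, small enough that all-pairs Monte-Carlo replication stays
cheap. The (1,1) cell at maf 0.5 has frequency ≈ 0.25, which keeps the
joint-cell information high relative to the marginals; a rare double-
homozygote target would need larger effects or samples for comparable
power. What the generator does *not* emulate: realistic coalescent LD,
population structure, ascertainment, missingness — so passing recovery and
calibration tests demonstrates correctness of the machinery under clean
exchangeable nulls, not field performance on structured cohorts.

## Problem sizes and numerical choices

The suite's oracle-equivalence checks run 100 instances per engine with
m up to 22 (FastANOVA/COE, n ≤ 60) or 18 (TEAM, n ≤ 200, both alphabets),
thresholds at the 60th percentile of the true statistic distribution; bound
soundness and vertex dominance use ≥1000 random draws each; FWER
calibration runs the full TEAM pipeline on 500 pure-null datasets (m=20,
n=50, K=200, α=0.05) and expects the empirical rate inside the binomial
95% band [0.031, 0.069] around the procedure's exact level 10/201 ≈ 0.0498.
These sizes keep the whole suite under a minute while exercising every
code path at meaningful scale.

Floating-point policy: statistics are compared engine-to-oracle at 1e-9
relative; SS quantities are clamped to [0, SS_total] before the F
conventions apply; bound comparisons carry the 1e-9 pruning slack described
above. Missing genotypes are rejected outright (imputation would silently
change every downstream count).

## Known limitations

* COE bounds are evaluated per partner margin rather than amortized over
  margin-sharing groups; its constant factors matter only beyond the small-
  sample regime it is specified for.
* The per-permutation maxima for pruning engines re-run the engine per
  permutation rather than batching permutations; exactness is identical,
  speed is not the contract.
* FDR q-values are permutation plug-in estimates without finite-sample
  conservativeness guarantees (unlike the add-one FWER p-values).
* Covariates, missing data, dosage genotypes and stratified permutation
  schemes are out of scope.
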