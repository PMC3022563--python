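"""Shared data model and file I/O for two-locus epistasis scans.

The scan engines all operate on a SNP-major genotype matrix (small integer
codes, no missing values) and a per-individual phenotype vector, either
quantitative (ANOVA setting) or binary case/control (contingency-table
setting).  Results are flat tables of SNP pairs with their test statistic
and, after permutation error control, an adjusted significance level.

Conventions
-----------
* genotype codes: ``binary`` alphabet {0, 1} (homozygous designs) or
  ``triallelic`` {0, 1, 2} (human-style additive coding);
* binary phenotype classes: 0 = control, 1 = case;
* all internal indexing is 0-based; a pair (i, j) is always stored with
  ``i < j`` in matrix order;
* missing genotypes are rejected, never imputed — every engine assumes
  complete contingency tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

BINARY = "binary"
TRIALLELIC = "triallelic"
ALPHABET_CARD = {BINARY: 2, TRIALLELIC: 3}

QUANTITATIVE = "quantitative"
BINARY_TRAIT = "binary"


class DataError(ValueError):
    """Raised for malformed genotype/phenotype inputs."""


@dataclass
class GenotypeMatrix:
    """SNP-major genotype matrix: ``codes[i, s]`` is SNP *i* of individual *s*.

    Parameters
    ----------
    codes
        ``(m, n)`` integer array, values within the declared alphabet.
    snp_ids
        ``m`` unique SNP identifiers.
    individual_ids
        ``n`` unique individual identifiers.
    alphabet
        ``"binary"`` ({0,1}) or ``"triallelic"`` ({0,1,2}).
    """

    codes: np.ndarray
    snp_ids: list[str]
    individual_ids: list[str]
    alphabet: str

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.individual_ids = [str(s) for s in self.individual_ids]
        if self.alphabet not in ALPHABET_CARD:
            raise DataError(f"unknown alphabet {self.alphabet!r}")
        if self.codes.ndim != 2:
            raise DataError("genotype codes must be a 2-D matrix")
        m, n = self.codes.shape
        if m < 2 or n < 2:
            raise DataError("need at least 2 SNPs and 2 individuals")
        if len(self.snp_ids) != m:
            raise DataError("snp_ids length does not match matrix")
        if len(self.individual_ids) != n:
            raise DataError("individual_ids length does not match matrix")
        if len(set(self.snp_ids)) != m:
            raise DataError("duplicate SNP id")
        if len(set(self.individual_ids)) != n:
            raise DataError("duplicate individual id")
        card = ALPHABET_CARD[self.alphabet]
        if self.codes.min() < 0 or self.codes.max() >= card:
            raise DataError(
                f"genotype code outside alphabet {self.alphabet!r}"
            )

    @property
    def m(self) -> int:
        return self.codes.shape[0]

    @property
    def n(self) -> int:
        return self.codes.shape[1]

    @property
    def card(self) -> int:
        return ALPHABET_CARD[self.alphabet]


@dataclass
class PhenotypeVector:
    """Per-individual trait values, quantitative or binary (0/1)."""

    values: np.ndarray
    kind: str
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = [str(s) for s in self.individual_ids]
        if self.values.ndim != 1:
            raise DataError("phenotype values must be 1-D")
        if len(self.individual_ids) != self.values.size:
            raise DataError("individual_ids length does not match values")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise DataError("duplicate individual id in phenotype")
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite phenotype value")
        if self.kind == BINARY_TRAIT:
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                raise DataError("binary phenotype values must be 0/1")
            if len(np.unique(self.values)) < 2:
                raise DataError("phenotype has a single class")
        elif self.kind == QUANTITATIVE:
            if float(np.var(self.values)) == 0.0:
                raise DataError("quantitative phenotype has zero variance")
        else:
            raise DataError(f"unknown phenotype kind {self.kind!r}")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ScanRow:
    snp_a: str
    snp_b: str
    statistic: float
    k: int
    significance: float | None = None
    significance_kind: str = "none"


@dataclass
class ScanResult:
    """Ordered table of SNP-pair statistics.

    Rows are sorted by statistic descending, ties broken by pair index
    order (so output is deterministic); each unordered pair appears at
    most once, with ``snp_a`` preceding ``snp_b`` in matrix order.
    """

    rows: list[ScanRow]
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple],
        snp_ids: Sequence[str],
        metadata: dict | None = None,
    ) -> "ScanResult":
        """Build a sorted result from ``(i, j, statistic, k)`` tuples."""
        ordered = sorted(pairs, key=lambda p: (-p[2], p[0], p[1]))
        rows = [
            ScanRow(snp_ids[i], snp_ids[j], float(stat), int(k))
            for i, j, stat, k in ordered
        ]
        return cls(rows=rows, metadata=dict(metadata or {}))

    def __len__(self) -> int:
        return len(self.rows)

    def pair_set(self) -> set[tuple[str, str]]:
        return {(r.snp_a, r.snp_b) for r in self.rows}


def _fmt(x: float) -> str:
    return "%.10g" % x


def write_results(result: ScanResult, path) -> None:
    """Write a results TSV: ``# key=value`` metadata lines, a header, rows.

    Statistics are printed with 10 significant digits; ``+inf`` prints as
    ``inf``; unset significance prints as ``NA``.
    """
    with open(path, "w") as fh:
        for key, val in result.metadata.items():
            fh.write(f"# {key}={val}\n")
        fh.write("snp_a\tsnp_b\tstatistic\tk\tsignificance\tsignificance_kind\n")
        for r in result.rows:
            sig = "NA" if r.significance is None else _fmt(r.significance)
            fh.write(
                f"{r.snp_a}\t{r.snp_b}\t{_fmt(r.statistic)}\t{r.k}\t{sig}\t"
                f"{r.significance_kind}\n"
            )


def read_results(path) -> ScanResult:
    """Parse a file written by :func:`write_results` (round-trip exact)."""
    metadata: dict = {}
    rows: list[ScanRow] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith("# "):
            key, _, val = line[2:].partition("=")
            metadata[key] = val
        elif line:
            body.append(line)
    header = body[0].split("\t")
    expected = ["snp_a", "snp_b", "statistic", "k", "significance", "significance_kind"]
    if header != expected:
        raise DataError(f"unexpected results header {header}")
    for line in body[1:]:
        a, b, stat, k, sig, kind = line.split("\t")
        rows.append(
            ScanRow(
                a,
                b,
                float(stat),
                int(k),
                None if sig == "NA" else float(sig),
                kind,
            )
        )
    return ScanResult(rows=rows, metadata=metadata)


# ---------------------------------------------------------------------------
# genotype / phenotype file I/O
# ---------------------------------------------------------------------------

_VALID_CODES = {"0", "1", "2"}


def _infer_alphabet(codes: np.ndarray, override: str | None) -> str:
    if override is not None:
        return override
    return TRIALLELIC if (codes == 2).any() else BINARY


def read_genotypes(path, format: str = "tsv", alphabet: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix.

    ``tsv``: native SNP-major table — header ``snp_id`` then individual ids,
    one row per SNP, cells in {0,1,2}, tab-separated.

    ``plink_raw``: PLINK ``--recode A`` text — whitespace-separated,
    header ``FID IID PAT MAT SEX PHENOTYPE`` then one column per SNP with
    additive 0/1/2 coding; transposed to SNP-major on read.  The PHENOTYPE
    column is ignored (the phenotype comes from its own file).

    Missing genotypes (``NA`` or empty cells) are rejected with a count of
    offending cells; the scan engines require complete tables.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path, alphabet)
    if format == "plink_raw":
        return _read_genotypes_plink_raw(path, alphabet)
    raise DataError(f"unknown genotype format {format!r}")


def _parse_code_table(rows: list[list[str]], what: str) -> np.ndarray:
    n_bad = sum(1 for row in rows for cell in row if cell not in _VALID_CODES)
    if n_bad:
        raise DataError(
            f"missing genotype not supported: {n_bad} cell(s) in {what} are "
            "not in {0,1,2}"
        )
    return np.array([[int(c) for c in row] for row in rows], dtype=np.int8)


def _read_genotypes_tsv(path, alphabet: str | None) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    if header[0] != "snp_id":
        raise DataError("genotype TSV must start with an 'snp_id' header column")
    individual_ids = header[1:]
    snp_ids, rows = [], []
    width = len(individual_ids)
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != width + 1:
            raise DataError(f"ragged genotype row for {parts[0]!r}")
        snp_ids.append(parts[0])
        rows.append(parts[1:])
    codes = _parse_code_table(rows, "genotype TSV")
    return GenotypeMatrix(codes, snp_ids, individual_ids, _infer_alphabet(codes, alphabet))


def _read_genotypes_plink_raw(path, alphabet: str | None) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    header = lines[0]
    fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if header[: len(fixed)] != fixed:
        raise DataError("not a PLINK .raw header")
    snp_ids = header[len(fixed):]
    individual_ids, rows = [], []
    for parts in lines[1:]:
        if len(parts) != len(fixed) + len(snp_ids):
            raise DataError("ragged PLINK .raw row")
        individual_ids.append(parts[1])
        rows.append(parts[len(fixed):])
    # individual-major on disk; transpose to SNP-major
    codes = _parse_code_table(rows, "PLINK .raw").T
    return GenotypeMatrix(codes, snp_ids, individual_ids, _infer_alphabet(codes, alphabet))


def write_genotypes(G: GenotypeMatrix, path) -> None:
    """Write the native SNP-major genotype TSV."""
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(G.individual_ids) + "\n")
        for i, sid in enumerate(G.snp_ids):
            fh.write(sid + "\t" + "\t".join(str(int(c)) for c in G.codes[i]) + "\n")


def read_phenotype(path, kind: str | None = None) -> PhenotypeVector:
    """Read a two-column (individual_id, value) TSV; header optional.

    The trait kind is inferred binary iff every value is 0 or 1,
    quantitative otherwise; pass ``kind`` to override.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    records = [ln.split("\t") for ln in lines]
    if any(len(r) != 2 for r in records):
        raise DataError("phenotype TSV must have exactly two columns")
    # header detection: second field of the first row not numeric
    try:
        float(records[0][1])
    except ValueError:
        records = records[1:]
    ids, values = [], []
    for rid, raw in records:
        try:
            values.append(float(raw))
        except ValueError:
            raise DataError(f"non-numeric phenotype value {raw!r} for {rid!r}")
        ids.append(rid)
    arr = np.array(values, dtype=float)
    if kind is None:
        kind = BINARY_TRAIT if np.all(np.isin(arr, (0.0, 1.0))) else QUANTITATIVE
    return PhenotypeVector(arr, kind, ids)


def write_phenotype(y: PhenotypeVector, path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tvalue\n")
        for rid, val in zip(y.individual_ids, y.values):
            if y.kind == BINARY_TRAIT:
                fh.write(f"{rid}\t{int(val)}\n")
            else:
                fh.write(f"{rid}\t{_fmt(val)}\n")


def align_samples(
    G: GenotypeMatrix, y: PhenotypeVector
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Reorder both inputs to the id intersection, in genotype-file order.

    Ids present in only one file are dropped with a warning; fewer than two
    common individuals is an error.  Idempotent on already-aligned inputs.
    """
    pheno_pos = {rid: s for s, rid in enumerate(y.individual_ids)}
    keep = [s for s, rid in enumerate(G.individual_ids) if rid in pheno_pos]
    common_ids = [G.individual_ids[s] for s in keep]
    dropped = (len(G.individual_ids) - len(keep)) + (len(y.individual_ids) - len(keep))
    if dropped:
        warnings.warn(
            f"dropping {dropped} individual(s) present in only one input",
            stacklevel=2,
        )
    if len(keep) < 2:
        raise DataError("fewer than 2 individuals shared by genotype and phenotype")
    if common_ids == G.individual_ids and common_ids == y.individual_ids:
        return G, y
    G2 = GenotypeMatrix(G.codes[:, keep], G.snp_ids, common_ids, G.alphabet)
    order = [pheno_pos[rid] for rid in common_ids]
    y2 = PhenotypeVector(y.values[order], y.kind, common_ids)
    return G2, y2
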