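"""Synthetic genotype/phenotype generator with planted two-locus effects.

Genotypes: SNP 0 is drawn i.i.d. per individual (binary: Bernoulli(maf);
triallelic: Hardy-Weinberg class probabilities from the minor-allele
frequency); each later SNP copies its predecessor's code per individual
with probability ``ld_rho`` and redraws otherwise, giving a Markov chain
of neighbor LD whose expected adjacent Hamming distance is
``(1 - ld_rho)`` times that of an independent pair.  Monomorphic rows are
redrawn (at most 100 attempts).

Planted interactions are single-cell indicators — the effect acts only on
individuals whose planted pair sits in one target joint-genotype cell —
so marginal single-SNP effects stay weak while the two-locus signal is
strong, the scenario exhaustive pair scans exist for.  Quantitative traits
add Gaussian noise to the indicator effect; binary traits draw cases from
a logistic model whose intercept is solved so the expected case fraction
is one half.

Two ready-made scenario constructors encode the package's reference study
conditions: a homozygous-design quantitative panel (m=20 binary SNPs,
n=200, effect = 2 noise SD) and a human-style case/control panel (m=20
triallelic SNPs, n=500, logistic effect 2.0), both planting the effect in
the (1, 1) joint cell at maf 0.5.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .core_data import (
    BINARY,
    BINARY_TRAIT,
    QUANTITATIVE,
    TRIALLELIC,
    GenotypeMatrix,
    PhenotypeVector,
)


@dataclass
class PlantedEffect:
    """A pure-epistasis effect on one joint-genotype cell of one pair."""

    i: int
    j: int
    cell: tuple[int, int]  # (code of SNP i, code of SNP j)
    effect_size: float
    model: str  # "quantitative" | "logistic"


@dataclass
class SimConfig:
    m: int = 20
    n: int = 200
    alphabet: str = BINARY
    maf_range: tuple[float, float] = (0.5, 0.5)
    ld_rho: float = 0.0
    planted: PlantedEffect | None = None
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if self.planted is not None:
            p = self.planted
            if p.i == p.j:
                raise ValueError("planted pair must be two distinct SNPs")
            if not (0 <= p.i < self.m and 0 <= p.j < self.m):
                raise ValueError("planted pair indices out of range")
            if not np.isfinite(p.effect_size):
                raise ValueError("effect_size must be finite")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)


def quantitative_scenario(seed: int, effect_size: float | None = None) -> SimConfig:
    """Homozygous-design reference scenario: binary genotypes, n=200,
    planted quantitative effect of two noise SDs in the (1,1) cell."""
    return SimConfig(
        m=20,
        n=200,
        alphabet=BINARY,
        maf_range=(0.5, 0.5),
        planted=PlantedEffect(2, 11, (1, 1), 2.0 if effect_size is None else effect_size,
                              "quantitative"),
        noise_sigma=1.0,
        seed=seed,
    )


def binary_scenario(seed: int, effect_size: float | None = None) -> SimConfig:
    """Human-style reference scenario: triallelic genotypes, n=500,
    planted logistic effect 2.0 in the het-het (1,1) cell."""
    return SimConfig(
        m=20,
        n=500,
        alphabet=TRIALLELIC,
        maf_range=(0.5, 0.5),
        planted=PlantedEffect(2, 11, (1, 1), 2.0 if effect_size is None else effect_size,
                              "logistic"),
        noise_sigma=1.0,
        seed=seed,
    )


def _draw_row(rng: np.random.Generator, n: int, maf: float, alphabet: str) -> np.ndarray:
    if alphabet == BINARY:
        return (rng.random(n) < maf).astype(np.int8)
    q = maf
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
    return rng.choice(3, size=n, p=probs).astype(np.int8)


def generate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    rng = np.random.default_rng([cfg.seed, 0])
    lo, hi = cfg.maf_range
    rows = []
    prev = None
    for i in range(cfg.m):
        for attempt in range(100):
            maf = float(rng.uniform(lo, hi))
            fresh = _draw_row(rng, cfg.n, maf, cfg.alphabet)
            if prev is not None and cfg.ld_rho > 0:
                copy = rng.random(cfg.n) < cfg.ld_rho
                row = np.where(copy, prev, fresh).astype(np.int8)
            else:
                row = fresh
            if np.unique(row).size > 1:
                break
        else:
            raise RuntimeError(f"SNP {i} monomorphic after 100 redraws")
        rows.append(row)
        prev = row
    snp_ids = [f"snp{i}" for i in range(cfg.m)]
    ind_ids = [f"ind{s}" for s in range(cfg.n)]
    return GenotypeMatrix(np.vstack(rows), snp_ids, ind_ids, cfg.alphabet)


def _cell_indicator(G: GenotypeMatrix, planted: PlantedEffect) -> np.ndarray:
    a, b = planted.cell
    return ((G.codes[planted.i] == a) & (G.codes[planted.j] == b)).astype(float)


def plant_quantitative_trait(G: GenotypeMatrix, cfg: SimConfig) -> PhenotypeVector:
    """y = effect * 1[planted cell] + Gaussian noise (pure noise when no
    effect is planted)."""
    rng = np.random.default_rng([cfg.seed, 1])
    y = rng.normal(0.0, cfg.noise_sigma, size=cfg.n)
    if cfg.planted is not None:
        y = y + cfg.planted.effect_size * _cell_indicator(G, cfg.planted)
    return PhenotypeVector(y, QUANTITATIVE, G.individual_ids)


def plant_binary_trait(G: GenotypeMatrix, cfg: SimConfig) -> PhenotypeVector:
    """Logistic case/control labels with intercept solved so the expected
    case fraction is 0.5; redrawn (<=100 times) if a class comes up empty."""
    rng = np.random.default_rng([cfg.seed, 2])
    if cfg.planted is not None:
        ind = cfg.planted.effect_size * _cell_indicator(G, cfg.planted)
    else:
        ind = np.zeros(cfg.n)
    if np.ptp(ind) == 0:
        beta0 = -float(ind[0])
    else:
        beta0 = float(
            brentq(lambda b: expit(b + ind).mean() - 0.5, -50.0, 50.0)
        )
    p_case = expit(beta0 + ind)
    for _ in range(100):
        y = (rng.random(cfg.n) < p_case).astype(float)
        if 0 < y.sum() < cfg.n:
            return PhenotypeVector(y, BINARY_TRAIT, G.individual_ids)
    raise RuntimeError("binary trait single-class after 100 redraws")


def generate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Genotypes plus the trait implied by the planted model (quantitative
    when no effect is planted and the config's model is unspecified)."""
    G = generate_genotypes(cfg)
    if cfg.planted is not None and cfg.planted.model == "logistic":
        return G, plant_binary_trait(G, cfg)
    if cfg.planted is not None and cfg.planted.model == "quantitative":
        return G, plant_quantitative_trait(G, cfg)
    return G, plant_quantitative_trait(G, cfg)


def null_binary_dataset(
    seed: int, m: int, n: int, alphabet: str = BINARY
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Phenotype independent of every genotype — for calibration tests."""
    cfg = SimConfig(m=m, n=n, alphabet=alphabet, maf_range=(0.2, 0.5), seed=seed)
    G = generate_genotypes(cfg)
    return G, plant_binary_trait(G, cfg)


def null_quantitative_dataset(
    seed: int, m: int, n: int, alphabet: str = BINARY
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    cfg = SimConfig(m=m, n=n, alphabet=alphabet, maf_range=(0.2, 0.5), seed=seed)
    G = generate_genotypes(cfg)
    return G, plant_quantitative_trait(G, cfg)
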