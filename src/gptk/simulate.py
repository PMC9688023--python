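"""Synthetic genotype panels and additive quantitative traits.

The generator mirrors the structure of the public multi-generation benchmark
panel used to compare genomic-prediction methods: a multi-chromosome biallelic
SNP panel (default five chromosomes carrying 10,000 SNPs), 4,000 individuals
of which the first 3,000 form the reference population and the remaining
1,000 the validation population, and continuous traits with a controlled
narrow-sense heritability.

Genotypes are independent loci drawn binomial(2, p) at a per-marker allele
frequency sampled uniformly from ``maf_range`` (no linkage; none of the
implemented predictors requires LD to be exercised).  Traits are strictly
additive: a random subset of markers act as QTL with standard-normal effects,
and Gaussian environmental noise is scaled so the expected ratio of genetic
to phenotypic variance equals the requested heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .genotype_io import GenotypeMatrix, Marker, PhenotypeTable

__all__ = [
    "SimConfig",
    "TrueGeneticValues",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "reference_validation_split",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset (defaults mirror the benchmark panel)."""

    n_individuals: int = 4000
    n_markers: int = 10_000
    n_chromosomes: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 100
    heritability: float = 0.45
    n_reference: int = 3000
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if not 0 <= self.heritability <= 1:
            raise ConfigError("heritability must lie in [0, 1]")
        if self.n_qtl > self.n_markers:
            raise ConfigError("n_qtl exceeds n_markers")
        if self.n_qtl < 1 and self.heritability > 0:
            raise ConfigError("a heritable trait needs at least one QTL")
        if not 0 < self.n_reference < self.n_individuals:
            raise ConfigError("n_reference must be in (0, n_individuals)")
        if self.n_chromosomes < 1 or self.n_markers < self.n_chromosomes:
            raise ConfigError("need at least one marker per chromosome")


@dataclass
class TrueGeneticValues:
    """Ground truth of one simulated trait, for parameter-recovery checks."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    genetic_values: np.ndarray
    realized_h2: float


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw an independent-locus genotype panel, deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    dosages = rng.binomial(2, p, size=(cfg.n_individuals, cfg.n_markers)).astype(float)
    # markers spread as evenly as possible over chromosomes, in order
    chrom_of = np.array_split(np.arange(cfg.n_markers), cfg.n_chromosomes)
    markers = []
    for c, idx in enumerate(chrom_of, start=1):
        for k, j in enumerate(idx, start=1):
            markers.append(Marker(id=f"snp{j + 1}", chrom=str(c), pos=k, a1="A", a2="B"))
    sample_ids = [f"ind{i + 1}" for i in range(cfg.n_individuals)]
    return GenotypeMatrix(dosages, sample_ids, markers)


def simulate_phenotypes(
    g: GenotypeMatrix, cfg: SimConfig
) -> tuple[PhenotypeTable, TrueGeneticValues]:
    """Overlay an additive trait with heritability ``cfg.heritability`` on ``g``.

    Uses a generator seeded at ``cfg.seed + 1`` so the trait can be re-drawn
    on a fixed panel by varying the seed.  Noise variance is set from the
    realized genetic variance of the sample, so the ratio equals the target
    heritability exactly in expectation.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = g.n_individuals
    if cfg.heritability == 0 and cfg.n_qtl == 0:
        qtl = np.empty(0, dtype=int)
        effects = np.empty(0)
        gv = np.zeros(n)
    else:
        qtl = np.sort(rng.choice(g.n_markers, size=cfg.n_qtl, replace=False))
        effects = rng.standard_normal(cfg.n_qtl)
        X = g.dosages[:, qtl]
        gv = (X - X.mean(axis=0)) @ effects
    var_g = float(np.var(gv))
    h2 = cfg.heritability
    if h2 >= 1.0:
        noise = np.zeros(n)
    elif var_g == 0.0:
        if h2 > 0:
            raise ConfigError("cannot reach positive heritability with zero genetic variance")
        noise = rng.standard_normal(n)
    else:
        var_e = var_g * (1 - h2) / h2 if h2 > 0 else 1.0
        noise = rng.standard_normal(n) * np.sqrt(var_e)
    if h2 == 0:
        # a null trait: pure noise, genetic values untouched for diagnostics
        y = noise if var_g == 0 else rng.standard_normal(n)
    else:
        y = gv + noise
    var_y = float(np.var(y))
    realized = var_g / var_y if var_y > 0 else 0.0
    if h2 == 0:
        realized = 0.0
    table = PhenotypeTable(list(g.sample_ids), {"trait": y})
    return table, TrueGeneticValues(qtl, effects, gv, realized)


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable, TrueGeneticValues]:
    """Convenience wrapper: genotypes plus one trait from a single config."""
    g = simulate_genotypes(cfg)
    y, truth = simulate_phenotypes(g, cfg)
    return g, y, truth


def reference_validation_split(
    g: GenotypeMatrix, cfg: SimConfig
) -> tuple[list[str], list[str]]:
    """Generation-ordered split: first ``n_reference`` ids train, the rest validate."""
    if not cfg.n_reference < g.n_individuals:
        raise ConfigError("n_reference must be smaller than the panel")
    ids = list(g.sample_ids)
    return ids[: cfg.n_reference], ids[cfg.n_reference :]
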