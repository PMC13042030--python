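"""Synthetic inputs with the statistical structure the analyses assume.

Everything the pipeline consumes can be generated here: individual-level
cohorts with additive quantitative phenotypes (for the binarization and
downsampling experiments), marginal GWAS score tests standing in for an
external association pipeline, cell-type enrichment p-value matrices with
planted CNS signal, and gene-level burden tables with a stated coupling
between constraint (shet) and squared genic effects. Every generator is
seed-deterministic and returns its ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .classify import CELL_TYPE_CATEGORIES, EnrichmentMatrix


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for an individual-level cohort with an additive phenotype."""

    n_individuals: int
    n_variants: int
    heritability: float
    maf: Sequence[float] | tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least two individuals")
        if self.n_variants < 1:
            raise ValueError("need at least one variant")
        if not (0 <= self.heritability < 1):
            raise ValueError("heritability must lie in [0, 1)")


@dataclass
class Cohort:
    """Genotypes (n x m, dosage 0/1/2), phenotype, and the generating truth."""

    genotypes: np.ndarray
    phenotype: np.ndarray
    maf: np.ndarray
    beta: np.ndarray  # effects per standardized genotype
    spec: CohortSpec


def make_cohort(spec: CohortSpec) -> Cohort:
    """Draw genotypes ~ Binomial(2, p) and an additive phenotype at h2."""
    rng = np.random.default_rng(spec.seed)
    if isinstance(spec.maf, tuple) and len(spec.maf) == 2:
        lo, hi = spec.maf
        p = rng.uniform(lo, hi, size=spec.n_variants)
    else:
        p = np.asarray(spec.maf, dtype=float)
        if p.shape != (spec.n_variants,):
            raise ValueError("explicit MAF list must match n_variants")
    if np.any((p <= 0) | (p > 0.5)):
        raise ValueError("MAF must lie in (0, 0.5]")

    g = rng.binomial(2, p, size=(spec.n_individuals, spec.n_variants)).astype(
        np.int8
    )
    h2 = spec.heritability
    if h2 > 0:
        beta = rng.normal(0.0, 1.0, size=spec.n_variants)
        beta *= np.sqrt(h2 / np.sum(beta**2))  # exact target on std scale
        g_std = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        genetic = g_std @ beta
    else:
        beta = np.zeros(spec.n_variants)
        genetic = np.zeros(spec.n_individuals)
    noise = rng.normal(0.0, np.sqrt(1.0 - h2), size=spec.n_individuals)
    return Cohort(g, genetic + noise, p, beta, spec)


def run_marginal_gwas(genotypes: np.ndarray, phenotype) -> pd.DataFrame:
    """Per-variant score tests; works for quantitative or 0/1 phenotypes.

    For a quantitative y this is the usual single-SNP least-squares z; for a
    binary 0/1 y it is the score test on the case indicator, which is the
    small-effect equivalent of logistic regression. Monomorphic variants get
    z = 0 with a flag.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must take at least two distinct values")
    n = genotypes.shape[0]
    g = genotypes.astype(float)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    ss_g = np.einsum("ij,ij->j", gc, gc)
    mono = ss_g == 0
    ss_g_safe = np.where(mono, 1.0, ss_g)
    xy = gc.T @ yc
    beta = xy / ss_g_safe
    ss_y = float(yc @ yc)
    # score-test z: correlation * sqrt(n)
    r = xy / np.sqrt(ss_g_safe * ss_y)
    z = r * np.sqrt(n)
    se = np.where(mono, np.inf, np.sqrt(ss_y / n / ss_g_safe))
    return pd.DataFrame(
        {
            "beta": np.where(mono, 0.0, beta),
            "se": se,
            "z": np.where(mono, 0.0, z),
            "monomorphic": mono,
        }
    )


def make_enrichment_matrix(
    n_traits: int,
    planted_brain: Sequence[int],
    signal_strength: float = 6.0,
    seed: int = 0,
    n_cell_types: int = 220,
) -> EnrichmentMatrix:
    """Null-uniform trait x cell-type p-values with planted CNS signal.

    Planted traits get CNS-column p-values that are one-sided tail
    probabilities of Normal(delta, 1) draws; every other entry is
    Uniform(0, 1).
    """
    rng = np.random.default_rng(seed)
    categories = _cell_type_map(n_cell_types)
    traits = [f"trait{i:03d}" for i in range(n_traits)]
    pvals = rng.uniform(size=(n_traits, n_cell_types))
    cns_cols = np.array([c == "CNS" for c in categories.values])
    for t in planted_brain:
        zs = rng.normal(signal_strength, 1.0, size=int(cns_cols.sum()))
        pvals[t, cns_cols] = norm.sf(zs)
    df = pd.DataFrame(pvals, index=traits, columns=categories.index)
    return EnrichmentMatrix(pvalues=df, categories=categories)


def _cell_type_map(n_cell_types: int) -> pd.Series:
    """Assign cell types round-robin to the ten standard categories."""
    names = [f"ct{i:03d}" for i in range(n_cell_types)]
    cats = [
        CELL_TYPE_CATEGORIES[i % len(CELL_TYPE_CATEGORIES)]
        for i in range(n_cell_types)
    ]
    return pd.Series(cats, index=names, name="category")


@dataclass(frozen=True)
class BurdenSpec:
    """Recipe for gene x trait burden tables with an shet coupling.

    ``coupling`` maps (shet array, category) -> E[gamma^2]; the default makes
    squared effects on brain traits rise more steeply with constraint than
    effects on non-brain traits, so the two normalized curves cross.
    """

    n_genes: int = 1000
    n_traits_per_category: int = 5
    shet_range: tuple[float, float] = (1e-4, 1.0)
    se_range: tuple[float, float] = (0.05, 0.15)
    coupling: Callable[[np.ndarray, str], np.ndarray] | None = None
    seed: int = 0

    def coupling_fn(self, shet: np.ndarray, category: str) -> np.ndarray:
        if self.coupling is not None:
            out = np.asarray(self.coupling(shet, category), dtype=float)
        else:
            # steeper constraint-dependence for brain traits
            exponent = 1.0 if category == "brain" else 0.4
            scale = 0.05
            out = scale * (shet / 1e-2) ** exponent
        if np.any(out < 0):
            raise ValueError("coupling must be nonnegative")
        return out


def make_burden_table(spec: BurdenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level burden records plus the generating truth.

    Returns (records, truth): records has one row per (gene, trait) with
    gamma_hat = gamma + Normal(0, SE); truth carries the noiseless gamma and
    gamma^2 per row.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.shet_range
    shet = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_genes))
    genes = [f"gene{i:04d}" for i in range(spec.n_genes)]
    rows = []
    truth_rows = []
    for category in ("brain", "non-brain"):
        mean_g2 = spec.coupling_fn(shet, category)
        for j in range(spec.n_traits_per_category):
            trait = f"{category}-t{j}"
            sign = rng.choice([-1.0, 1.0], size=spec.n_genes)
            gamma = sign * np.sqrt(mean_g2)
            se = rng.uniform(*spec.se_range, size=spec.n_genes)
            gamma_hat = gamma + rng.normal(0.0, se)
            rows.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "trait": trait,
                        "category": category,
                        "gamma_hat": gamma_hat,
                        "se": se,
                        "shet": shet,
                    }
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "trait": trait,
                        "gamma": gamma,
                        "gamma2": gamma**2,
                    }
                )
            )
    return (
        pd.concat(rows, ignore_index=True),
        pd.concat(truth_rows, ignore_index=True),
    )
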