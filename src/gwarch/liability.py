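"""Liability-threshold calculus for case-control GWAS.

Under the classical liability threshold model, disease status is the
indicator that a standard-normal latent liability exceeds T = Phi^{-1}(1-K),
where K is the population prevalence. In the small-effect regime, a
case-control study of M individuals with case fraction omega has the same
power as a quantitative GWAS of the liability with effective sample size

    N' = M omega (1-omega) phi(T)^2 / (K^2 (1-K)^2),

and z-scores deflate approximately linearly, z_after = sqrt(N'/N) z_before.
This module provides that calculus, the log-odds <-> liability-scale effect
conversion, estimation of M omega(1-omega) from summary-statistic standard
errors, and a harness that binarizes a synthetic quantitative cohort and
compares observed z-score deflation with the predicted slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


@dataclass(frozen=True)
class CaseControlDesign:
    """(M, omega, K) of a case-control GWAS plus derived threshold terms."""

    M: float
    omega: float
    K: float

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError("sample size M must be >= 0")
        if not (0 < self.omega < 1):
            raise ValueError("case fraction omega must lie in (0, 1)")
        if not (0 < self.K < 1):
            raise ValueError("prevalence K must lie in (0, 1)")

    @property
    def T(self) -> float:
        """Liability threshold, the upper-K quantile of the standard normal."""
        return float(norm.isf(self.K))

    @property
    def phiT(self) -> float:
        return float(norm.pdf(self.T))


@dataclass(frozen=True)
class LogOddsEffect:
    """Per-allele log odds ratio with its standard error and MAF."""

    zeta: float
    se: float
    p: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not (0 < self.p <= 0.5):
            raise ValueError("MAF must lie in (0, 0.5]")


def effective_sample_size(design: CaseControlDesign) -> float:
    """Liability-scale N' matching the power of the case-control design."""
    k1 = design.K * (1.0 - design.K)
    return design.M * design.omega * (1.0 - design.omega) * design.phiT**2 / k1**2


def rescale_z(z, N: float, Nprime: float):
    """Deflate (or inflate) z-scores to a different effective sample size."""
    if N <= 0 or Nprime <= 0:
        raise ValueError("sample sizes must be positive")
    return np.asarray(z, dtype=float) * np.sqrt(Nprime / N)


def logodds_to_liability(effect: LogOddsEffect, design: CaseControlDesign):
    """Map a log-odds effect to the liability scale (small-effect regime).

    beta = zeta * K(1-K) / phi(T); the standard error transforms by the same
    factor.
    """
    factor = design.K * (1.0 - design.K) / design.phiT
    return effect.zeta * factor, effect.se * factor


def liability_to_logodds(beta: float, se: float, design: CaseControlDesign):
    """Inverse of :func:`logodds_to_liability`."""
    factor = design.phiT / (design.K * (1.0 - design.K))
    return beta * factor, se * factor


def estimate_design_scale(summary: pd.DataFrame) -> float:
    """Estimate M omega(1-omega) from (maf, se) columns of summary stats.

    The sampling model SE(zeta_hat)^2 = 1 / (2 M omega(1-omega) p (1-p))
    implies M omega(1-omega) = 1 / (2 p (1-p) SE^2) at every SNP; the median
    across SNPs is robust to misreported entries.
    """
    if len(summary) == 0:
        raise ValueError("summary table is empty")
    p = np.asarray(summary["maf"], dtype=float)
    se = np.asarray(summary["se"], dtype=float)
    if np.any((p <= 0) | (p > 0.5)):
        raise ValueError("MAF must lie in (0, 0.5]")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    return float(np.median(1.0 / (2.0 * p * (1.0 - p) * se**2)))


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset, average ranks)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.all(x == x[0]):
        raise ValueError("all values equal; transform undefined")
    r = rankdata(x, method="average")
    return norm.ppf((r - offset) / (x.size - 2.0 * offset + 1.0))


@dataclass
class SlopeResult:
    """Through-origin regression of transformed z on original z."""

    slope: float
    predicted_slope: float
    se_boot: float
    n_prime: float
    z_before: np.ndarray
    z_after: np.ndarray

    @property
    def residuals(self) -> np.ndarray:
        return self.z_after - self.slope * self.z_before


def _through_origin(z_before: np.ndarray, z_after: np.ndarray) -> float:
    denom = float(np.dot(z_before, z_before))
    if denom == 0:
        raise ValueError("all original z-scores are zero")
    return float(np.dot(z_before, z_after) / denom)


def _boot_slope(z0, z1, rng, n_boot: int) -> float:
    n = len(z0)
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        slopes[b] = _through_origin(z0[idx], z1[idx])
    return float(np.std(slopes, ddof=1))


def binarize_and_compare(
    cohort,
    prevalence: float,
    tail: str = "upper",
    seed=0,
    n_boot: int = 200,
    min_cases: int = 50,
) -> SlopeResult:
    """Binarize a quantitative cohort at a prevalence cutoff and regress z's.

    Cases are the individuals beyond the K-quantile in the chosen tail; a
    per-variant score test on the case indicator gives the binarized GWAS
    z-scores, which are regressed through the origin on the original
    quantitative z-scores. The predicted slope sqrt(N'/N) comes from the
    liability calculus with M = N and omega = K.
    """
    from .synthetic import run_marginal_gwas

    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must lie in (0, 1)")
    y = cohort.phenotype
    n = len(y)
    n_cases = int(round(prevalence * n))
    if n_cases < min_cases:
        raise ValueError(
            f"prevalence {prevalence} yields {n_cases} cases < {min_cases}"
        )
    order = np.argsort(y)
    labels = np.zeros(n, dtype=np.int8)
    if tail == "upper":
        labels[order[-n_cases:]] = 1
    else:
        labels[order[:n_cases]] = 1

    rng = np.random.default_rng(seed)
    z_before = run_marginal_gwas(cohort.genotypes, y)["z"].to_numpy()
    z_after = run_marginal_gwas(cohort.genotypes, labels)["z"].to_numpy()
    design = CaseControlDesign(M=float(n), omega=prevalence, K=prevalence)
    n_prime = effective_sample_size(design)
    slope = _through_origin(z_before, z_after)
    se = _boot_slope(z_before, z_after, rng, n_boot)
    return SlopeResult(
        slope=slope,
        predicted_slope=float(np.sqrt(n_prime / n)),
        se_boot=se,
        n_prime=n_prime,
        z_before=z_before,
        z_after=z_after,
    )


def downsample_and_compare(
    cohort,
    n_sub: int,
    seed=0,
    n_boot: int = 200,
) -> SlopeResult:
    """Quantitative GWAS on a random subsample; slope vs the full-cohort z.

    The predicted slope is sqrt(n_sub / N): downsampling is the pure
    sample-size analogue of binarizing at matched effective size.
    """
    from .synthetic import run_marginal_gwas

    n = len(cohort.phenotype)
    if not (1 < n_sub <= n):
        raise ValueError("subsample size must lie in (1, N]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_sub, replace=False)
    z_before = run_marginal_gwas(cohort.genotypes, cohort.phenotype)["z"].to_numpy()
    z_after = run_marginal_gwas(
        cohort.genotypes[idx], cohort.phenotype[idx]
    )["z"].to_numpy()
    slope = _through_origin(z_before, z_after)
    se = _boot_slope(z_before, z_after, rng, n_boot)
    return SlopeResult(
        slope=slope,
        predicted_slope=float(np.sqrt(n_sub / n)),
        se_boot=se,
        n_prime=float(n_sub),
        z_before=z_before,
        z_after=z_after,
    )
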