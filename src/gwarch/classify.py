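"""Trait classification from cell-type enrichment and hit-pattern summaries.

Heritability-enrichment p-values (one per trait x cell type, e.g. from
stratified LD score regression) are combined within cell-type categories by
the aggregated Cauchy association test (ACAT), which tolerates arbitrary
correlation among the inputs. A trait is called brain-related when its
combined central-nervous-system (CNS) p-value clears a Bonferroni threshold
of 0.05 / (n_categories x n_traits). The module also summarizes ascertained
hit tables (median MAF, median |z|, CDFs) and prunes a ranked trait list to
an approximately uncorrelated subset using a genetic-correlation cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import HitTable, ecdf

logger = logging.getLogger(__name__)

CELL_TYPE_CATEGORIES = (
    "adrenal/pancreas",
    "cardiovascular",
    "CNS",
    "connective/bone",
    "gastrointestinal",
    "immune",
    "kidney",
    "liver",
    "other",
    "skeletal muscle",
)


def acat_combine(pvals, eps: float = 1e-15) -> float:
    """Aggregated Cauchy combination of p-values.

    T = (1/k) sum tan((0.5 - p_i) pi); combined p = 0.5 - arctan(T)/pi.
    Inputs at 0 or 1 are clamped to [eps, 1 - eps] with a warning. Dominated
    by its smallest input, and exact under the null for any dependence.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D list of p-values")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("p-values at 0 or 1 clamped for ACAT", stacklevel=2)
        p = np.clip(p, eps, 1.0 - eps)
    t = float(np.mean(np.tan((0.5 - p) * np.pi)))
    return float(0.5 - np.arctan(t) / np.pi)


@dataclass
class EnrichmentMatrix:
    """Traits x cell types one-sided p-values with a category map."""

    pvalues: pd.DataFrame  # rows traits, columns cell types
    categories: pd.Series  # cell type -> category

    def __post_init__(self) -> None:
        missing = set(self.pvalues.columns) - set(self.categories.index)
        if missing:
            raise ValueError(f"cell types without a category: {sorted(missing)}")
        vals = self.pvalues.to_numpy()
        if np.any((vals <= 0) | (vals > 1)):
            raise ValueError("enrichment p-values must lie in (0, 1]")

    def columns_in(self, category: str) -> list[str]:
        keep = self.categories[self.categories == category].index
        return [c for c in self.pvalues.columns if c in set(keep)]

    def write(self, pval_path, category_path) -> None:
        self.pvalues.to_csv(pval_path, sep="\t", index_label="trait")
        self.categories.rename_axis("cell_type").to_csv(category_path, sep="\t")

    @classmethod
    def read(cls, pval_path, category_path) -> "EnrichmentMatrix":
        pv = pd.read_csv(pval_path, sep="\t", index_col="trait")
        cats = pd.read_csv(category_path, sep="\t", index_col="cell_type")[
            "category"
        ]
        return cls(pv, cats)


def classify_traits(
    matrix: EnrichmentMatrix,
    n_traits: int | None = None,
    alpha: float = 0.05,
    n_categories: int | None = None,
) -> pd.DataFrame:
    """Label each trait brain-related from its ACAT-combined CNS p-value.

    The Bonferroni threshold is alpha / (n_categories * n_traits); the
    comparison is strict (a trait exactly at threshold is not labeled).
    Returns per-trait combined p-values for every category plus the label.
    """
    cats = list(dict.fromkeys(matrix.categories))
    if "CNS" not in cats:
        raise ValueError("enrichment matrix has no CNS category")
    n_traits = n_traits if n_traits is not None else len(matrix.pvalues)
    n_categories = n_categories if n_categories is not None else len(cats)
    threshold = alpha / (n_categories * n_traits)
    out = {}
    for cat in cats:
        cols = matrix.columns_in(cat)
        out[cat] = matrix.pvalues[cols].apply(
            lambda row: acat_combine(row.to_numpy()), axis=1
        )
    res = pd.DataFrame(out, index=matrix.pvalues.index)
    res["brain_related"] = res["CNS"] < threshold
    res.attrs["threshold"] = threshold
    return res


@dataclass
class TraitSummary:
    trait: str
    n_hits: int
    median_maf: float
    median_abs_z: float
    maf_grid: np.ndarray
    maf_cdf: np.ndarray
    z_grid: np.ndarray
    z_cdf: np.ndarray


def hit_summary(
    hits: HitTable,
    maf_grid: np.ndarray | None = None,
    z_grid: np.ndarray | None = None,
) -> TraitSummary:
    """Median MAF / |z| and empirical CDFs of one trait's ascertained hits."""
    if len(hits) == 0:
        raise ValueError("empty hit table")
    traits = hits.traits()
    if len(traits) != 1:
        raise ValueError("hit_summary expects a single-trait table")
    maf = hits.df["maf"].to_numpy(dtype=float)
    abs_z = np.abs(hits.df["z"].to_numpy(dtype=float))
    if maf_grid is None:
        maf_grid = np.linspace(0.01, 0.5, 99)
    if z_grid is None:
        z_grid = np.linspace(5.45, 30.0, 200)
    return TraitSummary(
        trait=traits[0],
        n_hits=len(hits),
        median_maf=float(np.median(maf)),
        median_abs_z=float(np.median(abs_z)),
        maf_grid=np.asarray(maf_grid, dtype=float),
        maf_cdf=ecdf(maf, maf_grid),
        z_grid=np.asarray(z_grid, dtype=float),
        z_cdf=ecdf(abs_z, z_grid),
    )


def prune_traits(
    ranked_traits,
    rg: pd.DataFrame,
    cutoff: float = 0.5,
) -> list:
    """Greedy pruning to approximately uncorrelated traits.

    ``ranked_traits`` must already be ordered from strongest enrichment
    down; a trait is kept iff |rg| <= cutoff against every previously kept
    trait. Traits with a missing correlation entry are skipped with a log
    message, mirroring the exclusion of traits lacking estimates.
    """
    vals = rg.to_numpy(dtype=float)
    if rg.shape[0] != rg.shape[1] or not np.allclose(
        vals, vals.T, equal_nan=True
    ):
        raise ValueError("genetic-correlation matrix must be symmetric")
    if np.nanmax(np.abs(vals)) > 1 + 1e-9:
        raise ValueError("genetic correlations must lie in [-1, 1]")
    kept: list = []
    for trait in ranked_traits:
        if trait not in rg.index:
            logger.info("trait %s lacks rg estimates; skipped", trait)
            continue
        row = rg.loc[trait]
        ok = True
        for other in kept:
            r = row.get(other, np.nan)
            if np.isnan(r):
                logger.info("missing rg(%s, %s); trait skipped", trait, other)
                ok = False
                break
            if abs(r) > cutoff:
                ok = False
                break
        if ok:
            kept.append(trait)
    return kept
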