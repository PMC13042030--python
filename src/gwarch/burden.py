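"""Gene-level constraint versus squared burden effects.

Rare-variant burden tests give per-gene effect estimates gamma_hat with
standard errors; gamma_hat^2 - SE^2 is an unbiased estimator of the squared
genic effect gamma^2. Genes are grouped into quantile bins of shet (the
strength of selection against heterozygous loss-of-function carriers), mean
normalized squared effects are traced per trait category across bins, and
uncertainty comes from a trait-level bootstrap. A crossing of the
brain-related and non-brain curves — higher among constrained genes, lower
among unconstrained ones — indicates that effects on brain-related traits
track fitness consequences more closely, rather than a uniform scale shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

REQUIRED_COLUMNS = ("gene", "trait", "category", "gamma_hat", "se", "shet")


def unbiased_gamma2(gamma_hat, se) -> np.ndarray:
    """gamma_hat^2 - SE^2: unbiased for gamma^2 under Gaussian noise."""
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    return gamma_hat**2 - se**2


def bin_assignment(shet, n_bins: int = 15) -> np.ndarray:
    """Quantile bins (1-based) with stable tie-breaking by input order.

    When values are distinct, bin sizes differ by at most one; fewer
    distinct values than bins is an error.
    """
    shet = np.asarray(shet, dtype=float)
    if n_bins < 2:
        raise ValueError("need at least two bins")
    if len(np.unique(shet)) < n_bins:
        raise ValueError("fewer distinct shet values than bins")
    order = np.argsort(shet, kind="stable")
    n = len(shet)
    bins = np.empty(n, dtype=int)
    # split the sorted order into n_bins nearly equal runs
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    for b in range(n_bins):
        bins[order[edges[b] : edges[b + 1]]] = b + 1
    return bins


@dataclass
class BurdenCurves:
    """Normalized per-bin category means with bootstrap bands and smooths."""

    curve: pd.DataFrame  # columns bin, category, mean_g2
    bands: pd.DataFrame | None  # bin, category, lo, hi
    smooth: pd.DataFrame | None  # bin, category, fitted
    norm_constant: float
    n_bins: int
    norm_bin: int


def _per_gene_bins(records: pd.DataFrame, n_bins: int) -> pd.Series:
    genes = records[["gene", "shet"]].drop_duplicates("gene")
    genes = genes.sort_values("gene", kind="stable")  # stable tie rule
    bins = bin_assignment(genes["shet"].to_numpy(), n_bins)
    return pd.Series(bins, index=genes["gene"].to_numpy())


def _curve_frame(
    df: pd.DataFrame, weight_traits_equally: bool
) -> pd.DataFrame:
    if weight_traits_equally:
        per_trait = df.groupby(["bin", "category", "trait"], observed=True)[
            "g2"
        ].mean()
        cur = per_trait.groupby(["bin", "category"]).mean()
    else:
        cur = df.groupby(["bin", "category"], observed=True)["g2"].mean()
    return cur.rename("mean_g2").reset_index()


def shet_binned_curve(
    records: pd.DataFrame,
    n_bins: int = 15,
    norm_bin: int = 10,
    n_boot: int = 200,
    seed=0,
    resample: str = "trait",
    weight_traits_equally: bool = False,
    span: float = 0.75,
) -> BurdenCurves:
    """Per-bin, per-category mean normalized gamma^2 with bootstrap bands.

    Bins are shet quantiles over genes (both categories pooled); every value
    is divided by the pooled grand mean in ``norm_bin`` so the tenth bin is
    one by construction. ``resample`` picks the bootstrap unit: "trait"
    (traits with replacement) or "gene" (genes within each trait). A lowess
    smoother (tricube-weighted local linear regression) over the bin index
    summarizes each category. Empty bin-category cells stay missing.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"burden table missing columns: {missing}")
    if not (1 <= norm_bin <= n_bins):
        raise ValueError("norm_bin must lie within 1..n_bins")
    df = records.copy()
    df["g2"] = unbiased_gamma2(df["gamma_hat"], df["se"])
    gene_bins = _per_gene_bins(df, n_bins)
    df["bin"] = df["gene"].map(gene_bins)

    norm = df[df["bin"] == norm_bin]["g2"].mean()
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("normalization bin has zero or undefined mean")
    df["g2"] = df["g2"] / norm

    curve = _curve_frame(df, weight_traits_equally)

    bands = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        traits = df["trait"].unique()
        for b in range(n_boot):
            if resample == "trait":
                chosen = rng.choice(traits, size=len(traits), replace=True)
                parts = [
                    df[df["trait"] == t].assign(trait=f"{t}#{i}")
                    for i, t in enumerate(chosen)
                ]
                rb = pd.concat(parts, ignore_index=True)
            elif resample == "gene":
                parts = []
                for t, grp in df.groupby("trait"):
                    idx = rng.integers(0, len(grp), size=len(grp))
                    parts.append(grp.iloc[idx])
                rb = pd.concat(parts, ignore_index=True)
            else:
                raise ValueError("resample must be 'trait' or 'gene'")
            boots.append(
                _curve_frame(rb, weight_traits_equally).assign(rep=b)
            )
        allb = pd.concat(boots, ignore_index=True)
        bands = (
            allb.groupby(["bin", "category"])["mean_g2"]
            .quantile([0.025, 0.975])
            .unstack()
            .rename(columns={0.025: "lo", 0.975: "hi"})
            .reset_index()
        )

    smooth_rows = []
    for cat, grp in curve.groupby("category"):
        grp = grp.sort_values("bin")
        if len(grp) >= 4:
            fitted = lowess(
                grp["mean_g2"], grp["bin"], frac=span, return_sorted=False
            )
            smooth_rows.append(
                pd.DataFrame(
                    {"bin": grp["bin"], "category": cat, "fitted": fitted}
                )
            )
    smooth = (
        pd.concat(smooth_rows, ignore_index=True) if smooth_rows else None
    )
    return BurdenCurves(
        curve=curve,
        bands=bands,
        smooth=smooth,
        norm_constant=float(norm),
        n_bins=n_bins,
        norm_bin=norm_bin,
    )


def curve_crossing(curves: BurdenCurves, low_bins=None, high_bins=None) -> dict:
    """Summarize whether the two category curves switch order.

    Returns the mean difference (brain minus the other category) over the
    low-shet and high-shet thirds of the bin range.
    """
    cur = curves.curve.pivot(index="bin", columns="category", values="mean_g2")
    cats = list(cur.columns)
    if len(cats) != 2:
        raise ValueError("curve crossing needs exactly two categories")
    brain = "brain" if "brain" in cats else cats[0]
    other = [c for c in cats if c != brain][0]
    n = curves.n_bins
    low_bins = low_bins if low_bins is not None else range(1, n // 3 + 1)
    high_bins = (
        high_bins if high_bins is not None else range(n - n // 3 + 1, n + 1)
    )
    diff = cur[brain] - cur[other]
    return {
        "low_diff": float(diff.loc[diff.index.isin(list(low_bins))].mean()),
        "high_diff": float(diff.loc[diff.index.isin(list(high_bins))].mean()),
    }
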