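"""Goodness-of-fit via residual p-values and cross-validated uniformity.

For an ascertained hit (z_i, p_i), the residual p-value is

    Pr(|Z| > |z_i| | |Z| > z_threshold, p = p_i, model),

which is exactly Uniform(0, 1) when the fitted model matches the generating
process (probability integral transform). Residuals are computed out of
sample by 10-fold cross-validation over genomic blocks; per-trait-model
uniformity is tested with two-sided Kolmogorov-Smirnov and controlled
across trait-model pairs with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kstest
from statsmodels.stats.multitest import multipletests

from .architecture import HitTable
from .inference import (
    InferenceConfig,
    fit_alternative_alpha,
    fit_alternative_normal,
    fit_group,
    fitted_model_from_trait,
)
from .sfs import SFSTable

MODEL_FAMILIES = ("stabilizing", "normal", "alpha")


def residual_pvalue(z, p, model, config: InferenceConfig | None = None):
    """Residual p-value(s) of hit(s) under a fitted model.

    ``model`` is any object with a ``residual_tail(z, p)`` method (the
    frozen fits produced by the inference module).
    """
    config = config or InferenceConfig()
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(np.abs(z_arr) < config.z_threshold):
        raise ValueError("residual p-values are defined only for |z| above threshold")
    if np.any((p_arr <= config.maf_threshold) | (p_arr > 0.5)):
        raise ValueError("MAF outside the ascertained range")
    out = model.residual_tail(z_arr, p_arr)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if np.isscalar(z) else out


def _fit_family(
    train: HitTable,
    family: str,
    table: SFSTable,
    config: InferenceConfig,
    seed,
):
    trait = train.traits()[0]
    n = float(train.meta[trait]["n"])
    if family == "stabilizing":
        gf = fit_group([train], table, config, seed=seed)
        return fitted_model_from_trait(
            gf.trait_fits[0], gf.fs, table, n, config
        )
    if family == "normal":
        fit = fit_alternative_normal(train, table, config)
    elif family == "alpha":
        fit = fit_alternative_alpha(train, table, config)
    else:
        raise ValueError(f"unknown model family: {family}")
    return fitted_model_from_trait(fit, None, table, n, config)


def crossvalidated_residuals(
    hits: HitTable,
    family: str,
    table: SFSTable,
    config: InferenceConfig | None = None,
    seed=0,
    n_folds: int = 10,
) -> pd.DataFrame:
    """Out-of-sample residual p-values with block-level folds.

    Blocks are shuffled into ``n_folds`` groups; the model family is
    refitted on the training blocks of each fold and residuals are scored on
    the held-out hits, so every hit is scored exactly once.
    """
    config = config or InferenceConfig()
    trait = hits.traits()
    if len(trait) != 1:
        raise ValueError("expected a single-trait hit table")
    trait = trait[0]
    df = hits.df
    blocks = np.sort(df["block"].unique())
    if len(blocks) < n_folds:
        raise ValueError(
            f"need at least {n_folds} distinct blocks, got {len(blocks)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(blocks))
    fold_of_block = {
        int(blocks[j]): int(i % n_folds) for i, j in enumerate(perm)
    }
    fold_idx = df["block"].map(fold_of_block).to_numpy()

    records = []
    for fold in range(n_folds):
        test_mask = fold_idx == fold
        if not test_mask.any():
            continue
        train = HitTable(
            df[~test_mask].reset_index(drop=True), hits.meta
        )
        model = _fit_family(
            train, family, table, config, seed=rng.integers(2**31 - 1)
        )
        sub = df[test_mask]
        res = residual_pvalue(
            sub["z"].to_numpy(), sub["maf"].to_numpy(), model, config
        )
        records.append(
            pd.DataFrame(
                {
                    "trait": trait,
                    "variant": sub["variant"].to_numpy(),
                    "residual_p": np.atleast_1d(res),
                    "fold": fold,
                    "model": family,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def uniformity_report(
    records: pd.DataFrame,
    fdr_level: float = 0.05,
    min_residuals: int = 20,
) -> pd.DataFrame:
    """KS uniformity per (trait, model) with BH correction across pairs."""
    rows = []
    for (trait, model), grp in records.groupby(["trait", "model"]):
        vals = grp["residual_p"].to_numpy(dtype=float)
        if len(vals) < min_residuals:
            continue
        stat, pval = kstest(vals, "uniform")
        rows.append(
            {
                "trait": trait,
                "model": model,
                "n": len(vals),
                "ks_stat": float(stat),
                "ks_p": float(pval),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        reject, p_adj, _, _ = multipletests(
            out["ks_p"], alpha=fdr_level, method="fdr_bh"
        )
        out["ks_p_bh"] = p_adj
        out["reject"] = reject
    return out
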