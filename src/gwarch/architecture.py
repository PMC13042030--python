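"""Generative model for ascertained GWAS hits of a complex trait.

A trait is described by its heritability h2, mutational target size L (sites
at which a mutation affects the trait), and GWAS sample size N (for binary
traits, the liability-scale effective size N'). Each of the L sites draws a
selection coefficient s ~ f(s); the site carries a segregating variant with
probability seg_prob(s); its minor allele frequency p comes from the
demography-aware SFS P(p | s); its effect on the standardized trait is
beta | s ~ Normal(0, c s), where the trait-specific constant c is pinned by
the heritability normalization

    h2 = L * E_{f(s), SFS}[ seg_prob(s) * 2 p (1-p) * c * s ];

and its GWAS z-score is z ~ Normal(beta * sqrt(2 p (1-p) N), 1). A variant is
a hit iff p > maf_threshold and |z| > z_threshold. Sites are independent (no
LD); block labels are resampling bookkeeping only.

The one-dimensional (no-pleiotropy) variant replaces the Gaussian effect with
a deterministic magnitude: z ~ Normal(sqrt(c s 2 p (1-p) N), 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .sfs import SFSTable, bin_mean_2pq
from .spline_fs import SplineFS

Z_THRESHOLD = 5.45  # |z| equivalent of two-sided p < 5e-8
MAF_THRESHOLD = 0.01


class DegenerateModelError(ValueError):
    """The heritability normalization constant is numerically undefined."""


@dataclass(frozen=True)
class TraitParams:
    """Trait-level parameters of the generative model."""

    h2: float
    L: float
    N: float
    z_threshold: float = Z_THRESHOLD
    maf_threshold: float = MAF_THRESHOLD
    trait: str = "trait"

    def __post_init__(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ValueError(f"h2 must lie in [0, 1), got {self.h2}")
        if self.L < 0:
            raise ValueError(f"L must be >= 0, got {self.L}")
        if self.N < 0:
            raise ValueError(f"N must be >= 0, got {self.N}")


@dataclass
class HitTable:
    """Ascertained GWAS hits for one or more traits.

    ``df`` columns: trait, variant, maf, z, block (chrom/pos optional).
    ``meta`` maps trait id -> metadata dict (n, h2, ...).
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    REQUIRED = ("trait", "variant", "maf", "z", "block")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"hit table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.df["trait"]))

    def for_trait(self, trait: str) -> "HitTable":
        sub = self.df[self.df["trait"] == trait].reset_index(drop=True)
        return HitTable(sub, {trait: self.meta.get(trait, {})})

    def validate_ascertainment(
        self,
        z_threshold: float = Z_THRESHOLD,
        maf_threshold: float = MAF_THRESHOLD,
    ) -> None:
        bad = (np.abs(self.df["z"]) <= z_threshold) | (
            self.df["maf"] <= maf_threshold
        ) | (self.df["maf"] > 0.5)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} rows violate the ascertainment predicate"
            )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# gwarch-hits v1\n")
            for trait in sorted(self.meta):  # one meta line per trait
                line = yaml.safe_dump(
                    self.meta[trait], default_flow_style=True, sort_keys=True
                ).strip()
                fh.write(f"# meta {trait}: {line}\n")
            self.df.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, path) -> "HitTable":
        import io

        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("# meta "):
                key, val = line[len("# meta ") :].split(":", 1)
                meta[key.strip()] = yaml.safe_load(val)
            elif not line.startswith("#"):
                body_start = i
                break
        df = pd.read_csv(
            io.StringIO("".join(lines[body_start:])), sep="\t",
            float_precision="round_trip",
        )
        return cls(df, meta)


class CommonBins:
    """Frequency-bin geometry above the MAF threshold.

    Restricts each SFS bin to its part above the threshold under the
    log-uniform within-bin law, with per-bin Gauss-Legendre nodes in ln p
    for integrals over the ascertained frequency range.
    """

    def __init__(
        self,
        table: SFSTable,
        maf_threshold: float = MAF_THRESHOLD,
        n_p_quad: int = 4,
    ):
        edges = table.bin_edges
        a, b = edges[:-1], edges[1:]
        self.mean2pq = bin_mean_2pq(edges)
        self.log_widths = np.log(b / a)

        common = b > maf_threshold
        self.common_cols = np.nonzero(common)[0]
        a_c = np.maximum(a[common], maf_threshold)
        b_c = b[common]
        # fraction of each bin's log-uniform mass above the threshold
        self.common_frac = np.log(b_c / a_c) / self.log_widths[common]
        self.common_lo = a_c
        self.common_hi = b_c

        # per-common-bin quadrature in ln p, weights summing to 1 per bin
        x, wq = np.polynomial.legendre.leggauss(n_p_quad)
        la, lb = np.log(a_c)[:, None], np.log(b_c)[:, None]
        self.p_nodes = np.exp(0.5 * (lb - la) * x[None, :] + 0.5 * (la + lb))
        # averaging weights for (1/ln(b/a)) * int g(p) dln p, summing to 1
        self.p_node_w = np.broadcast_to(
            wq[None, :] / wq.sum(), self.p_nodes.shape
        ).copy()
        self.twopq_nodes = 2.0 * self.p_nodes * (1.0 - self.p_nodes)


class ModelGrid(CommonBins):
    """Discretization of (f(s), SFS) shared by the simulator and likelihood.

    Selection is handled on Gauss-Legendre nodes in ln s (weights already
    folded with the f(s) density), frequencies on the SFS bin grid with a
    log-uniform law inside each bin.
    """

    def __init__(
        self,
        fs: SplineFS,
        table: SFSTable,
        n_s: int = 48,
        maf_threshold: float = MAF_THRESHOLD,
        n_p_quad: int = 4,
    ):
        super().__init__(table, maf_threshold=maf_threshold, n_p_quad=n_p_quad)
        pos = table.positive_s
        lo = max(fs.support[0], float(pos.min()))
        hi = min(fs.support[1], float(pos.max()))
        if not lo < hi:
            raise ValueError("f(s) support does not overlap the SFS grid")
        self.s, self.w = fs.quadrature(n_s, lo, hi)
        self.w = self.w / self.w.sum()  # condition on the covered window
        self.mass, self.seg = table.rows_at(self.s)
        self.table = table
        self.maf_threshold = maf_threshold

    def heritability_integral(self) -> float:
        """I = E[seg_prob(s) * s * 2p(1-p)] under f(s) and the SFS."""
        per_s = self.mass @ self.mean2pq
        return float(np.sum(self.w * self.seg * self.s * per_s))

    def common_mass(self) -> np.ndarray:
        """Per s-node probability that a segregating variant is common."""
        return self.mass[:, self.common_cols] @ self.common_frac

    def trait_constant_k(self) -> float:
        """k = 4 mu / E[2q(1-q) s]; near 1 in the full-scale model."""
        return 4.0 * self.table.mutation_rate / self.heritability_integral()


def effect_variance_constant(
    params: TraitParams,
    fs: SplineFS,
    table: SFSTable,
    n_s: int = 48,
    grid: ModelGrid | None = None,
) -> float:
    """Trait-specific c with Var(beta | s) = c s, from the h2 normalization."""
    if grid is None:
        grid = ModelGrid(fs, table, n_s=n_s, maf_threshold=params.maf_threshold)
    integral = grid.heritability_integral()
    if not np.isfinite(integral) or integral <= 0:
        raise DegenerateModelError(
            "E[seg * s * 2p(1-p)] is zero; cannot normalize effect variance"
        )
    if params.L == 0:
        raise DegenerateModelError("L = 0 leaves c undefined")
    return params.h2 / (params.L * integral)


@dataclass
class SimulatedHits:
    """Hits plus the bookkeeping needed for oracles and sweeps."""

    hits: HitTable
    params: TraitParams
    c: float
    n_sites: int
    n_segregating: int
    n_common: int
    seg_maf_hist: np.ndarray  # pre-ascertainment histogram over SFS bins
    ledger: pd.DataFrame | None = None

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def _empty_hits(trait: str, meta: dict) -> HitTable:
    df = pd.DataFrame(
        {
            "trait": pd.Series([], dtype=str),
            "variant": pd.Series([], dtype=str),
            "maf": pd.Series([], dtype=float),
            "z": pd.Series([], dtype=float),
            "block": pd.Series([], dtype=int),
        }
    )
    return HitTable(df, {trait: meta})


def _simulate(
    params: TraitParams,
    fs: SplineFS,
    table: SFSTable,
    seed,
    one_dimensional: bool,
    n_blocks: int,
    n_s: int,
    keep_ledger: bool,
    site_sampling: str,
    grid: ModelGrid | None,
) -> SimulatedHits:
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = ModelGrid(fs, table, n_s=n_s, maf_threshold=params.maf_threshold)
    meta = {"n": float(params.N), "h2": float(params.h2), "L": float(params.L)}
    L = int(round(params.L))
    if L == 0:
        return SimulatedHits(
            _empty_hits(params.trait, meta), params, 0.0, 0, 0, 0,
            np.zeros(grid.table.n_bins),
        )
    c = (
        effect_variance_constant(params, fs, table, grid=grid)
        if params.h2 > 0
        else 0.0
    )
    if site_sampling == "poisson":
        counts = rng.poisson(L * grid.w)
    elif site_sampling == "fixed":
        counts = rng.multinomial(L, grid.w)
    else:
        raise ValueError("site_sampling must be 'fixed' or 'poisson'")

    if keep_ledger and L > 5_000_000:
        raise ValueError("ledger output only supported for L <= 5e6")

    maf_parts, z_parts, s_parts = [], [], []
    ledger_rows = [] if keep_ledger else None
    seg_hist = np.zeros(grid.table.n_bins)
    n_seg_total = 0
    n_common_total = 0
    thr = params.maf_threshold
    for k in range(len(grid.s)):
        if counts[k] == 0:
            continue
        n_seg = rng.binomial(counts[k], grid.seg[k])
        n_seg_total += int(n_seg)
        if n_seg == 0:
            continue
        bins = rng.multinomial(n_seg, grid.mass[k])
        seg_hist += bins
        if keep_ledger:
            # rare sites never hit but carry heritability: draw them too
            edges = grid.table.bin_edges
            for col in np.nonzero(bins)[0]:
                if col in set(grid.common_cols):
                    continue
                n_bin = int(bins[col])
                a, bb = edges[col], edges[col + 1]
                p = a * (bb / a) ** rng.random(n_bin)
                beta = rng.normal(0.0, np.sqrt(c * grid.s[k]), size=n_bin)
                z = rng.normal(
                    beta * np.sqrt(2.0 * p * (1.0 - p) * params.N), 1.0
                )
                ledger_rows.append(
                    pd.DataFrame(
                        {
                            "s": grid.s[k],
                            "p": p,
                            "beta": beta,
                            "z": z,
                            "is_hit": False,
                        }
                    )
                )
        for j, col in enumerate(grid.common_cols):
            n_bin = bins[col]
            if n_bin == 0:
                continue
            n_c = (
                rng.binomial(n_bin, grid.common_frac[j])
                if grid.common_frac[j] < 1.0
                else n_bin
            )
            n_below = int(n_bin - n_c)
            if keep_ledger and n_below:
                # the sub-threshold slice of a straddling bin
                lo_b, hi_b = grid.table.bin_edges[col], grid.common_lo[j]
                p = lo_b * (hi_b / lo_b) ** rng.random(n_below)
                beta = rng.normal(0.0, np.sqrt(c * grid.s[k]), size=n_below)
                z = rng.normal(
                    beta * np.sqrt(2.0 * p * (1.0 - p) * params.N), 1.0
                )
                ledger_rows.append(
                    pd.DataFrame(
                        {"s": grid.s[k], "p": p, "beta": beta, "z": z,
                         "is_hit": False}
                    )
                )
            if n_c == 0:
                continue
            n_common_total += int(n_c)
            lo, hi = grid.common_lo[j], grid.common_hi[j]
            p = lo * (hi / lo) ** rng.random(n_c)
            sqrt_pow = np.sqrt(2.0 * p * (1.0 - p) * params.N)
            if one_dimensional:
                mean_z = np.sqrt(c * grid.s[k]) * sqrt_pow
                z = rng.normal(mean_z, 1.0)
                beta = np.full(n_c, np.sqrt(c * grid.s[k]))
            else:
                beta = rng.normal(0.0, np.sqrt(c * grid.s[k]), size=n_c)
                z = rng.normal(beta * sqrt_pow, 1.0)
            hit = np.abs(z) > params.z_threshold
            if keep_ledger:
                ledger_rows.append(
                    pd.DataFrame(
                        {
                            "s": grid.s[k],
                            "p": p,
                            "beta": beta,
                            "z": z,
                            "is_hit": hit,
                        }
                    )
                )
            if hit.any():
                maf_parts.append(p[hit])
                z_parts.append(z[hit])
                s_parts.append(np.full(int(hit.sum()), grid.s[k]))

    if maf_parts:
        maf = np.concatenate(maf_parts)
        z = np.concatenate(z_parts)
        order = rng.permutation(len(maf))  # decouple row order from s loop
        maf, z = maf[order], z[order]
        df = pd.DataFrame(
            {
                "trait": params.trait,
                "variant": [f"v{i:06d}" for i in range(len(maf))],
                "maf": maf,
                "z": z,
                "block": rng.integers(0, n_blocks, size=len(maf)),
            }
        )
        hits = HitTable(df, {params.trait: meta})
    else:
        hits = _empty_hits(params.trait, meta)
    ledger = (
        pd.concat(ledger_rows, ignore_index=True)
        if keep_ledger and ledger_rows
        else (pd.DataFrame(columns=["s", "p", "beta", "z", "is_hit"]) if keep_ledger else None)
    )
    return SimulatedHits(
        hits, params, c, L, n_seg_total, n_common_total, seg_hist, ledger
    )


def simulate_hits(
    params: TraitParams,
    fs: SplineFS,
    table: SFSTable,
    seed,
    n_blocks: int = 100,
    n_s: int = 48,
    keep_ledger: bool = False,
    site_sampling: str = "fixed",
    grid: ModelGrid | None = None,
) -> SimulatedHits:
    """Draw L sites from the pleiotropic model and return the ascertained hits."""
    return _simulate(
        params, fs, table, seed, False, n_blocks, n_s, keep_ledger,
        site_sampling, grid,
    )


def simulate_hits_one_dimensional(
    params: TraitParams,
    fs: SplineFS,
    table: SFSTable,
    seed,
    n_blocks: int = 100,
    n_s: int = 48,
    keep_ledger: bool = False,
    site_sampling: str = "fixed",
    grid: ModelGrid | None = None,
) -> SimulatedHits:
    """No-pleiotropy variant: deterministic effect magnitude given s."""
    return _simulate(
        params, fs, table, seed, True, n_blocks, n_s, keep_ledger,
        site_sampling, grid,
    )


def power_projection(
    params: TraitParams,
    fs: SplineFS,
    table: SFSTable,
    n_grid,
    reps: int = 10,
    seed=0,
    n_s: int = 48,
) -> pd.DataFrame:
    """Median ascertained hit count across ``reps`` simulations per sample size."""
    n_grid = list(n_grid)
    if not n_grid:
        raise ValueError("n_grid must be non-empty")
    rng_seq = np.random.SeedSequence(seed).spawn(len(n_grid) * reps)
    grid = ModelGrid(fs, table, n_s=n_s, maf_threshold=params.maf_threshold)
    rows = []
    it = iter(rng_seq)
    for n in n_grid:
        p_n = replace(params, N=float(n))
        counts = []
        for _ in range(reps):
            if n == 0:
                counts.append(0)
                next(it)
                continue
            sim = simulate_hits(p_n, fs, table, next(it), grid=grid)
            counts.append(sim.n_hits)
        rows.append(
            {
                "n": n,
                "median_hits": float(np.median(counts)),
                "hits": counts,
            }
        )
    return pd.DataFrame(rows)


def l_sweep(
    params: TraitParams,
    fs: SplineFS,
    table: SFSTable,
    L_values,
    seed=0,
    n_s: int = 48,
) -> dict[float, SimulatedHits]:
    """Simulate the trait at several mutational target sizes, h2 and N fixed."""
    out = {}
    children = np.random.SeedSequence(seed).spawn(len(list(L_values)))
    grid = ModelGrid(fs, table, n_s=n_s, maf_threshold=params.maf_threshold)
    for child, L in zip(children, L_values):
        p_l = replace(params, L=float(L))
        out[float(L)] = simulate_hits(p_l, fs, table, child, grid=grid)
    return out


def ecdf(values, grid) -> np.ndarray:
    """Right-continuous empirical CDF of ``values`` evaluated on ``grid``."""
    values = np.sort(np.asarray(values, dtype=float))
    grid = np.asarray(grid, dtype=float)
    return np.searchsorted(values, grid, side="right") / max(len(values), 1)
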