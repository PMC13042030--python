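"""Maximum-likelihood inference of f(s), h2 and L from ascertained hits.

The per-hit log-likelihood is the ascertainment-corrected ratio

    LL_hit = log P(z, p | h2, L, f(s)) - log P(hit | h2, L, f(s)),

with numerator integrand phi(z; 0, 1 + c s 2p(1-p) N) P(p | s) f(s) seg(s)
and denominator the double integral of the same over |z| > z_threshold and
p > maf_threshold. The trait-specific constant c = h2 / (L E[seg s 2p(1-p)])
ties effect variance to heritability per site. The trait objective adds a
Poisson term for the observed hit count, n log(L P(hit)) - L P(hit), which
separates h2 from L (the conditional hit likelihood alone identifies only
their ratio), and subtracts the penalty 0.05 (L / 3e8 + h2 / 1) that keeps
estimates inside plausible ranges when the likelihood is flat.

A group of traits shares one f(s): the outer optimization moves the four
spline knot values (positions fixed on log10 s), the inner loop profiles
each trait's (h2, L) by nested one-dimensional searches on log scales.
Alternative effect-size models (frequency-independent normal, and the
alpha-model with Var(beta | p) proportional to (2p(1-p))^alpha) share the
machinery with p drawn from the neutral SFS. Confidence envelopes come from
resampling genomic blocks with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm

from .architecture import (
    MAF_THRESHOLD,
    Z_THRESHOLD,
    CommonBins,
    HitTable,
    ModelGrid,
)
from .sfs import SFSTable
from .spline_fs import SplineFS


@dataclass(frozen=True)
class InferenceConfig:
    """Grids, penalty constants, optimizer settings and bootstrap sizes."""

    n_s: int = 32
    n_p_quad: int = 4
    knot_log10s: tuple | None = None  # None: spread evenly over the s grid
    support: tuple | None = None  # None: the table's positive s range
    fs_n_quad: int = 96
    penalty_scale: float = 0.05
    penalty_l: float = 3e8
    penalty_h2: float = 1.0
    l_bounds_log10: tuple = (3.0, 9.5)
    h2_bounds: tuple = (1e-3, 0.99)
    use_hit_count: bool = True
    n_starts: int = 8
    start_spread: float = 1.5
    nm_maxiter: int = 150
    nm_xatol: float = 0.05
    nm_fatol: float = 1e-3
    outer_xatol: float = 0.02
    outer_maxiter: int = 30
    inner_xatol: float = 1e-3
    inner_maxiter: int = 25
    min_hits: int = 20
    bootstrap_b: int = 50
    bootstrap_starts: int = 1
    sigma2_bounds_log10: tuple = (-8.0, 0.0)
    alpha_bounds: tuple = (-1.0, 0.0)
    z_threshold: float = Z_THRESHOLD
    maf_threshold: float = MAF_THRESHOLD

    def knots_for(self, table: SFSTable) -> np.ndarray:
        if self.knot_log10s is not None:
            return np.asarray(self.knot_log10s, dtype=float)
        pos = table.positive_s
        return np.linspace(np.log10(pos.min()), np.log10(pos.max()), 4)

    def support_for(self, table: SFSTable) -> tuple[float, float]:
        if self.support is not None:
            return self.support
        pos = table.positive_s
        return float(pos.min()), float(pos.max())


@dataclass
class TraitFit:
    trait: str
    h2_hat: float
    l_hat: float
    c_hat: float
    ll: float
    n_hits: int
    converged: bool

    @property
    def h2_over_l(self) -> float:
        return self.h2_hat / self.l_hat


@dataclass
class GroupFit:
    fs: SplineFS
    knot_values: np.ndarray
    trait_fits: list
    total_ll: float
    envelopes: dict | None = None


@dataclass
class AlternativeFit:
    model: str  # "normal" | "alpha"
    trait: str
    sigma2: float
    alpha: float
    l_hat: float
    implied_h2: float
    ll: float
    n_hits: int
    converged: bool


# ---------------------------------------------------------------------------
# likelihood engines
# ---------------------------------------------------------------------------


def _single_trait(hits: HitTable) -> tuple[str, float]:
    traits = hits.traits()
    if len(traits) != 1:
        raise ValueError("expected a single-trait hit table")
    trait = traits[0]
    meta = hits.meta.get(trait, {})
    if "n" not in meta:
        raise ValueError(f"trait {trait} lacks sample size 'n' in metadata")
    return trait, float(meta["n"])


class _TraitEngine:
    """Per-trait precomputation shared across likelihood evaluations."""

    def __init__(self, hits: HitTable, table: SFSTable, config: InferenceConfig):
        self.trait, self.N = _single_trait(hits)
        df = hits.df
        if len(df) < 1:
            raise ValueError("empty hit table")
        z = df["z"].to_numpy(dtype=float)
        p = df["maf"].to_numpy(dtype=float)
        if np.any(np.abs(z) <= config.z_threshold) or np.any(
            (p <= config.maf_threshold) | (p > 0.5)
        ):
            raise ValueError("hit table violates the ascertainment predicate")
        self.z = z
        self.p = p
        self.twopq = 2.0 * p * (1.0 - p)
        self.bin = table.bin_index(p)
        widths = np.log(table.bin_edges[1:] / table.bin_edges[:-1])
        # density jacobian of the log-uniform within-bin law
        self.log_jac = -np.log(p * widths[self.bin])
        self.n = len(z)
        self.blocks = df["block"].to_numpy()
        self.config = config
        self.table = table

    def bind(self, grid: ModelGrid) -> "_BoundStabilizing":
        return _BoundStabilizing(self, grid)


class _BoundStabilizing:
    """Engine bound to one f(s) discretization; evaluations vary only c."""

    def __init__(self, engine: _TraitEngine, grid: ModelGrid):
        self.engine = engine
        self.grid = grid
        ws = grid.w * grid.seg
        with np.errstate(divide="ignore"):
            self.logA = np.log(ws[:, None] * grid.mass[:, engine.bin])
        self.s2pq = grid.s[:, None] * engine.twopq[None, :] * engine.N
        self.B = ws[:, None] * (grid.mass[:, grid.common_cols] * grid.common_frac)
        self.node_s2pq = (
            grid.s[:, None, None] * grid.twopq_nodes[None, :, :] * engine.N
        )
        self.node_w = grid.p_node_w
        self.z2 = engine.z**2
        self.thr = engine.config.z_threshold

    def p_hit(self, c: float) -> float:
        var = 1.0 + c * self.node_s2pq
        tail = 2.0 * norm.sf(self.thr / np.sqrt(var))
        per_bin = (tail * self.node_w[None, :, :]).sum(axis=2)
        return float((self.B * per_bin).sum())

    def per_hit_lognum(self, c: float) -> np.ndarray:
        var = 1.0 + c * self.s2pq
        logdens = -self.z2[None, :] / (2.0 * var) - 0.5 * np.log(
            2.0 * np.pi * var
        )
        return logsumexp(self.logA + logdens, axis=0) + self.engine.log_jac

    def conditional_ll(self, c: float) -> tuple[float, float]:
        ph = self.p_hit(c)
        if not np.isfinite(ph) or ph <= 0:
            return -np.inf, 0.0
        lognum = self.per_hit_lognum(c)
        return float(lognum.sum() - self.engine.n * np.log(ph)), ph


def _trait_objective(
    bound: _BoundStabilizing,
    integral: float,
    h2: float,
    L: float,
    config: InferenceConfig,
) -> float:
    c = h2 / (L * integral)
    ll, ph = bound.conditional_ll(c)
    if not np.isfinite(ll):
        return -np.inf
    if config.use_hit_count:
        lam = L * ph
        if lam <= 0:
            return -np.inf
        ll += bound.engine.n * np.log(lam) - lam
    ll -= config.penalty_scale * (
        L / config.penalty_l + h2 / config.penalty_h2
    )
    return ll


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def hit_loglik(
    z,
    p,
    h2: float,
    L: float,
    N: float,
    fs: SplineFS,
    table: SFSTable,
    config: InferenceConfig | None = None,
):
    """Ascertainment-corrected log-likelihood of hits at (z, p).

    Scalar in, scalar out; arrays in, per-hit array out. Inputs must satisfy
    the ascertainment predicate.
    """
    config = config or InferenceConfig()
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    import pandas as pd

    df = pd.DataFrame(
        {
            "trait": "t",
            "variant": [f"v{i}" for i in range(len(z_arr))],
            "maf": p_arr,
            "z": z_arr,
            "block": 0,
        }
    )
    hits = HitTable(df, {"t": {"n": N}})
    engine = _TraitEngine(hits, table, config)
    grid = ModelGrid(
        fs, table, n_s=config.n_s, maf_threshold=config.maf_threshold,
        n_p_quad=config.n_p_quad,
    )
    integral = grid.heritability_integral()
    c = h2 / (L * integral)
    bound = engine.bind(grid)
    ph = bound.p_hit(c)
    out = bound.per_hit_lognum(c) - np.log(ph)
    return float(out[0]) if np.isscalar(z) else out


def hit_cell_probability(
    z_lo: float,
    z_hi: float,
    p_lo: float,
    p_hi: float,
    h2: float,
    L: float,
    N: float,
    fs: SplineFS,
    table: SFSTable,
    config: InferenceConfig | None = None,
) -> float:
    """P(|z| in [z_lo, z_hi], p in [p_lo, p_hi] | hit) under the model.

    The p-interval is intersected with each frequency bin; used to compare
    the analytic ascertained density against brute-force simulation.
    """
    config = config or InferenceConfig()
    grid = ModelGrid(
        fs, table, n_s=config.n_s, maf_threshold=config.maf_threshold,
        n_p_quad=config.n_p_quad,
    )
    integral = grid.heritability_integral()
    c = h2 / (L * integral)
    ws = grid.w * grid.seg
    z_lo = max(z_lo, config.z_threshold)

    def z_part(var, lo, hi):
        sd = np.sqrt(var)
        return 2.0 * (norm.sf(lo / sd) - norm.sf(hi / sd))

    total = 0.0
    denom = 0.0
    for j, col in enumerate(grid.common_cols):
        a, b = grid.common_lo[j], grid.common_hi[j]
        # full-bin denominator contribution via the bin's quadrature nodes
        var_nodes = 1.0 + c * grid.s[:, None] * grid.twopq_nodes[j][None, :] * N
        tail_full = (
            z_part(var_nodes, config.z_threshold, np.inf) * grid.p_node_w[j]
        ).sum(axis=1)
        denom += float((ws * grid.mass[:, col] * grid.common_frac[j] * tail_full).sum())
        lo, hi = max(a, p_lo), min(b, p_hi)
        if lo >= hi:
            continue
        # overlap mass fraction relative to the FULL bin's log width (the
        # bin mass lives on the full bin under the log-uniform law)
        frac = np.log(hi / lo) / grid.log_widths[col]
        # quadrature on the overlapping part
        x, wq = np.polynomial.legendre.leggauss(config.n_p_quad)
        la, lb = np.log(lo), np.log(hi)
        p_nodes = np.exp(0.5 * (lb - la) * x + 0.5 * (la + lb))
        tw = 2.0 * p_nodes * (1.0 - p_nodes)
        var = 1.0 + c * grid.s[:, None] * tw[None, :] * N
        tail = (z_part(var, z_lo, z_hi) * (wq / wq.sum())[None, :]).sum(axis=1)
        total += float((ws * grid.mass[:, col] * frac * tail).sum())
    return total / denom


def fit_trait(
    hits: HitTable,
    fs: SplineFS,
    table: SFSTable,
    config: InferenceConfig | None = None,
    grid: ModelGrid | None = None,
) -> TraitFit:
    """Penalized ML for (h2, L) at a fixed f(s): nested 1-D searches.

    Outer bounded search on log10 L, inner on h2; non-convergence is flagged
    on the returned fit rather than raised.
    """
    config = config or InferenceConfig()
    if len(hits) < config.min_hits:
        raise ValueError(
            f"need at least {config.min_hits} hits, got {len(hits)}"
        )
    engine = _TraitEngine(hits, table, config)
    if grid is None:
        grid = ModelGrid(
            fs, table, n_s=config.n_s, maf_threshold=config.maf_threshold,
            n_p_quad=config.n_p_quad,
        )
    bound = engine.bind(grid)
    integral = grid.heritability_integral()
    if not np.isfinite(integral) or integral <= 0:
        raise ValueError("degenerate model: E[seg * s * 2p(1-p)] <= 0")
    return _fit_trait_bound(bound, integral, config, engine.trait)


def _fit_trait_bound(
    bound: _BoundStabilizing,
    integral: float,
    config: InferenceConfig,
    trait: str,
) -> TraitFit:
    def inner(log_l: float):
        L = 10.0**log_l
        res = minimize_scalar(
            lambda h2: -_trait_objective(bound, integral, h2, L, config),
            bounds=config.h2_bounds,
            method="bounded",
            options={
                "xatol": config.inner_xatol,
                "maxiter": config.inner_maxiter,
            },
        )
        return res

    outer = minimize_scalar(
        lambda lg: inner(lg).fun,
        bounds=config.l_bounds_log10,
        method="bounded",
        options={"xatol": config.outer_xatol, "maxiter": config.outer_maxiter},
    )
    log_l = float(outer.x)
    res_in = inner(log_l)
    h2 = float(res_in.x)
    L = 10.0**log_l
    ll = -float(res_in.fun)
    converged = bool(outer.success and res_in.success and np.isfinite(ll))
    return TraitFit(
        trait=trait,
        h2_hat=h2,
        l_hat=L,
        c_hat=h2 / (L * integral),
        ll=ll,
        n_hits=bound.engine.n,
        converged=converged,
    )


def _as_trait_list(traits) -> list[HitTable]:
    if isinstance(traits, HitTable):
        names = traits.traits()
        if len(names) == 1:
            return [traits]
        return [traits.for_trait(t) for t in names]
    return list(traits)


def fit_group(
    traits,
    table: SFSTable,
    config: InferenceConfig | None = None,
    seed=0,
    init_knot_values: np.ndarray | None = None,
) -> GroupFit:
    """Shared-f(s) fit: simplex over four knot values, per-trait (h2, L).

    Multiple scattered simplex starts (count from config); the best total
    penalized log-likelihood wins, ties broken by the earliest start. The
    knot-value vector carries an additive gauge freedom (the density is
    normalized), removed by centering.
    """
    config = config or InferenceConfig()
    trait_tables = _as_trait_list(traits)
    if not trait_tables:
        raise ValueError("need at least one trait")
    engines = [_TraitEngine(t, table, config) for t in trait_tables]
    knots = config.knots_for(table)
    support = config.support_for(table)

    def group_ll(kv: np.ndarray) -> tuple[float, list[TraitFit]]:
        kv = kv - kv.mean()
        if np.any(np.abs(kv) > 25):
            return -np.inf, []
        fs = SplineFS(
            knot_values=kv, knot_log10s=knots, support=support,
            n_quad=config.fs_n_quad,
        )
        grid = ModelGrid(
            fs, table, n_s=config.n_s, maf_threshold=config.maf_threshold,
            n_p_quad=config.n_p_quad,
        )
        integral = grid.heritability_integral()
        if not np.isfinite(integral) or integral <= 0:
            return -np.inf, []
        fits = []
        total = 0.0
        for eng in engines:
            fit = _fit_trait_bound(eng.bind(grid), integral, config, eng.trait)
            fits.append(fit)
            total += fit.ll
        return total, fits

    rng = np.random.default_rng(seed)
    starts = [np.zeros(4)] if init_knot_values is None else [
        np.asarray(init_knot_values, dtype=float)
    ]
    while len(starts) < config.n_starts:
        starts.append(rng.normal(0.0, config.start_spread, size=4))

    best = None
    for idx, x0 in enumerate(starts):
        res = minimize(
            lambda kv: -group_ll(kv)[0],
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": config.nm_maxiter,
                "xatol": config.nm_xatol,
                "fatol": config.nm_fatol,
            },
        )
        if best is None or res.fun < best[0] - 1e-12:
            best = (res.fun, idx, res.x)
    kv = best[2] - best[2].mean()
    total, fits = group_ll(kv)
    fs = SplineFS(
        knot_values=kv, knot_log10s=knots, support=support,
        n_quad=config.fs_n_quad,
    )
    return GroupFit(fs=fs, knot_values=kv, trait_fits=fits, total_ll=total)


# ---------------------------------------------------------------------------
# alternative effect-size models
# ---------------------------------------------------------------------------


class _BoundFrequencyCoupled:
    """Neutral-SFS engine for the normal and alpha effect-size models."""

    def __init__(self, engine: _TraitEngine, table: SFSTable, config: InferenceConfig):
        i0 = np.nonzero(table.s_values == 0.0)[0]
        if not i0.size:
            raise ValueError("table lacks a neutral (s=0) row")
        i0 = int(i0[0])
        self.engine = engine
        self.mass0 = table.mass[i0]
        self.seg0 = float(table.seg_prob[i0])
        bins = CommonBins(
            table, maf_threshold=config.maf_threshold, n_p_quad=config.n_p_quad
        )
        self.common_cols = bins.common_cols
        self.common_frac = bins.common_frac
        self.twopq_nodes = bins.twopq_nodes
        self.node_w = bins.p_node_w
        self.mean2pq = bins.mean2pq
        with np.errstate(divide="ignore"):
            self.logA0 = np.log(self.seg0 * self.mass0[engine.bin])
        self.z2 = engine.z**2
        self.thr = config.z_threshold
        self.config = config

    def p_hit(self, sigma2: float, alpha: float) -> float:
        v = sigma2 * self.twopq_nodes ** (1.0 + alpha) * self.engine.N
        tail = 2.0 * norm.sf(self.thr / np.sqrt(1.0 + v))
        per_bin = (tail * self.node_w).sum(axis=1)
        return float(
            self.seg0
            * (self.mass0[self.common_cols] * self.common_frac * per_bin).sum()
        )

    def conditional_ll(self, sigma2: float, alpha: float) -> tuple[float, float]:
        ph = self.p_hit(sigma2, alpha)
        if ph <= 0:
            return -np.inf, 0.0
        v = sigma2 * self.engine.twopq ** (1.0 + alpha) * self.engine.N
        var = 1.0 + v
        lognum = (
            self.logA0
            - self.z2 / (2.0 * var)
            - 0.5 * np.log(2.0 * np.pi * var)
            + self.engine.log_jac
        )
        return float(lognum.sum() - self.engine.n * np.log(ph)), ph

    def implied_h2(self, sigma2: float, alpha: float, L: float) -> float:
        e2pq = float(
            (self.mass0 * self.mean2pq ** (1.0 + alpha)).sum()
        )
        return L * self.seg0 * sigma2 * e2pq

    def objective(self, sigma2: float, alpha: float) -> tuple[float, float]:
        """Profile L in closed form; return (objective, L*)."""
        cfg = self.config
        ll, ph = self.conditional_ll(sigma2, alpha)
        if not np.isfinite(ll):
            return -np.inf, 1.0
        n = self.engine.n
        e2pq = float((self.mass0 * self.mean2pq ** (1.0 + alpha)).sum())
        lin = cfg.penalty_scale / cfg.penalty_l + (
            cfg.penalty_scale / cfg.penalty_h2
        ) * self.seg0 * sigma2 * e2pq
        if cfg.use_hit_count:
            l_star = n / (ph + lin)
            l_star = float(
                np.clip(l_star, 10.0 ** cfg.l_bounds_log10[0],
                        10.0 ** cfg.l_bounds_log10[1])
            )
            ll += n * np.log(l_star * ph) - l_star * ph - lin * l_star
        else:
            l_star = 10.0 ** cfg.l_bounds_log10[0]
            ll -= lin * l_star
        return ll, l_star


def _fit_frequency_coupled(
    hits: HitTable,
    table: SFSTable,
    config: InferenceConfig,
    fixed_alpha: float | None,
    model: str,
) -> AlternativeFit:
    if len(hits) < config.min_hits:
        raise ValueError(
            f"need at least {config.min_hits} hits, got {len(hits)}"
        )
    engine = _TraitEngine(hits, table, config)
    bound = _BoundFrequencyCoupled(engine, table, config)
    lo, hi = config.sigma2_bounds_log10

    if fixed_alpha is None and config.alpha_bounds[0] == config.alpha_bounds[1]:
        fixed_alpha = float(config.alpha_bounds[0])
    if fixed_alpha is not None:
        res = minimize_scalar(
            lambda ls: -bound.objective(10.0**ls, fixed_alpha)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": config.inner_xatol, "maxiter": 60},
        )
        sigma2, alpha = 10.0 ** float(res.x), fixed_alpha
        converged = bool(res.success)
    else:
        a_lo, a_hi = config.alpha_bounds

        def neg(x):
            ls, a = x
            if not (lo <= ls <= hi and a_lo <= a <= a_hi):
                return np.inf
            return -bound.objective(10.0**ls, a)[0]

        best = None
        for x0 in ([-2.0, -0.2], [-4.0, -0.6], [-1.0, 0.0]):
            res = minimize(
                neg, np.array(x0), method="Nelder-Mead",
                options={"maxiter": config.nm_maxiter, "xatol": 1e-3,
                         "fatol": 1e-4},
            )
            if best is None or res.fun < best.fun:
                best = res
        sigma2, alpha = 10.0 ** float(best.x[0]), float(best.x[1])
        converged = bool(best.success)

    obj, l_star = bound.objective(sigma2, alpha)
    return AlternativeFit(
        model=model,
        trait=engine.trait,
        sigma2=sigma2,
        alpha=alpha,
        l_hat=l_star,
        implied_h2=bound.implied_h2(sigma2, alpha, l_star),
        ll=obj,
        n_hits=engine.n,
        converged=converged,
    )


def fit_alternative_normal(
    hits: HitTable, table: SFSTable, config: InferenceConfig | None = None
) -> AlternativeFit:
    """Frequency-independent normal effect model, p from the neutral SFS."""
    config = config or InferenceConfig()
    return _fit_frequency_coupled(hits, table, config, 0.0, "normal")


def fit_alternative_alpha(
    hits: HitTable, table: SFSTable, config: InferenceConfig | None = None
) -> AlternativeFit:
    """Alpha-model: Var(beta | p) = sigma2 (2p(1-p))^alpha with alpha <= 0."""
    config = config or InferenceConfig()
    return _fit_frequency_coupled(hits, table, config, None, "alpha")


# ---------------------------------------------------------------------------
# fitted-model objects for residual diagnostics
# ---------------------------------------------------------------------------


@dataclass
class FittedStabilizing:
    """Frozen stabilizing-selection model: supports residual tail queries."""

    fs: SplineFS
    h2: float
    L: float
    N: float
    table: SFSTable
    config: InferenceConfig = field(default_factory=InferenceConfig)

    def __post_init__(self) -> None:
        self._grid = ModelGrid(
            self.fs, self.table, n_s=self.config.n_s,
            maf_threshold=self.config.maf_threshold,
            n_p_quad=self.config.n_p_quad,
        )
        self._c = self.h2 / (self.L * self._grid.heritability_integral())

    @property
    def c(self) -> float:
        return self._c

    def residual_tail(self, z, p) -> np.ndarray:
        """Pr(|Z| > |z| | hit at MAF p) with f(s | p) weighting."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        p = np.atleast_1d(np.asarray(p, dtype=float))
        g = self._grid
        cols = self.table.bin_index(p)
        W = (g.w * g.seg)[:, None] * g.mass[:, cols]
        twopq = 2.0 * p * (1.0 - p)
        var = 1.0 + self._c * g.s[:, None] * twopq[None, :] * self.N
        sd = np.sqrt(var)
        num = (W * 2.0 * norm.sf(np.abs(z)[None, :] / sd)).sum(axis=0)
        den = (W * 2.0 * norm.sf(self.config.z_threshold / sd)).sum(axis=0)
        return num / den


@dataclass
class FittedFrequencyCoupled:
    """Frozen normal/alpha model for residual tail queries."""

    sigma2: float
    alpha: float
    N: float
    config: InferenceConfig = field(default_factory=InferenceConfig)

    def residual_tail(self, z, p) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        p = np.atleast_1d(np.asarray(p, dtype=float))
        twopq = 2.0 * p * (1.0 - p)
        var = 1.0 + self.sigma2 * twopq ** (1.0 + self.alpha) * self.N
        sd = np.sqrt(var)
        return norm.sf(np.abs(z) / sd) / norm.sf(self.config.z_threshold / sd)


def fitted_model_from_trait(
    fit: TraitFit | AlternativeFit,
    fs: SplineFS | None,
    table: SFSTable,
    N: float,
    config: InferenceConfig | None = None,
):
    """Package a fit result as a frozen model for diagnostics."""
    config = config or InferenceConfig()
    if isinstance(fit, TraitFit):
        if fs is None:
            raise ValueError("stabilizing model needs its f(s)")
        return FittedStabilizing(
            fs=fs, h2=fit.h2_hat, L=fit.l_hat, N=N, table=table, config=config
        )
    return FittedFrequencyCoupled(
        sigma2=fit.sigma2, alpha=fit.alpha, N=N, config=config
    )


# ---------------------------------------------------------------------------
# block bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapEnvelopes:
    knot_values: np.ndarray  # (B, 4), gauge-centered
    h2: np.ndarray  # (B, n_traits)
    l: np.ndarray  # (B, n_traits)
    traits: list

    def quantiles(self, q=(0.05, 0.95)) -> dict:
        q = list(q)
        return {
            "knot_values": np.quantile(self.knot_values, q, axis=0),
            "h2": np.quantile(self.h2, q, axis=0),
            "l": np.quantile(self.l, q, axis=0),
            "h2_over_l": np.quantile(self.h2 / self.l, q, axis=0),
        }


def _resample_blocks(hits: HitTable, rng: np.random.Generator) -> HitTable:
    df = hits.df
    blocks = df["block"].unique()
    if len(blocks) < 2:
        raise ValueError("cannot resample with a single genomic block")
    chosen = rng.choice(blocks, size=len(blocks), replace=True)
    parts = [df[df["block"] == b] for b in chosen]
    import pandas as pd

    out = pd.concat(parts, ignore_index=True)
    return HitTable(out, hits.meta)


def bootstrap_blocks(
    traits,
    table: SFSTable,
    config: InferenceConfig | None = None,
    seed=0,
    B: int | None = None,
    resample: bool = True,
    point: GroupFit | None = None,
) -> BootstrapEnvelopes:
    """Refit the group on block-resampled hit tables; collect envelopes.

    ``resample=False`` refits the original tables (identity resample), so a
    single replicate collapses onto the point estimate. Bootstrap refits
    start from the point estimate with a reduced start count.
    """
    config = config or InferenceConfig()
    B = B if B is not None else config.bootstrap_b
    trait_tables = _as_trait_list(traits)
    rng = np.random.default_rng(seed)
    if point is None:
        point = fit_group(trait_tables, table, config, seed=seed)
    boot_cfg = replace(config, n_starts=config.bootstrap_starts)
    kvs, h2s, ls = [], [], []
    for b in range(B):
        if resample:
            tabs = [_resample_blocks(t, rng) for t in trait_tables]
        else:
            tabs = trait_tables
        gf = fit_group(
            tabs, table, boot_cfg, seed=rng.integers(2**31 - 1),
            init_knot_values=point.knot_values,
        )
        kvs.append(gf.knot_values)
        h2s.append([f.h2_hat for f in gf.trait_fits])
        ls.append([f.l_hat for f in gf.trait_fits])
    return BootstrapEnvelopes(
        knot_values=np.array(kvs),
        h2=np.array(h2s),
        l=np.array(ls),
        traits=[f.trait for f in point.trait_fits],
    )
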