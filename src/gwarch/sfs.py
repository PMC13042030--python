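"""Allele-frequency distributions P(p | s) under selection and demography.

The sampler tracks individual mutations forward in time through a
piecewise-constant demography under underdominant (heterozygote-disadvantage)
selection, the per-variant selection mode induced by pleiotropic stabilizing
selection on traits. Genotype fitnesses are (1, 1-s, 1) for
(minor-hom, het, major-hom); the deterministic update for minor-allele
frequency q is

    dq = -s q (1-q) (1-2q) / wbar,   wbar = 1 - 2 s q (1-q),

followed by binomial drift with 2N draws.

Each replicate is one mutation injected at a generation drawn with
probability proportional to 2N_t across the burn-in and all epochs (mutational
opportunity is proportional to the number of chromosomes), started at
frequency 1/(2N_t) and tracked to the present. The folded frequencies of the
mutations still segregating at sampling time estimate the segregating-
conditional SFS, and

    seg_prob = mu * sum_t 2N_t * Pr(segregating at present | injection)

is the per-site probability that a mutational opportunity carries a
segregating variant, exact in the small-theta limit where at most one
mutation per site survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .demography import DemographicModel

DEFAULT_MUTATION_RATE = 1.25e-8


@dataclass(frozen=True)
class SelectionGrid:
    """Strictly increasing selection coefficients; may start at 0 (neutral)."""

    s_values: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s_values, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("selection grid must be a non-empty 1-D array")
        if np.any(~np.isfinite(s)) or np.any(s < 0):
            raise ValueError("selection coefficients must be finite and >= 0")
        if np.any(np.diff(s) <= 0):
            raise ValueError("selection grid must be strictly increasing")
        if np.any(s >= 1):
            raise ValueError("selection coefficients must be < 1")
        object.__setattr__(self, "s_values", s)

    @classmethod
    def log_spaced(
        cls,
        s_min: float = 1e-6,
        s_max: float = 1e-1,
        n: int = 64,
        include_neutral: bool = True,
    ) -> "SelectionGrid":
        s = np.geomspace(s_min, s_max, n)
        if include_neutral:
            s = np.concatenate([[0.0], s])
        return cls(s)

    @classmethod
    def toy(cls) -> "SelectionGrid":
        """Grid paired with the toy demography (2N*s spans ~0.8 to 1e3)."""
        return cls.log_spaced(1e-4, 0.25, 12, include_neutral=True)

    @property
    def positive(self) -> np.ndarray:
        return self.s_values[self.s_values > 0]

    def __len__(self) -> int:
        return len(self.s_values)


def default_bin_edges(demography: DemographicModel, n_bins: int = 100) -> np.ndarray:
    """Log-spaced minor-allele-frequency bins on (1/(2*2N_final), 0.5]."""
    lo = 1.0 / (4.0 * demography.final_size)
    return np.geomspace(lo, 0.5, n_bins + 1)


def bin_mean_2pq(edges: np.ndarray) -> np.ndarray:
    """E[2p(1-p)] per bin under the log-uniform within-bin law.

    For p log-uniform on (a, b]: E[p] = (b-a)/ln(b/a) and
    E[p^2] = (b^2-a^2)/(2 ln(b/a)).
    """
    a, b = edges[:-1], edges[1:]
    lr = np.log(b / a)
    ep = (b - a) / lr
    ep2 = (b * b - a * a) / (2.0 * lr)
    return 2.0 * (ep - ep2)


@dataclass
class SFSSimResult:
    """Output of one forward simulation at a single selection coefficient."""

    bin_edges: np.ndarray
    mass: np.ndarray  # normalized over bins, conditional on segregating
    seg_prob: float
    n_segregating: int
    n_replicates: int


def _simulate_survivor_frequencies(
    traj: np.ndarray, s: float, replicates: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Track injected mutations to the present; return surviving minor freqs.

    Returns (folded frequencies of survivors, total mutational opportunity
    weight W = sum_t 2N_t).
    """
    two_n = 2 * traj
    w_total = float(two_n.sum())
    t_total = len(traj)
    # injection generation per replicate, weighted by chromosome count
    probs = two_n / w_total
    t_inj = rng.choice(t_total, size=replicates, p=probs)
    t_inj.sort()
    ptr = 0
    active = np.empty(0, dtype=float)
    # Generation t: first drift the standing mutations from t-1 into t, then
    # add the mutations arising in t itself, so a mutation arising in the
    # sampling generation is a present-day singleton (this ordering gives the
    # correct singleton sojourn weight).
    for t in range(t_total):
        if active.size:
            if s != 0.0:
                pq = active * (1.0 - active)
                wbar = 1.0 - 2.0 * s * pq
                q_sel = active - s * pq * (1.0 - 2.0 * active) / wbar
            else:
                q_sel = active
            n_now = two_n[t]
            counts = rng.binomial(n_now, q_sel)
            keep = (counts > 0) & (counts < n_now)
            active = counts[keep] / n_now
        n_new = np.searchsorted(t_inj, t, side="right") - ptr
        if n_new:
            active = np.concatenate(
                [active, np.full(n_new, 1.0 / two_n[t], dtype=float)]
            )
            ptr += n_new
    return np.minimum(active, 1.0 - active), w_total


def simulate_frequency(
    demography: DemographicModel,
    s: float,
    replicates: int,
    seed,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    bin_edges: np.ndarray | None = None,
    panel_size: int | None = None,
) -> SFSSimResult:
    """Forward-simulate the folded frequency distribution at one ``s``.

    ``panel_size`` optionally resamples each surviving population frequency
    down to a GWAS panel of that many diploids (binomial with 2*panel_size
    draws) before folding and binning; survivors that resample to a
    monomorphic panel are counted as non-segregating.
    """
    if not np.isfinite(s) or s < 0:
        raise ValueError(f"selection coefficient must be finite and >= 0, got {s}")
    if s >= 1:
        raise ValueError("selection coefficient must be < 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if bin_edges is None:
        bin_edges = default_bin_edges(demography)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be a sorted 1-D array of length >= 2")

    rng = np.random.default_rng(seed)
    traj = demography.size_trajectory()
    maf, w_total = _simulate_survivor_frequencies(traj, s, replicates, rng)

    if panel_size is not None:
        two_n_panel = 2 * int(panel_size)
        # maf holds folded values; resampling is label-symmetric so folding
        # the binomial draw of the folded frequency is equivalent
        counts = rng.binomial(two_n_panel, maf)
        counts = np.minimum(counts, two_n_panel - counts)
        maf = counts[counts > 0] / two_n_panel

    # "segregating" means above the lowest bin edge
    maf = maf[maf > bin_edges[0]]
    n_seg = int(maf.size)
    hist, _ = np.histogram(maf, bins=bin_edges)
    if n_seg > 0:
        mass = hist / n_seg
    else:
        mass = np.zeros(len(bin_edges) - 1)
        mass[0] = 1.0  # degenerate placeholder; seg_prob below is ~0
    seg_prob = min(1.0, mutation_rate * w_total * (n_seg / replicates))
    return SFSSimResult(
        bin_edges=bin_edges,
        mass=mass,
        seg_prob=float(seg_prob),
        n_segregating=n_seg,
        n_replicates=replicates,
    )


@dataclass
class SFSTable:
    """Cached P(p | s) over a selection grid, rows conditional on segregating."""

    s_values: np.ndarray
    bin_edges: np.ndarray
    mass: np.ndarray  # shape (n_s, n_bins), rows sum to 1
    seg_prob: np.ndarray  # shape (n_s,)
    mutation_rate: float = DEFAULT_MUTATION_RATE
    demography_hash: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s_values = np.asarray(self.s_values, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        self.seg_prob = np.asarray(self.seg_prob, dtype=float)
        if self.mass.shape != (len(self.s_values), len(self.bin_edges) - 1):
            raise ValueError("mass matrix shape does not match grid and bins")
        sums = self.mass.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("each SFS row must sum to 1 within 1e-9")
        if np.any((self.seg_prob < 0) | (self.seg_prob > 1)):
            raise ValueError("seg_prob entries must lie in [0, 1]")

    # -- geometry helpers -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.mass.shape[1]

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def bin_mids(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def positive_s(self) -> np.ndarray:
        return self.s_values[self.s_values > 0]

    def bin_index(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p > 0.5)):
            raise ValueError("MAF must lie in (0, 0.5]")
        idx = np.searchsorted(self.bin_edges, p, side="left") - 1
        return np.clip(idx, -1, self.n_bins - 1)

    # -- interpolation ----------------------------------------------------
    def _interp_weights(self, s: float) -> tuple[int, int, float]:
        """Log-linear interpolation bracket among positive grid rows."""
        pos = self.s_values > 0
        sp = self.s_values[pos]
        offset = int(np.argmax(pos))
        if s < sp[0] or s > sp[-1]:
            warnings.warn(
                f"s={s:g} outside grid [{sp[0]:g}, {sp[-1]:g}]; clamped",
                stacklevel=3,
            )
            s = float(np.clip(s, sp[0], sp[-1]))
        j = int(np.searchsorted(sp, s, side="right")) - 1
        j = min(max(j, 0), len(sp) - 2)
        w = (np.log(s) - np.log(sp[j])) / (np.log(sp[j + 1]) - np.log(sp[j]))
        w = float(np.clip(w, 0.0, 1.0))
        return offset + j, offset + j + 1, w

    def row(self, s: float) -> tuple[np.ndarray, float]:
        """(bin masses, seg_prob) at ``s``, interpolating between grid rows."""
        exact = np.nonzero(np.isclose(self.s_values, s, rtol=1e-12, atol=0.0))[0]
        if s == 0.0 or exact.size:
            if not exact.size:
                raise ValueError("s=0 requested but neutral row absent from grid")
            i = int(exact[0])
            return self.mass[i], float(self.seg_prob[i])
        if s < 0:
            raise ValueError("selection coefficient must be >= 0")
        i, j, w = self._interp_weights(s)
        mass = (1.0 - w) * self.mass[i] + w * self.mass[j]
        tot = mass.sum()
        if tot > 0:
            mass = mass / tot
        # geometric interpolation: seg_prob spans orders of magnitude in s
        tiny = 1e-300
        seg = float(
            np.exp(
                (1.0 - w) * np.log(self.seg_prob[i] + tiny)
                + w * np.log(self.seg_prob[j] + tiny)
            )
        )
        return mass, seg

    def rows_at(self, s_nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized ``row`` over many positive s values."""
        masses = np.empty((len(s_nodes), self.n_bins))
        segs = np.empty(len(s_nodes))
        for k, s in enumerate(s_nodes):
            masses[k], segs[k] = self.row(float(s))
        return masses, segs

    def density(self, s: float, p: float) -> float:
        """Probability density of MAF ``p`` given ``s`` (segregating sites)."""
        p = float(p)
        if not (0 < p <= 0.5):
            raise ValueError("MAF must lie in (0, 0.5]")
        mass, _ = self.row(s)
        if p <= self.bin_edges[0]:
            return 0.0
        idx = int(self.bin_index(p))
        return float(mass[idx] / self.bin_widths[idx])

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# gwarch-sfs v1\n")
            fh.write(f"# demography_hash: {self.demography_hash}\n")
            fh.write(f"# mutation_rate: {self.mutation_rate:.12g}\n")
            for key in sorted(self.meta):
                fh.write(f"# meta {key}: {self.meta[key]}\n")
            fh.write(
                "# bin_edges: "
                + ",".join(f"{e:.12g}" for e in self.bin_edges)
                + "\n"
            )
            cols = "\t".join(f"m{i:03d}" for i in range(self.n_bins))
            fh.write(f"s\tseg_prob\t{cols}\n")
            for i, s in enumerate(self.s_values):
                row = "\t".join(f"{m:.12g}" for m in self.mass[i])
                fh.write(f"{s:.12g}\t{self.seg_prob[i]:.12g}\t{row}\n")

    @classmethod
    def load(cls, path) -> "SFSTable":
        meta: dict = {}
        demography_hash = ""
        mutation_rate = DEFAULT_MUTATION_RATE
        bin_edges = None
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# demography_hash:"):
                    demography_hash = line.split(":", 1)[1].strip()
                elif line.startswith("# mutation_rate:"):
                    mutation_rate = float(line.split(":", 1)[1])
                elif line.startswith("# meta "):
                    key, val = line[len("# meta ") :].split(":", 1)
                    meta[key.strip()] = val.strip()
                elif line.startswith("# bin_edges:"):
                    bin_edges = np.array(
                        [float(x) for x in line.split(":", 1)[1].split(",")]
                    )
                elif line.startswith("#") or line.startswith("s\t"):
                    continue
                elif line:
                    rows.append([float(x) for x in line.split("\t")])
        if bin_edges is None or not rows:
            raise ValueError(f"{path} is not a gwarch SFS cache")
        arr = np.array(rows)
        return cls(
            s_values=arr[:, 0],
            bin_edges=bin_edges,
            mass=arr[:, 2:],
            seg_prob=arr[:, 1],
            mutation_rate=mutation_rate,
            demography_hash=demography_hash,
            meta=meta,
        )


def sfs_lookup(table: SFSTable, s: float, p: float) -> float:
    """Density of MAF ``p`` given ``s`` (conditional on segregating)."""
    return table.density(s, p)


def build_sfs_table(
    demography: DemographicModel,
    grid: SelectionGrid,
    replicates: int,
    seed,
    bin_edges: np.ndarray | None = None,
    n_bins: int = 100,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    panel_size: int | None = None,
    cache_path=None,
) -> SFSTable:
    """Simulate every grid row and assemble (optionally caching) the table."""
    if len(grid) == 0:
        raise ValueError("selection grid is empty")
    if bin_edges is None:
        bin_edges = default_bin_edges(demography, n_bins=n_bins)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(grid))
    mass = np.empty((len(grid), len(bin_edges) - 1))
    seg = np.empty(len(grid))
    for i, s in enumerate(grid.s_values):
        res = simulate_frequency(
            demography,
            float(s),
            replicates,
            children[i],
            mutation_rate=mutation_rate,
            bin_edges=bin_edges,
            panel_size=panel_size,
        )
        if res.n_segregating == 0:
            warnings.warn(
                f"no segregating replicates at s={s:g}; row is degenerate",
                stacklevel=2,
            )
        mass[i] = res.mass / res.mass.sum()
        seg[i] = res.seg_prob
    table = SFSTable(
        s_values=grid.s_values,
        bin_edges=bin_edges,
        mass=mass,
        seg_prob=seg,
        mutation_rate=mutation_rate,
        demography_hash=demography.content_hash(),
        meta={
            "seed": str(seed),
            "replicates": str(replicates),
            "panel_size": "none" if panel_size is None else str(panel_size),
        },
    )
    if cache_path is not None:
        table.save(cache_path)
    return table


def neutral_folded_expectation(two_n: int, bin_edges: np.ndarray) -> np.ndarray:
    """Exact binned folded neutral SFS for a constant-size population.

    At stationarity with theta -> 0 the expected number of sites at derived
    count i is proportional to 1/i; folding combines i and 2N - i, so the
    segregating-conditional mass at minor count i is proportional to
    1/i + 1/(2N - i) (halved at i = N). Used as the classical oracle for the
    simulated neutral SFS.
    """
    counts = np.arange(1, two_n // 2 + 1)
    weights = 1.0 / counts + 1.0 / (two_n - counts)
    if two_n % 2 == 0:
        weights[-1] /= 2.0
    freqs = counts / two_n
    mass = np.zeros(len(bin_edges) - 1)
    idx = np.searchsorted(bin_edges, freqs, side="left") - 1
    ok = (idx >= 0) & (idx < len(mass)) & (freqs > bin_edges[0])
    np.add.at(mass, idx[ok], weights[ok])
    return mass / mass.sum()
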