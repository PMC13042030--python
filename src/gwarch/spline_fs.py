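"""Four-knot spline density f(s) of selection coefficients.

The density of selection coefficients for new trait-affecting mutations is
parameterized by log-density values at four fixed knot positions on log10 s.
Between knots the log-density is interpolated with a natural cubic spline;
beyond the outermost knots it is extended linearly with the end slopes and
clamped to zero outside the support. The density is normalized so that
its integral over the support is 1, so the four knot values carry three
effective degrees of freedom (an additive shift cancels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

# Full-scale default: one knot per decade across the s range that matters for
# human GWAS architectures.
DEFAULT_KNOT_LOG10S = (-5.0, -4.0, -3.0, -2.0)

# Desk-scale knots matching the package's toy demography, whose selection
# grid spans 1e-4 to 0.25 (selection is rescaled up as population size is
# rescaled down).
TOY_KNOT_LOG10S = (-3.5, -2.75, -2.0, -1.25)
TOY_SUPPORT = (1e-4, 0.25)


def _gauss_legendre_log(lo: float, hi: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights for integration in u = ln s over [lo, hi]."""
    x, w = np.polynomial.legendre.leggauss(n)
    a, b = np.log(lo), np.log(hi)
    u = 0.5 * (b - a) * x + 0.5 * (a + b)
    return np.exp(u), 0.5 * (b - a) * w * np.exp(u)  # ds = s du


@dataclass
class SplineFS:
    """f(s) with four knots on log10 s; ``knot_values`` are log-densities."""

    knot_values: np.ndarray
    knot_log10s: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_KNOT_LOG10S)
    )
    support: tuple[float, float] | None = None
    n_quad: int = 256

    def __post_init__(self) -> None:
        self.knot_values = np.asarray(self.knot_values, dtype=float)
        self.knot_log10s = np.asarray(self.knot_log10s, dtype=float)
        if self.knot_values.shape != self.knot_log10s.shape:
            raise ValueError("knot values and positions must match in length")
        if np.any(np.diff(self.knot_log10s) <= 0):
            raise ValueError("knot positions must be strictly increasing")
        if self.support is None:
            pad = 1.0  # one decade beyond the outer knots
            self.support = (
                10.0 ** (self.knot_log10s[0] - pad),
                10.0 ** (self.knot_log10s[-1] + pad),
            )
        lo, hi = self.support
        if not (0 < lo < hi):
            raise ValueError("support must satisfy 0 < lo < hi")
        self._spline = CubicSpline(
            self.knot_log10s, self.knot_values, bc_type="natural"
        )
        s_q, w_q = _gauss_legendre_log(lo, hi, self.n_quad)
        self._log_norm = float(
            np.log(np.sum(w_q * np.exp(self._raw_log_density(s_q))))
        )

    def _raw_log_density(self, s: np.ndarray) -> np.ndarray:
        """Unnormalized log f at s > 0, linear extrapolation past outer knots."""
        x = np.log10(np.asarray(s, dtype=float))
        lo_k, hi_k = self.knot_log10s[0], self.knot_log10s[-1]
        out = self._spline(np.clip(x, lo_k, hi_k))
        d_lo = float(self._spline(lo_k, 1))
        d_hi = float(self._spline(hi_k, 1))
        out = np.where(x < lo_k, self.knot_values[0] + d_lo * (x - lo_k), out)
        out = np.where(x > hi_k, self.knot_values[-1] + d_hi * (x - hi_k), out)
        return out

    def log_pdf(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        lo, hi = self.support
        with np.errstate(divide="ignore"):
            out = np.where(
                (s >= lo) & (s <= hi),
                self._raw_log_density(np.clip(s, lo, hi)) - self._log_norm,
                -np.inf,
            )
        return out

    def pdf(self, s) -> np.ndarray:
        return np.exp(self.log_pdf(s))

    def quadrature(self, n: int | None = None, lo: float | None = None,
                   hi: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(s nodes, weights) with weights summing to the f-mass on [lo, hi].

        Gauss-Legendre in ln s; the weights already include the pdf factor,
        so sum(w * g(s)) approximates E[g(S) 1{lo <= S <= hi}].
        """
        n = n or self.n_quad
        lo = self.support[0] if lo is None else max(lo, self.support[0])
        hi = self.support[1] if hi is None else min(hi, self.support[1])
        s_q, w_q = _gauss_legendre_log(lo, hi, n)
        return s_q, w_q * self.pdf(s_q)

    def mode(self, n_grid: int = 2048) -> float:
        """Location of the density maximum on a dense log grid."""
        s = np.geomspace(self.support[0], self.support[1], n_grid)
        return float(s[np.argmax(self.log_pdf(s))])

    def mean_log10(self) -> float:
        s, w = self.quadrature()
        return float(np.sum(w * np.log10(s)) / np.sum(w))

    @classmethod
    def toy_reference(cls) -> "SplineFS":
        """Moderate-selection f(s) used as the default simulation condition.

        A unimodal density with its log-density peak near s = 1.8e-3 and a
        steeply falling strong-selection tail; at desk scale it plays the
        role of the distribution shared by typical quantitative traits.
        """
        return cls(
            knot_values=np.array([0.0, 1.2, 0.0, -2.5]),
            knot_log10s=np.array(TOY_KNOT_LOG10S),
            support=TOY_SUPPORT,
        )

    @classmethod
    def toy_strong(cls) -> "SplineFS":
        """Strong-selection f(s): the desk-scale brain-trait-like condition.

        Most of the probability mass sits at selection coefficients so large
        that carriers essentially never become common; the GWAS-visible
        minority of mutations comes from a weakly selected shoulder. The
        resulting ascertained hits are fewer, of higher MAF, and of modest
        significance, while the pre-ascertainment frequency distribution is
        shifted toward rare variants relative to the reference density.
        """
        return cls(
            knot_values=np.array([-2.8, 2.0, -3.4, -1.5]),
            knot_log10s=np.array(TOY_KNOT_LOG10S),
            support=TOY_SUPPORT,
        )

    def shifted(self, decades: float) -> "SplineFS":
        """Same shape translated along log10 s (stronger selection if > 0)."""
        return SplineFS(
            knot_values=self.knot_values.copy(),
            knot_log10s=self.knot_log10s + decades,
            n_quad=self.n_quad,
        )
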