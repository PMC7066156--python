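"""Falconer conversions from familial regression slopes to narrow-sense
heritability, and trend tests of the slope process across quantiles.

With assortative mating (spouse correlation r) the classical conversions are

    offspring-parent:   h^2 = 2 * beta_OP / (1 + r)
    offspring-midparent: h^2 = beta_OM
    full sibs:          h^2 = (sqrt(1 + 8 r beta_FS) - 1) / (2 r)

the full-sib form being the inverse of beta_FS = h^2/2 + r h^4/2; as r -> 0 it
tends to 2 * beta_FS.  Standard errors propagate by the delta method with r
treated as fixed.

Trend tests decompose the slope (or h^2) process over the quantile grid into
linear, quadratic and cubic components using discrete orthogonal polynomial
contrasts built on the actual grid; each contrast of the slopes is referred to
a t distribution with the pair set's pedigree degrees of freedom, with the
contrast variance taken from the bootstrap covariance of the slope process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .quantreg import QuantileGrid, QuantileProcessFit

__all__ = [
    "HeritabilityEstimate",
    "HeritabilityCurve",
    "TrendTest",
    "DifferenceTest",
    "h2_from_op",
    "h2_from_om",
    "h2_from_fs",
    "h2_curve",
    "orthogonal_contrasts",
    "linear_contrast_slope",
    "trend_test",
    "difference_test",
]


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    method: str
    r_spouse: float
    source_slope: float
    source_se: float


@dataclass
class HeritabilityCurve:
    grid: QuantileGrid
    h2: np.ndarray
    se: np.ndarray
    method: str
    r_spouse: float


@dataclass
class TrendTest:
    degree: int
    estimate: float
    se: float
    t_stat: float
    p_value: float
    df: int
    per_percentile_slope: float | None = None
    per_percentile_se: float | None = None


@dataclass
class DifferenceTest:
    tau_hi: float
    tau_lo: float
    difference: float
    se: float
    t_stat: float
    p_value: float
    df: int


def h2_from_op(beta_op: float, se_beta: float, r_spouse: float) -> HeritabilityEstimate:
    """h^2 = 2*beta_OP/(1 + r_spouse); SE scales by the same factor."""
    if r_spouse <= -1.0:
        raise ValueError("r_spouse must exceed -1")
    factor = 2.0 / (1.0 + r_spouse)
    return HeritabilityEstimate(
        h2=factor * beta_op,
        se=factor * se_beta,
        method="OP",
        r_spouse=r_spouse,
        source_slope=beta_op,
        source_se=se_beta,
    )


def h2_from_om(beta_om: float, se_beta: float) -> HeritabilityEstimate:
    """The midparent slope estimates h^2 directly."""
    return HeritabilityEstimate(
        h2=beta_om,
        se=se_beta,
        method="MIDPARENT",
        r_spouse=float("nan"),
        source_slope=beta_om,
        source_se=se_beta,
    )


def h2_from_fs(beta_fs: float, se_beta: float, r_spouse: float) -> HeritabilityEstimate:
    """Invert beta_FS = h^2/2 + r*h^4/2 for h^2 (delta-method SE).

    For |r_spouse| below 1e-8 the series limit h^2 = 2*beta_FS is used.
    """
    disc = 1.0 + 8.0 * r_spouse * beta_fs
    if disc < 0.0:
        raise ValueError(
            f"1 + 8*r*beta = {disc:.4g} < 0: full-sib inversion undefined"
        )
    if abs(r_spouse) < 1e-8:
        h2 = 2.0 * beta_fs
        deriv = 2.0
    else:
        h2 = (np.sqrt(disc) - 1.0) / (2.0 * r_spouse)
        deriv = 2.0 / np.sqrt(disc)
    return HeritabilityEstimate(
        h2=float(h2),
        se=float(deriv * se_beta),
        method="FS",
        r_spouse=r_spouse,
        source_slope=beta_fs,
        source_se=se_beta,
    )


_CONVERTERS = {
    "OP": lambda b, s, r: h2_from_op(b, s, r),
    "MIDPARENT": lambda b, s, r: h2_from_om(b, s),
    "FS": lambda b, s, r: h2_from_fs(b, s, r),
}


def h2_curve(fit: QuantileProcessFit, r_spouse: float, method: str) -> HeritabilityCurve:
    """Convert a fitted slope process to the h^2 scale, level by level."""
    if method not in _CONVERTERS:
        raise ValueError(f"method must be one of {sorted(_CONVERTERS)}")
    ses = fit.slope_se
    h2 = np.empty(len(fit.grid))
    se = np.empty(len(fit.grid))
    for i, (b, s) in enumerate(zip(fit.slopes, ses)):
        est = _CONVERTERS[method](float(b), float(s), r_spouse)
        h2[i], se[i] = est.h2, est.se
    return HeritabilityCurve(grid=fit.grid, h2=h2, se=se, method=method, r_spouse=r_spouse)


def orthogonal_contrasts(grid: QuantileGrid, max_degree: int = 3) -> np.ndarray:
    """Discrete orthogonal polynomial contrasts of degree 1..max_degree.

    Rows are orthonormal, each orthogonal to the constant vector; built by
    Gram-Schmidt on the Vandermonde basis of the grid's percentile points so
    non-uniform grids are handled exactly.
    """
    t = np.asarray(grid.taus, float)
    if len(t) <= max_degree:
        raise ValueError("grid must have more points than the requested degree")
    V = np.vander(t, max_degree + 1, increasing=True)  # 1, t, t^2, ...
    Q, _ = np.linalg.qr(V)
    C = Q[:, 1:].T  # drop the constant direction
    # fix signs so the linear contrast increases with tau
    for k in range(C.shape[0]):
        lead = C[k, -1] - C[k, 0] if k == 0 else C[k, -1]
        if lead < 0:
            C[k] *= -1.0
    return C


def linear_contrast_slope(grid: QuantileGrid) -> np.ndarray:
    """Contrast whose inner product with the slopes is the least-squares slope
    of beta(tau) on percentile (change per 1 percentile)."""
    p = 100.0 * np.asarray(grid.taus, float)
    pc = p - p.mean()
    return pc / np.sum(pc**2)


def _contrast_stat(fit: QuantileProcessFit, c: np.ndarray) -> tuple[float, float]:
    if fit.slope_cov is None:
        raise ValueError("fit has no bootstrap covariance; run bootstrap_process first")
    est = float(c @ fit.slopes)
    var = float(c @ fit.slope_cov @ c)
    if var <= 0.0:
        raise FloatingPointError("contrast variance is non-positive (degenerate covariance)")
    return est, np.sqrt(var)


def trend_test(fit: QuantileProcessFit, degree: int) -> TrendTest:
    """Test the degree-1/2/3 orthogonal component of the slope process."""
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2, or 3")
    C = orthogonal_contrasts(fit.grid, max_degree=degree)
    est, se = _contrast_stat(fit, C[degree - 1])
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), fit.df)
    pps = pps_se = None
    if degree == 1:
        c_lin = linear_contrast_slope(fit.grid)
        pps, pps_se = _contrast_stat(fit, c_lin)
    return TrendTest(
        degree=degree,
        estimate=est,
        se=se,
        t_stat=float(t),
        p_value=float(p),
        df=fit.df,
        per_percentile_slope=pps,
        per_percentile_se=pps_se,
    )


def difference_test(
    fit: QuantileProcessFit, tau_hi: float = 0.90, tau_lo: float = 0.10
) -> DifferenceTest:
    """Contrast beta(tau_hi) - beta(tau_lo) with its bootstrap covariance."""
    c = np.zeros(len(fit.grid))
    c[fit.grid.index_of(tau_hi)] = 1.0
    c[fit.grid.index_of(tau_lo)] = -1.0
    est, se = _contrast_stat(fit, c)
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), fit.df)
    return DifferenceTest(
        tau_hi=tau_hi,
        tau_lo=tau_lo,
        difference=est,
        se=se,
        t_stat=float(t),
        p_value=float(p),
        df=fit.df,
    )
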