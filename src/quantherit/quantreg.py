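"""Weighted linear quantile regression over a grid of quantiles.

The estimator at quantile level ``tau`` minimises the weighted check loss

    sum_i  w_i * rho_tau(y_i - a - b * x_i),      rho_tau(u) = u * (tau - 1[u<0])

which is a linear program.  The solver here is a Mehrotra predictor-corrector
interior-point method applied to the bounded-variable dual LP

    max  c'd   s.t.  A d = (1 - tau) * A 1,   0 <= d <= 1,

with ``A = (diag(w) X)'`` and ``c = w * y``; the equality multiplier converges
to the primal coefficients.  Because the design matrix is shared by every
quantile level, all levels of a grid are solved simultaneously: each Newton
step reduces to a batch of 2x2 solves, which is what makes the 91-level
bootstrap affordable.  A final vertex-polish step enumerates the lines through
the points with the smallest residuals and keeps the best, so the returned
coefficients sit on an exact vertex of the LP.

Standard errors of the slope process come from a bootstrap (pair or family
resampling) as in the classical simultaneous-quantile-regression procedure:
per-level fits are independent, the bootstrap supplies the cross-level
covariance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import _ipsolve
from .pairs import PairSet

__all__ = [
    "QuantileGrid",
    "QuantileProcessFit",
    "OlsFit",
    "DegenerateDesignError",
    "check_loss",
    "fit_weighted_quantile",
    "fit_quantile_process",
    "bootstrap_process",
    "fit_weighted_ols",
]


class DegenerateDesignError(ValueError):
    """Raised when the regressor is constant and the slope is unidentifiable."""


@dataclass(frozen=True)
class QuantileGrid:
    """Ordered grid of quantile levels, default the 5th..95th percentiles."""

    taus: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(5, 96) / 100.0, 2)
    )

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        if taus.ndim != 1 or len(taus) == 0:
            raise ValueError("grid must be a non-empty 1-d sequence")
        if np.any(taus <= 0.0) or np.any(taus >= 1.0):
            raise ValueError("quantile levels must lie strictly inside (0, 1)")
        if np.any(np.diff(taus) <= 0):
            raise ValueError("quantile levels must be strictly increasing")
        object.__setattr__(self, "taus", taus)

    def __len__(self) -> int:
        return len(self.taus)

    def index_of(self, tau: float) -> int:
        hits = np.flatnonzero(np.isclose(self.taus, tau, atol=1e-9))
        if len(hits) == 0:
            raise ValueError(f"tau={tau} is not on the grid")
        return int(hits[0])

    @classmethod
    def from_range(cls, lo: float = 0.05, hi: float = 0.95, step: float = 0.01) -> "QuantileGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(np.round(lo + step * np.arange(n), 10))


@dataclass
class QuantileProcessFit:
    """Per-quantile intercept/slope plus bootstrap covariance of the slopes."""

    grid: QuantileGrid
    intercepts: np.ndarray
    slopes: np.ndarray
    slope_cov: np.ndarray | None = None
    n_boot: int = 0
    seed: int | None = None
    df: int = 0
    resample_unit: str | None = None
    n_redraws: int = 0

    @property
    def slope_se(self) -> np.ndarray:
        if self.slope_cov is None:
            return np.full(len(self.grid), np.nan)
        return np.sqrt(np.clip(np.diag(self.slope_cov), 0.0, None))

    def at(self, tau: float) -> tuple[float, float]:
        i = self.grid.index_of(tau)
        return float(self.intercepts[i]), float(self.slopes[i])


@dataclass
class OlsFit:
    slope: float
    slope_se: float
    intercept: float
    correlation: float
    df: int
    p_value: float


def check_loss(u, tau: float):
    """Check loss rho_tau(u) = u * (tau - 1[u < 0]); the quantile-regression objective."""
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    u = np.asarray(u, dtype=float)
    out = u * (tau - (u < 0))
    return out if out.ndim else float(out)


def _as_xyw(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(pairs, PairSet):
        df = pairs.pairs
        return (
            df["x"].to_numpy(float),
            df["y"].to_numpy(float),
            df["weight"].to_numpy(float),
        )
    x, y, w = pairs
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    return x, y, w


def _objective(x, y, w, taus, intercepts, slopes):
    """Weighted check loss of each (intercept, slope) at its tau.  Shapes (T,)."""
    r = y[:, None] - intercepts[None, :] - np.outer(x, slopes)
    return np.sum(w[:, None] * r * (taus[None, :] - (r < 0)), axis=0)


def _interior_point(X, y, w, taus, tol=1e-11, max_iter=100):
    """Batch interior-point solve; returns coefficients of shape (T, 2)."""
    n, p = X.shape
    T = len(taus)
    Xw = X * w[:, None]                       # row-scaled design
    c = (w * y)[:, None]                      # (n, 1)

    d = np.broadcast_to(1.0 - taus[None, :], (n, T)).copy()   # primal-feasible
    s = 1.0 - d

    G = Xw.T @ Xw
    try:
        beta0 = np.linalg.solve(G, Xw.T @ (w * y))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded earlier
        raise DegenerateDesignError("design matrix is singular") from exc
    beta = np.repeat(beta0[:, None], T, axis=1)               # (p, T)

    r = c - Xw @ beta
    delta = 0.1 * (1.0 + np.abs(r))
    z = np.maximum(r, 0.0) + delta            # complementary to s
    wv = np.maximum(-r, 0.0) + delta          # complementary to d

    big = 1e30

    def steps(dd, dz, dw):
        # primal: d + a*dd >= 0, s - a*dd >= 0 ; dual: z + a*dz >= 0, w + a*dw >= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ap = np.minimum(
                np.min(np.where(dd < 0, -d / dd, big), axis=0),
                np.min(np.where(dd > 0, s / dd, big), axis=0),
            )
            ad = np.minimum(
                np.min(np.where(dz < 0, -z / dz, big), axis=0),
                np.min(np.where(dw < 0, -wv / dw, big), axis=0),
            )
        return np.minimum(1.0, 0.9995 * ap), np.minimum(1.0, 0.9995 * ad)

    for _ in range(max_iter):
        r = c - Xw @ beta
        gap = np.sum(z * s + wv * d, axis=0)
        scale = 1.0 + np.abs(np.sum(c * d, axis=0))
        if np.all(gap < tol * scale * n):
            break

        q = 1.0 / (z / s + wv / d)
        M = np.einsum("ij,it,ik->tjk", Xw, q, Xw)
        # affine (predictor) direction: mu = 0
        g = r
        dy = np.linalg.solve(M, np.einsum("ij,it->tj", Xw, q * g)[:, :, None])[:, :, 0]
        dd = q * (g - Xw @ dy.T)
        dz = -z + (z / s) * dd
        dw = -wv - (wv / d) * dd
        ap, ad = steps(dd, dz, dw)

        gap_aff = np.sum(
            (z + ad * dz) * (s - ap * dd) + (wv + ad * dw) * (d + ap * dd), axis=0
        )
        mu = (gap_aff / gap) ** 3 * gap / (2.0 * n)           # (T,)

        # corrector with Mehrotra second-order terms
        c1 = dd * dw           # pairs with d
        c2 = -dd * dz          # pairs with s
        g = r + (mu - c1) / d - (mu - c2) / s
        dy = np.linalg.solve(M, np.einsum("ij,it->tj", Xw, q * g)[:, :, None])[:, :, 0]
        dd = q * (g - Xw @ dy.T)
        dz = (mu - c2) / s - z + (z / s) * dd
        dw = (mu - c1) / d - wv - (wv / d) * dd
        ap, ad = steps(dd, dz, dw)

        d += ap * dd
        s -= ap * dd
        z += ad * dz
        wv += ad * dw
        beta += dy.T * ad
    return beta.T                                             # (T, p)


def _polish(x, y, w, taus, coefs, n_candidates=4):
    """Snap each tau's solution to the best vertex (two-point line) nearby.

    The LP optimum interpolates two data points; the interior-point iterate
    is within tolerance of it, so the basis points are among the smallest
    absolute residuals.  Enumerate lines through the n_candidates closest
    points and keep whichever (including the unpolished iterate) attains the
    lowest weighted check loss.
    """
    n = len(x)
    T = len(taus)
    m = min(n_candidates, n)
    resid = np.abs(y[:, None] - coefs[:, 0][None, :] - np.outer(x, coefs[:, 1]))
    idx = np.argpartition(resid, m - 1, axis=0)[:m]           # (m, T)

    combos = list(itertools.combinations(range(m), 2))
    i_idx = idx[[a for a, _ in combos], :]                    # (C, T)
    j_idx = idx[[b for _, b in combos], :]
    xi, xj = x[i_idx], x[j_idx]
    yi, yj = y[i_idx], y[j_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        b_cand = (yj - yi) / (xj - xi)
    valid = np.isfinite(b_cand)
    b_cand = np.where(valid, b_cand, 0.0)
    a_cand = yi - b_cand * xi                                 # (C, T)

    # objectives: (n, C, T) residual tensor, reduced over n
    r = y[:, None, None] - a_cand[None] - x[:, None, None] * b_cand[None]
    loss = np.einsum("i,ict->ct", w, r * (taus[None, None, :] - (r < 0)))
    loss = np.where(valid, loss, np.inf)

    loss_ip = _objective(x, y, w, taus, coefs[:, 0], coefs[:, 1])
    best = np.argmin(loss, axis=0)                            # (T,)
    tt = np.arange(T)
    take = loss[best, tt] <= loss_ip
    out = coefs.copy()
    out[take, 0] = a_cand[best, tt][take]
    out[take, 1] = b_cand[best, tt][take]
    return out


def _fit_process_arrays(x, y, w, taus, polish=True, tol=1e-11, max_iter=100):
    if len(x) < 2:
        raise ValueError("need at least 2 pairs to fit a line")
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("all x values identical; slope unidentifiable")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    X = np.column_stack([np.ones_like(x), x])
    taus = np.asarray(taus, float)
    if _ipsolve.HAVE_NUMBA:
        coefs = _ipsolve.solve_process(X, y, w, taus, tol, max_iter)
    else:  # pragma: no cover - numpy fallback
        coefs = _interior_point(X, y, w, taus, tol=tol, max_iter=max_iter)
    if polish:
        coefs = _polish(x, y, w, taus, coefs)
    return coefs


def fit_weighted_quantile(pairs, tau: float) -> tuple[float, float]:
    """Minimise the weighted check loss at one quantile level.

    Returns ``(intercept, slope)``.  ``pairs`` is a :class:`~quantherit.pairs.PairSet`
    or an ``(x, y, weights)`` triple (weights may be None).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    x, y, w = _as_xyw(pairs)
    coefs = _fit_process_arrays(x, y, w, [tau])
    return float(coefs[0, 0]), float(coefs[0, 1])


def fit_quantile_process(pairs, grid: QuantileGrid, polish: bool = True) -> QuantileProcessFit:
    """Independent per-level fits over the whole grid (solved as one batch)."""
    x, y, w = _as_xyw(pairs)
    coefs = _fit_process_arrays(x, y, w, grid.taus, polish=polish)
    df = pairs.df if isinstance(pairs, PairSet) else max(len(x) - 2, 1)
    return QuantileProcessFit(
        grid=grid, intercepts=coefs[:, 0], slopes=coefs[:, 1], df=df
    )


def bootstrap_process(
    pairs,
    grid: QuantileGrid,
    n_boot: int = 1000,
    seed: int | None = None,
    resample_unit: str = "pair",
    max_redraw_frac: float = 0.10,
) -> QuantileProcessFit:
    """Point fits plus bootstrap covariance of the slope process.

    Resamples ``resample_unit`` ("pair" or "family") with replacement to the
    original count and refits the whole process per replicate.  A replicate
    whose resampled x values are constant is redrawn; more than
    ``max_redraw_frac * n_boot`` redraws aborts.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if resample_unit not in ("pair", "family"):
        raise ValueError("resample_unit must be 'pair' or 'family'")
    x, y, w = _as_xyw(pairs)
    fit = fit_quantile_process(pairs, grid)

    rng = np.random.default_rng(seed)
    if resample_unit == "family":
        if not isinstance(pairs, PairSet):
            raise ValueError("family resampling requires a PairSet with family ids")
        fam = pairs.pairs["family_id"].to_numpy()
        fam_ids, fam_inv = np.unique(fam, return_inverse=True)
        members = [np.flatnonzero(fam_inv == k) for k in range(len(fam_ids))]
        n_units = len(fam_ids)
    else:
        n_units = len(x)

    T = len(grid)
    boot = np.empty((n_boot, T))
    redraws = 0
    b = 0
    while b < n_boot:
        draw = rng.integers(0, n_units, size=n_units)
        if resample_unit == "family":
            idx = np.concatenate([members[u] for u in draw])
        else:
            idx = draw
        if np.ptp(x[idx]) == 0.0:
            redraws += 1
            if redraws > max_redraw_frac * n_boot:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        # replicates feed an empirical covariance; a looser tolerance suffices
        coefs = _fit_process_arrays(
            x[idx], y[idx], w[idx], grid.taus, polish=False, tol=1e-8
        )
        boot[b] = coefs[:, 1]
        b += 1

    cov = np.cov(boot, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    fit.slope_cov = 0.5 * (cov + cov.T)
    fit.n_boot = n_boot
    fit.seed = seed
    fit.resample_unit = resample_unit
    fit.n_redraws = redraws
    return fit


def fit_weighted_ols(pairs) -> OlsFit:
    """Frequency-weighted least-squares slope with the PairSet degrees of freedom."""
    from scipy import stats

    x, y, w = _as_xyw(pairs)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("all x values identical")
    sw = w.sum()
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    syy = np.sum(w * (y - my) ** 2)
    sxy = np.sum(w * (x - mx) * (y - my))
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateDesignError("zero variance in x or y")
    slope = sxy / sxx
    intercept = my - slope * mx
    corr = sxy / np.sqrt(sxx * syy)
    df = pairs.df if isinstance(pairs, PairSet) else max(len(x) - 2, 1)
    # residual variance on the frequency-weight scale with the pedigree df
    rss = np.sum(w * (y - intercept - slope * x) ** 2)
    se = np.sqrt(rss / df / sxx)
    t = slope / se if se > 0 else np.inf * np.sign(slope)
    p = 2.0 * stats.t.sf(abs(t), df)
    return OlsFit(
        slope=float(slope),
        slope_se=float(se),
        intercept=float(intercept),
        correlation=float(corr),
        df=int(df),
        p_value=float(p),
    )
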