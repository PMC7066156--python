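"""Numba-accelerated interior-point kernel for two-parameter quantile regression.

Same Mehrotra predictor-corrector iteration as the numpy batch solver in
``quantreg``, specialised to a design with an intercept and one regressor so
every Newton step is a closed-form 2x2 solve.  Compiled per quantile level;
the process driver loops levels over a shared workspace.  Falls back to the
numpy implementation when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard install here
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=True, fastmath=True)
def _ip_single(a0, a1, c, tau, tol, max_iter, work, beta):
    """Solve one quantile level; a0 = w, a1 = w*x, c = w*y (row-scaled data).

    ``work`` is a (10, n) scratch array, ``beta`` length-2 output (in: the
    weighted least-squares start, out: the solution).
    """
    n = a0.shape[0]
    d = work[0]
    s = work[1]
    z = work[2]
    wv = work[3]
    r = work[4]
    q = work[5]
    dd = work[6]
    dz = work[7]
    dw = work[8]
    cc = work[9]  # corrector cross terms packed as needed

    b0 = beta[0]
    b1 = beta[1]
    for i in range(n):
        d[i] = 1.0 - tau
        s[i] = tau
        ri = c[i] - a0[i] * b0 - a1[i] * b1
        delta = 0.1 * (1.0 + abs(ri))
        if ri > 0.0:
            z[i] = ri + delta
            wv[i] = delta
        else:
            z[i] = delta
            wv[i] = delta - ri

    for _ in range(max_iter):
        gap = 0.0
        cd = 0.0
        m00 = 0.0
        m01 = 0.0
        m11 = 0.0
        r0 = 0.0
        r1 = 0.0
        for i in range(n):
            ri = c[i] - a0[i] * b0 - a1[i] * b1
            r[i] = ri
            gap += z[i] * s[i] + wv[i] * d[i]
            cd += c[i] * d[i]
            qi = (s[i] * d[i]) / (z[i] * d[i] + wv[i] * s[i])
            q[i] = qi
            qg = qi * ri
            m00 += qi * a0[i] * a0[i]
            m01 += qi * a0[i] * a1[i]
            m11 += qi * a1[i] * a1[i]
            r0 += qg * a0[i]
            r1 += qg * a1[i]
        if gap < tol * (1.0 + abs(cd)) * n:
            break
        det = m00 * m11 - m01 * m01
        dy0 = (m11 * r0 - m01 * r1) / det
        dy1 = (m00 * r1 - m01 * r0) / det

        # predictor (affine) direction and its step lengths
        ap = 1.0
        ad = 1.0
        for i in range(n):
            ddi = q[i] * (r[i] - a0[i] * dy0 - a1[i] * dy1)
            dzi = -z[i] + (z[i] / s[i]) * ddi
            dwi = -wv[i] - (wv[i] / d[i]) * ddi
            dd[i] = ddi
            dz[i] = dzi
            dw[i] = dwi
            if ddi < 0.0:
                t = -d[i] / ddi
                if t < ap:
                    ap = t
            elif ddi > 0.0:
                t = s[i] / ddi
                if t < ap:
                    ap = t
            if dzi < 0.0:
                t = -z[i] / dzi
                if t < ad:
                    ad = t
            if dwi < 0.0:
                t = -wv[i] / dwi
                if t < ad:
                    ad = t
        ap = min(1.0, 0.9995 * ap)
        ad = min(1.0, 0.9995 * ad)

        gap_aff = 0.0
        for i in range(n):
            gap_aff += (z[i] + ad * dz[i]) * (s[i] - ap * dd[i]) + (
                wv[i] + ad * dw[i]
            ) * (d[i] + ap * dd[i])
        ratio = gap_aff / gap
        mu = ratio * ratio * ratio * gap / (2.0 * n)

        # corrector with second-order terms c1 = dd*dw (d side), c2 = -dd*dz (s side)
        m_r0 = 0.0
        m_r1 = 0.0
        for i in range(n):
            c1 = dd[i] * dw[i]
            c2 = -dd[i] * dz[i]
            gi = r[i] + (mu - c1) / d[i] - (mu - c2) / s[i]
            cc[i] = gi
            m_r0 += q[i] * gi * a0[i]
            m_r1 += q[i] * gi * a1[i]
        dy0 = (m11 * m_r0 - m01 * m_r1) / det
        dy1 = (m00 * m_r1 - m01 * m_r0) / det

        ap = 1.0
        ad = 1.0
        for i in range(n):
            ddi = q[i] * (cc[i] - a0[i] * dy0 - a1[i] * dy1)
            c1 = dd[i] * dw[i]
            c2 = -dd[i] * dz[i]
            dzi = (mu - c2) / s[i] - z[i] + (z[i] / s[i]) * ddi
            dwi = (mu - c1) / d[i] - wv[i] - (wv[i] / d[i]) * ddi
            dd[i] = ddi
            dz[i] = dzi
            dw[i] = dwi
            if ddi < 0.0:
                t = -d[i] / ddi
                if t < ap:
                    ap = t
            elif ddi > 0.0:
                t = s[i] / ddi
                if t < ap:
                    ap = t
            if dzi < 0.0:
                t = -z[i] / dzi
                if t < ad:
                    ad = t
            if dwi < 0.0:
                t = -wv[i] / dwi
                if t < ad:
                    ad = t
        ap = min(1.0, 0.9995 * ap)
        ad = min(1.0, 0.9995 * ad)

        for i in range(n):
            d[i] += ap * dd[i]
            s[i] -= ap * dd[i]
            z[i] += ad * dz[i]
            wv[i] += ad * dw[i]
        b0 += ad * dy0
        b1 += ad * dy1

    beta[0] = b0
    beta[1] = b1


@njit(cache=True, fastmath=True)
def _ip_process(a0, a1, c, taus, tol, max_iter, ls_beta):
    n = a0.shape[0]
    T = taus.shape[0]
    work = np.empty((10, n))
    out = np.empty((T, 2))
    for t in range(T):
        beta = ls_beta.copy()
        _ip_single(a0, a1, c, taus[t], tol, max_iter, work, beta)
        out[t, 0] = beta[0]
        out[t, 1] = beta[1]
    return out


def solve_process(X, y, w, taus, tol, max_iter):
    """Numba path: coefficients (T, 2) for a shared weighted design."""
    a0 = np.ascontiguousarray(w, dtype=float)
    a1 = np.ascontiguousarray(w * X[:, 1], dtype=float)
    c = np.ascontiguousarray(w * y, dtype=float)
    G00 = a0 @ a0
    G01 = a0 @ a1
    G11 = a1 @ a1
    r0 = a0 @ c
    r1 = a1 @ c
    det = G00 * G11 - G01 * G01
    ls_beta = np.array([(G11 * r0 - G01 * r1) / det, (G00 * r1 - G01 * r0) / det])
    return _ip_process(a0, a1, c, np.ascontiguousarray(taus, float), tol, max_iter, ls_beta)
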