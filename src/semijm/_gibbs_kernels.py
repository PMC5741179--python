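"""Compiled inner kernels for the collapsed Metropolis moves of the sampler.

The two collapsed-move log-posteriors are evaluated ~30 times per Gibbs sweep
on small arrays, where numpy call overhead dominates; numba-compiled loops cut
the sweep time substantially.  Pure-numpy fallbacks keep the module usable if
numba is unavailable; both paths are exercised against each other in tests.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import log_ndtr

_SQRT2 = math.sqrt(2.0)
_LOG_2PI_HALF = 0.5 * math.log(2.0 * math.pi)


def _py_probit_loglik(U, sign, theta):
    args = np.maximum(sign * (U @ theta), -38.0)
    return float(np.sum(log_ndtr(args)))


def _py_collapsed_loglik(Wm, WVW_flat, Sh, SX, n_rows, hh, Xh, XtX, a, g):
    w = Wm @ g
    v = WVW_flat @ np.outer(g, g).ravel()
    den = 1.0 + n_rows * v
    Sr = Sh - SX @ a
    quad_tot = hh - 2.0 * float(Xh @ a) + float(a @ XtX @ a)
    T = Sr - n_rows * w
    return -0.5 * (np.sum(np.log(den)) + quad_tot
                   - 2.0 * float(w @ Sr) + float(n_rows @ (w * w))
                   - float((v * T * T / den).sum()))


try:
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _log_ndtr_scalar(x: float) -> float:
        if x > -10.0:
            return math.log(0.5 * math.erfc(-x / _SQRT2))
        # asymptotic tail expansion of log Phi(x) for x << 0
        xsq = x * x
        series = 1.0 - 1.0 / xsq + 3.0 / (xsq * xsq)
        return -0.5 * xsq - math.log(-x) - _LOG_2PI_HALF + math.log(series)

    @njit(cache=False)
    def probit_loglik(U, sign, theta):
        n, k = U.shape
        total = 0.0
        for i in range(n):
            lp = 0.0
            for j in range(k):
                lp += U[i, j] * theta[j]
            arg = sign[i] * lp
            if arg < -38.0:
                arg = -38.0
            total += _log_ndtr_scalar(arg)
        return total

    @njit(cache=False)
    def collapsed_loglik(Wm, WVW_flat, Sh, SX, n_rows, hh, Xh, XtX, a, g):
        N, qp = Wm.shape
        p = SX.shape[1]
        quad_tot = hh
        for j in range(p):
            quad_tot -= 2.0 * Xh[j] * a[j]
            for l in range(p):
                quad_tot += a[j] * XtX[j, l] * a[l]
        total = quad_tot
        for i in range(N):
            w = 0.0
            for j in range(qp):
                w += Wm[i, j] * g[j]
            v = 0.0
            for j in range(qp):
                for l in range(qp):
                    v += WVW_flat[i, j * qp + l] * g[j] * g[l]
            den = 1.0 + n_rows[i] * v
            Sr = Sh[i]
            for j in range(p):
                Sr -= SX[i, j] * a[j]
            T = Sr - n_rows[i] * w
            total += (math.log(den) - 2.0 * w * Sr + n_rows[i] * w * w
                      - v * T * T / den)
        return -0.5 * total

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is expected to be present
    probit_loglik = _py_probit_loglik
    collapsed_loglik = _py_collapsed_loglik
    HAVE_NUMBA = False
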