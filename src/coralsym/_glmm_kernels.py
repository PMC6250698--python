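"""Compiled inner kernels for the binary GLMM Gibbs sampler.

Each kernel updates one structured random-effect term: a variance move
(marginal Metropolis on log sigma^2 with the effects integrated out, or the
conjugate scaled-inverse-chi-squared draw given the current effects)
followed by an exact multivariate-normal block draw of the effects via
u = Q^{-1}(b + L z), with Q = diag(d) + V^{-1}/sigma^2 and L its Cholesky
factor.  Kronecker terms with an identity factor decompose into independent
small systems handled in a loop.  Everything is numba-compiled; the
module-level pure-Python fallbacks keep the package importable without
numba (at a large speed penalty).
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def deco(f):
            return f

        return deco


@njit(cache=True)
def _fwd(L, b):
    """Solve L y = b for lower-triangular L."""
    n = L.shape[0]
    y = np.empty(n)
    for i in range(n):
        s = b[i]
        for j in range(i):
            s -= L[i, j] * y[j]
        y[i] = s / L[i, i]
    return y


@njit(cache=True)
def _bwd(L, y):
    """Solve L' x = y for lower-triangular L."""
    n = L.shape[0]
    x = np.empty(n)
    for i in range(n - 1, -1, -1):
        s = y[i]
        for j in range(i + 1, n):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _build_q(prec, var, d):
    q = d.size
    Q = prec / var
    for i in range(q):
        Q[i, i] += d[i]
    return Q


@njit(cache=True)
def _factor_stats(prec, var, d, b):
    """Cholesky factor, log-determinant and b'Q^{-1}b of Q(var)."""
    L = np.linalg.cholesky(_build_q(prec, var, d))
    logdet = 0.0
    for i in range(L.shape[0]):
        logdet += 2.0 * math.log(L[i, i])
    y = _fwd(L, b)
    quad = 0.0
    for i in range(y.size):
        quad += y[i] * y[i]
    return L, logdet, quad


@njit(cache=True)
def _log_target(q, var, logdet, quad, nu0, s0):
    """Marginal log-posterior of var (effects integrated out) plus the
    log-scale proposal Jacobian."""
    return (-0.5 * q * math.log(var) - 0.5 * logdet + 0.5 * quad
            - (0.5 * nu0 + 1.0) * math.log(var) - 0.5 * nu0 * s0 / var
            + math.log(var))


@njit(cache=True)
def update_dense(prec, var, u, d, b, nu0, s0, mh_scale, do_mh, rng):
    """One update of a dense-covariance term; returns the new variance
    (the effect vector u is overwritten in place)."""
    q = d.size
    if do_mh:
        Lc, ldc, qc = _factor_stats(prec, var, d, b)
        varp = var * math.exp(mh_scale * rng.standard_normal())
        Lp, ldp, qp = _factor_stats(prec, varp, d, b)
        la = (_log_target(q, varp, ldp, qp, nu0, s0)
              - _log_target(q, var, ldc, qc, nu0, s0))
        if math.log(rng.random() + 1e-300) < la:
            var = varp
            L = Lp
        else:
            L = Lc
    else:
        quad_u = 0.0
        for i in range(q):
            s = 0.0
            for j in range(q):
                s += prec[i, j] * u[j]
            quad_u += s * u[i]
        var = 0.5 * (nu0 * s0 + quad_u) / rng.gamma(0.5 * (nu0 + q))
        L = np.linalg.cholesky(_build_q(prec, var, d))
    r = b + L @ rng.standard_normal(q)
    u[:] = _bwd(L, _fwd(L, r))
    return var


@njit(cache=True)
def update_identity(var, u, d, b, nu0, s0, mh_scale, do_mh, rng):
    """One update of an identity-covariance term (diagonal systems)."""
    q = d.size
    if do_mh:
        varp = var * math.exp(mh_scale * rng.standard_normal())
        ldc = qc = ldp = qp = 0.0
        for i in range(q):
            dc = d[i] + 1.0 / var
            dp = d[i] + 1.0 / varp
            ldc += math.log(dc)
            ldp += math.log(dp)
            qc += b[i] * b[i] / dc
            qp += b[i] * b[i] / dp
        la = (_log_target(q, varp, ldp, qp, nu0, s0)
              - _log_target(q, var, ldc, qc, nu0, s0))
        if math.log(rng.random() + 1e-300) < la:
            var = varp
    else:
        quad_u = 0.0
        for i in range(q):
            quad_u += u[i] * u[i]
        var = 0.5 * (nu0 * s0 + quad_u) / rng.gamma(0.5 * (nu0 + q))
    for i in range(q):
        qd = d[i] + 1.0 / var
        u[i] = b[i] / qd + rng.standard_normal() / math.sqrt(qd)
    return var


@njit(cache=True)
def _gather(vec, na, nb, j, left):
    out = np.empty(na if left else nb)
    if left:
        for i in range(na):
            out[i] = vec[i * nb + j]
    else:
        for i in range(nb):
            out[i] = vec[j * nb + i]
    return out


@njit(cache=True)
def _scatter(vec, blk, na, nb, j, left):
    if left:
        for i in range(na):
            vec[i * nb + j] = blk[i]
    else:
        for i in range(nb):
            vec[j * nb + i] = blk[i]


@njit(cache=True)
def update_kron(prec, var, u, d, b, nu0, s0, mh_scale, do_mh, na, nb,
                left, rng):
    """One update of a Kronecker term with one identity factor.

    ``left=True`` means covariance A (x) I (prec is A^{-1}, na x na;
    independent systems indexed by the second factor); ``left=False``
    means I (x) B (prec is B^{-1}, nb x nb; contiguous blocks).
    """
    m = nb if left else na      # number of independent systems
    k = na if left else nb      # system dimension
    q = na * nb
    if do_mh:
        varp = var * math.exp(mh_scale * rng.standard_normal())
        Lc = np.empty((m, k, k))
        Lp = np.empty((m, k, k))
        ldc = qc = ldp = qp = 0.0
        for j in range(m):
            dj = _gather(d, na, nb, j, left)
            bj = _gather(b, na, nb, j, left)
            L1, l1, q1 = _factor_stats(prec, var, dj, bj)
            L2, l2, q2 = _factor_stats(prec, varp, dj, bj)
            Lc[j] = L1
            Lp[j] = L2
            ldc += l1
            qc += q1
            ldp += l2
            qp += q2
        la = (_log_target(q, varp, ldp, qp, nu0, s0)
              - _log_target(q, var, ldc, qc, nu0, s0))
        if math.log(rng.random() + 1e-300) < la:
            var = varp
            Lsel = Lp
        else:
            Lsel = Lc
        for j in range(m):
            bj = _gather(b, na, nb, j, left)
            r = bj + Lsel[j] @ rng.standard_normal(k)
            blk = _bwd(Lsel[j], _fwd(Lsel[j], r))
            _scatter(u, blk, na, nb, j, left)
    else:
        quad_u = 0.0
        for j in range(m):
            uj = _gather(u, na, nb, j, left)
            for i in range(k):
                s = 0.0
                for jj in range(k):
                    s += prec[i, jj] * uj[jj]
                quad_u += s * uj[i]
        var = 0.5 * (nu0 * s0 + quad_u) / rng.gamma(0.5 * (nu0 + q))
        for j in range(m):
            dj = _gather(d, na, nb, j, left)
            bj = _gather(b, na, nb, j, left)
            L = np.linalg.cholesky(_build_q(prec, var, dj))
            r = bj + L @ rng.standard_normal(k)
            blk = _bwd(L, _fwd(L, r))
            _scatter(u, blk, na, nb, j, left)
    return var
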