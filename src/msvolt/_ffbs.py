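"""Numba kernels: Kalman forward filter, backward sampler, and mixture
indicator sampling for the conditionally linear-Gaussian state space obtained
by log-squaring the observations and conditioning on Gaussian-mixture
indicators.

State:   x_t − μ = β (x_{t−1} − μ) + ε,   ε ~ N(0, diag(σ²)),  x₀ ~ N(μ, V₀)
Obs:     z_t = x_t + m_t + u_t,           u_t ~ N(0, diag(v_t))

with (m_t, v_t) the per-site mixture component moments.  Events are
independent and share parameters, so the kernels loop events × time with
dense J×J algebra written as explicit scalar loops (J is small; avoiding
temporaries dominates performance).  All randomness enters through pre-drawn
uniforms/normals so reproducibility is owned by the caller's Generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["filter_loglik", "ffbs_draw", "draw_indicators"]

_LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True, fastmath=True)
def _chol(A, L):
    """Cholesky factor of a PSD matrix into L, zeroing null directions.

    Returns the log-determinant of A restricted to its range (sum of
    2·log L_ii over nonzero pivots); −inf never occurs because callers only
    need it for strictly PD matrices.
    """
    n = A.shape[0]
    logdet = 0.0
    for i in range(n):
        for j in range(n):
            L[i, j] = 0.0
    for i in range(n):
        s = A[i, i]
        for k in range(i):
            s -= L[i, k] * L[i, k]
        if s <= 1e-13 * (abs(A[i, i]) + 1.0):
            L[i, i] = 0.0
            continue
        L[i, i] = np.sqrt(s)
        logdet += 2.0 * np.log(L[i, i])
        for j in range(i + 1, n):
            t = A[j, i]
            for k in range(i):
                t -= L[j, k] * L[i, k]
            L[j, i] = t / L[i, i]
    return logdet


@njit(cache=True, fastmath=True)
def _chol_solve_vec(L, b, out):
    """Solve L Lᵀ out = b given the Cholesky factor L (zero pivots → 0)."""
    n = L.shape[0]
    for i in range(n):
        if L[i, i] == 0.0:
            out[i] = 0.0
            continue
        s = b[i]
        for k in range(i):
            s -= L[i, k] * out[k]
        out[i] = s / L[i, i]
    for i in range(n - 1, -1, -1):
        if L[i, i] == 0.0:
            out[i] = 0.0
            continue
        s = out[i]
        for k in range(i + 1, n):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]
    return out


@njit(cache=True, fastmath=True)
def _chol_solve_mat(L, B, out, col):
    """Solve L Lᵀ out = B columnwise."""
    n = L.shape[0]
    for j in range(B.shape[1]):
        for i in range(n):
            col[i] = B[i, j]
        _chol_solve_vec(L, col, col)
        for i in range(n):
            out[i, j] = col[i]
    return out


@njit(cache=True, fastmath=True)
def _filter_event(z, m_obs, v_obs, mu, beta, sig2, V0, mf, Pf,
                  m, P, S, L, W, r, a, tmp):
    """Forward filter one event; fills filtered moments, returns loglik.

    z, m_obs, v_obs : (J, T); mf : (T, J); Pf : (T, J, J); the rest are
    caller-provided J or J×J work buffers.
    """
    J = z.shape[0]
    T = z.shape[1]
    for i in range(J):
        m[i] = mu[i]
        for j in range(J):
            P[i, j] = V0[i, j]
    ll = 0.0
    for t in range(T):
        if t > 0:
            # m <- mu + beta (m - mu);  P <- beta P betaᵀ + diag(sig2)
            for i in range(J):
                r[i] = m[i] - mu[i]
            for i in range(J):
                s = mu[i]
                for k in range(J):
                    s += beta[i, k] * r[k]
                a[i] = s
            for i in range(J):
                m[i] = a[i]
            for i in range(J):
                for j in range(J):
                    s = 0.0
                    for k in range(J):
                        s += beta[i, k] * P[k, j]
                    tmp[i, j] = s
            for i in range(J):
                for j in range(J):
                    s = 0.0
                    for k in range(J):
                        s += tmp[i, k] * beta[j, k]
                    P[i, j] = s
                P[i, i] += sig2[i]
        # innovation: S = P + diag(v), r = z - m_obs - m
        for i in range(J):
            for j in range(J):
                S[i, j] = P[i, j]
            S[i, i] += v_obs[i, t]
            r[i] = z[i, t] - m_obs[i, t] - m[i]
        logdet = _chol(S, L)
        _chol_solve_vec(L, r, a)          # a = S^{-1} r
        quad = 0.0
        for i in range(J):
            quad += r[i] * a[i]
        ll += -0.5 * (J * _LOG2PI + logdet + quad)
        # W = S^{-1} P;  m += Wᵀ r (= P S^{-1} r);  P -= P W
        _chol_solve_mat(L, P, W, tmp[0])
        for i in range(J):
            s = 0.0
            for k in range(J):
                s += P[i, k] * a[k]
            m[i] += s
        for i in range(J):
            for j in range(J):
                s = 0.0
                for k in range(J):
                    s += P[i, k] * W[k, j]
                tmp[i, j] = s
        for i in range(J):
            for j in range(J):
                P[i, j] -= 0.5 * (tmp[i, j] + tmp[j, i])  # keep symmetric
        for i in range(J):
            mf[t, i] = m[i]
            for j in range(J):
                Pf[t, i, j] = P[i, j]
    return ll


@njit(cache=True, fastmath=True)
def filter_loglik(z, m_obs, v_obs, mu, beta, sig2, V0):
    """Total log marginal density of z over independent events (E, J, T)."""
    E, J, T = z.shape
    mf = np.empty((T, J))
    Pf = np.empty((T, J, J))
    m = np.empty(J)
    P = np.empty((J, J))
    S = np.empty((J, J))
    L = np.empty((J, J))
    W = np.empty((J, J))
    r = np.empty(J)
    a = np.empty(J)
    tmp = np.empty((J, J))
    total = 0.0
    for e in range(E):
        total += _filter_event(z[e], m_obs[e], v_obs[e], mu, beta, sig2, V0,
                               mf, Pf, m, P, S, L, W, r, a, tmp)
    return total


@njit(cache=True, fastmath=True)
def ffbs_draw(z, m_obs, v_obs, mu, beta, sig2, V0, normals):
    """One exact draw of the latent paths given indicators and parameters.

    normals : (E, T, J) pre-drawn standard normals.  Returns x of shape
    (E, J, T).  Degenerate (zero-variance) directions collapse to the
    conditional mean.
    """
    E, J, T = z.shape
    x = np.empty((E, J, T))
    mf = np.empty((T, J))
    Pf = np.empty((T, J, J))
    m = np.empty(J)
    P = np.empty((J, J))
    S = np.empty((J, J))
    L = np.empty((J, J))
    W = np.empty((J, J))
    r = np.empty(J)
    a = np.empty(J)
    tmp = np.empty((J, J))
    BP = np.empty((J, J))
    G = np.empty((J, J))
    C = np.empty((J, J))
    for e in range(E):
        _filter_event(z[e], m_obs[e], v_obs[e], mu, beta, sig2, V0,
                      mf, Pf, m, P, S, L, W, r, a, tmp)
        _chol(Pf[T - 1], L)
        for i in range(J):
            s = mf[T - 1, i]
            for k in range(i + 1):
                s += L[i, k] * normals[e, T - 1, k]
            x[e, i, T - 1] = s
        for t in range(T - 2, -1, -1):
            # Ppred = beta Pf[t] betaᵀ + diag(sig2) (+ ridge); BP = beta Pf[t]
            tr = 0.0
            for i in range(J):
                for j in range(J):
                    s = 0.0
                    for k in range(J):
                        s += beta[i, k] * Pf[t, k, j]
                    BP[i, j] = s
            for i in range(J):
                for j in range(J):
                    s = 0.0
                    for k in range(J):
                        s += BP[i, k] * beta[j, k]
                    S[i, j] = s
                S[i, i] += sig2[i]
                tr += S[i, i]
            ridge = 1e-12 * (tr + 1.0)
            for i in range(J):
                S[i, i] += ridge
            _chol(S, L)
            # G = Pf betaᵀ Ppred^{-1} = (Ppred^{-1} BP)ᵀ
            _chol_solve_mat(L, BP, W, a)
            for i in range(J):
                for j in range(J):
                    G[i, j] = W[j, i]
            # mean = mf + G (x_{t+1} - mu - beta (mf - mu))
            for i in range(J):
                r[i] = mf[t, i] - mu[i]
            for i in range(J):
                s = mu[i]
                for k in range(J):
                    s += beta[i, k] * r[k]
                a[i] = x[e, i, t + 1] - s
            for i in range(J):
                s = mf[t, i]
                for k in range(J):
                    s += G[i, k] * a[k]
                m[i] = s
            # C = Pf - G Ppred Gᵀ = Pf - G BP (since Ppred Gᵀ = BP)
            for i in range(J):
                for j in range(J):
                    s = 0.0
                    for k in range(J):
                        s += G[i, k] * BP[k, j]
                    tmp[i, j] = s
            for i in range(J):
                for j in range(J):
                    C[i, j] = Pf[t, i, j] - 0.5 * (tmp[i, j] + tmp[j, i])
            _chol(C, L)
            for i in range(J):
                s = m[i]
                for k in range(i + 1):
                    s += L[i, k] * normals[e, t, k]
                x[e, i, t] = s
    return x


@njit(cache=True, fastmath=True)
def draw_indicators(resid, log_w, means, inv_var, u):
    """Sample mixture indicators sitewise from the discrete posterior.

    resid : flat array of z − x; log_w = log weight − ½log(2πv); u : flat
    uniforms.  Returns int64 component indices.
    """
    n = resid.shape[0]
    K = log_w.shape[0]
    out = np.empty(n, dtype=np.int64)
    p = np.empty(K)
    for i in range(n):
        r = resid[i]
        mx = -1e300
        for k in range(K):
            d = r - means[k]
            p[k] = log_w[k] - 0.5 * d * d * inv_var[k]
            if p[k] > mx:
                mx = p[k]
        tot = 0.0
        for k in range(K):
            p[k] = np.exp(p[k] - mx)
            tot += p[k]
        thr = u[i] * tot
        acc = 0.0
        kk = K - 1
        for k in range(K):
            acc += p[k]
            if acc >= thr:
                kk = k
                break
        out[i] = kk
    return out
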