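"""Numba kernels for truncated-Gaussian sampling on a polytope.

Both kernels target the unnormalized density

    log pi(u) = -1/2 u^T P u + h^T u   on  {u : C u >= c},

maintaining the gradient term g = P u and the constraint activity
cu = C u incrementally.  The Gibbs kernel sweeps coordinates drawing from
the exact univariate truncated-normal full conditionals (uniform on the
feasible interval where the conditional precision is negligible, i.e.
along flat null-space directions); the hit-and-run kernel draws a random
direction and samples the exact 1-D conditional on the feasible chord.

Truncated standard-normal draws use exact rejection samplers (naive,
uniform-envelope and shifted-exponential accept/reject), which are
numerically stable arbitrarily deep in the tails.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BIG = 1e300


@njit(cache=False)
def _rt_lower(a, b):
    """Standard normal truncated to [a, b] with 0 <= a < b."""
    if a < 0.3 and b - a > 1.2:
        # acceptance >= ~0.3
        while True:
            x = np.random.normal()
            if a <= x <= b:
                return x
    # shifted-exponential rejection (Robert 1995), exact for any a >= 0,
    # with resampling when the proposal overshoots b
    lam = 0.5 * (a + np.sqrt(a * a + 4.0))
    while True:
        x = a - np.log(1.0 - np.random.random()) / lam
        if x > b:
            continue
        z = x - lam
        if np.random.random() <= np.exp(-0.5 * z * z):
            return x


@njit(cache=False)
def _rt_std(a, b):
    """Standard normal truncated to [a, b], a < b (bounds may be +-1e300)."""
    if a >= 0.0:
        return _rt_lower(a, b)
    if b <= 0.0:
        return -_rt_lower(-b, -a)
    # interval straddles zero
    if b - a < 2.0:
        # uniform proposal, envelope exp(0) = 1 at the mode
        while True:
            x = a + (b - a) * np.random.random()
            if np.random.random() <= np.exp(-0.5 * x * x):
                return x
    while True:
        x = np.random.normal()
        if a <= x <= b:
            return x


@njit(cache=False)
def _truncnorm(m, s, lo, hi):
    """Normal(m, s^2) truncated to [lo, hi]."""
    if hi <= lo:
        return lo
    a = (lo - m) / s
    b = (hi - m) / s
    if a > _BIG:
        a = _BIG
    if b > _BIG:
        b = _BIG
    if a < -_BIG:
        a = -_BIG
    if b < -_BIG:
        b = -_BIG
    return m + s * _rt_std(a, b)


@njit(cache=False)
def gibbs_kernel(P, h, C, c, u0, n_keep, burn, thin, seed, flat_tol):
    """Systematic-scan Gibbs sampler; returns (n_keep, d) array.

    flat_tol: conditional precisions below flat_tol * max(diag P) are
    treated as flat directions (uniform draw on the feasible interval).
    """
    np.random.seed(seed)
    d = P.shape[0]
    p = C.shape[0]
    u = u0.copy()
    g = P @ u
    cu = C @ u
    pmax = 0.0
    for i in range(d):
        if P[i, i] > pmax:
            pmax = P[i, i]
    thresh = flat_tol * pmax
    out = np.empty((n_keep, d))
    total = burn + n_keep * thin
    kept = 0
    for it in range(total):
        for i in range(d):
            ui = u[i]
            lo = -_BIG
            hi = _BIG
            for row in range(p):
                cij = C[row, i]
                if cij != 0.0:
                    bound = (c[row] - (cu[row] - cij * ui)) / cij
                    if cij > 0.0:
                        if bound > lo:
                            lo = bound
                    else:
                        if bound < hi:
                            hi = bound
            if hi < lo:
                # interval empty by rounding: keep the current value
                continue
            pii = P[i, i]
            if pii > thresh:
                mean = (h[i] - (g[i] - pii * ui)) / pii
                sd = 1.0 / np.sqrt(pii)
                new = _truncnorm(mean, sd, lo, hi)
            else:
                if hi >= _BIG or lo <= -_BIG:
                    continue  # flat and unbounded: leave unchanged
                new = lo + (hi - lo) * np.random.random()
            delta = new - ui
            if delta != 0.0:
                u[i] = new
                for jj in range(d):
                    g[jj] += P[jj, i] * delta
                for row in range(p):
                    if C[row, i] != 0.0:
                        cu[row] += C[row, i] * delta
        if it >= burn and (it - burn) % thin == 0 and kept < n_keep:
            out[kept] = u
            kept += 1
    return out


@njit(cache=False)
def hitandrun_kernel(P, h, C, c, u0, n_keep, burn, thin, seed, flat_tol):
    """Hit-and-run sampler with exact 1-D conditionals on feasible chords."""
    np.random.seed(seed)
    d = P.shape[0]
    p = C.shape[0]
    u = u0.copy()
    g = P @ u
    cu = C @ u
    pmax = 0.0
    for i in range(d):
        if P[i, i] > pmax:
            pmax = P[i, i]
    thresh = flat_tol * pmax
    out = np.empty((n_keep, d))
    total = burn + n_keep * thin
    kept = 0
    for it in range(total):
        # isotropic random direction
        dvec = np.empty(d)
        norm2 = 0.0
        for i in range(d):
            x = np.random.normal()
            dvec[i] = x
            norm2 += x * x
        inv = 1.0 / np.sqrt(norm2)
        for i in range(d):
            dvec[i] *= inv
        Pd = P @ dvec
        Cd = C @ dvec
        q = 0.0
        lin = 0.0
        for i in range(d):
            q += dvec[i] * Pd[i]
            lin += dvec[i] * (h[i] - g[i])
        tlo = -_BIG
        thi = _BIG
        for row in range(p):
            cd = Cd[row]
            slack = cu[row] - c[row]
            if cd > 1e-14:
                t = -slack / cd
                if t > tlo:
                    tlo = t
            elif cd < -1e-14:
                t = slack / (-cd)
                if t < thi:
                    thi = t
        if thi < tlo:
            t = 0.0
        elif q > thresh:
            t = _truncnorm(lin / q, 1.0 / np.sqrt(q), tlo, thi)
        elif thi < _BIG and tlo > -_BIG:
            t = tlo + (thi - tlo) * np.random.random()
        else:
            t = 0.0
        if t != 0.0:
            for i in range(d):
                u[i] += t * dvec[i]
                g[i] += t * Pd[i]
            for row in range(p):
                cu[row] += t * Cd[row]
        if it >= burn and (it - burn) % thin == 0 and kept < n_keep:
            out[kept] = u
            kept += 1
    return out
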