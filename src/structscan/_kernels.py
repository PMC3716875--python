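"""Numba-accelerated folding kernels (float64, diagonal layout).

These mirror the reference implementation in fold.py exactly; fold.py falls
back to the numpy/extended-precision path when numba is unavailable or when
float64 overflows.  Layout: diag arrays ``Z[d, a]`` hold the value for the
0-based interval [a, a+d].
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAS_NUMBA = True
except Exception:  # pragma: no cover - numba is expected in the environment
    HAS_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False)
def inside_diag(codes, wmat, hfac, ml, span, dmax, no_lp):
    n = codes.shape[0]
    Z = np.zeros((dmax + 1, n))
    Z[0, :] = 1.0
    H = np.zeros((span + 1, n))
    G = np.zeros((span + 1, n))
    for d in range(1, dmax + 1):
        nd = n - d
        if nd <= 0:
            break
        if ml + 1 <= d <= span:
            inner = d - 2
            for a in range(nd):
                w = wmat[codes[a], codes[a + d]]
                if w <= 0.0:
                    continue
                if inner >= 0:
                    hin = H[inner, a + 1] if inner <= span else 0.0
                    gin = G[inner, a + 1] if inner <= span else 0.0
                    yin = Z[inner, a + 1] - hin
                else:
                    yin = 1.0
                    gin = 0.0
                if no_lp:
                    G[d, a] = w * (yin + gin)
                    H[d, a] = w * hfac * gin
                else:
                    zin = Z[inner, a + 1] if inner >= 0 else 1.0
                    H[d, a] = w * zin
        emax = min(d, span)
        for a in range(nd):
            z = Z[d - 1, a]
            for e in range(ml + 1, emax + 1):
                h = H[e, a + d - e]
                if h > 0.0:
                    if e == d:
                        z += h
                    else:
                        z += Z[d - e - 1, a] * h
            Z[d, a] = z
    return Z, H, G


@njit(cache=False)
def outside_window(Z, H, G, codes, wmat, hfac, s, W, ml, span, no_lp):
    """Exact pair probabilities for the window [s, s+W-1]; local indices."""
    OZ = np.zeros((W, W))
    OH = np.zeros((W, W))
    OG = np.zeros((W, W))
    OY = np.zeros((W, W))
    OZ[0, W - 1] = 1.0
    for d in range(W - 1, -1, -1):
        emax = min(d, span)
        for u in range(W - d):
            v = u + d
            if no_lp:
                oy = OY[u, v]
                if oy != 0.0:
                    OZ[u, v] += oy
                    OH[u, v] -= oy
            oz = OZ[u, v]
            if oz != 0.0:
                if d >= 1:
                    OZ[u, v - 1] += oz
                for e in range(ml + 1, emax + 1):
                    k = v - e
                    h = H[e, s + k]
                    if e == d:
                        OH[k, v] += oz
                    else:
                        if h != 0.0:
                            zl = Z[k - 1 - u, s + u]
                            OZ[u, k - 1] += oz * h
                            OH[k, v] += oz * zl
            if ml + 1 <= d <= span:
                w = wmat[codes[s + u], codes[s + v]]
                if w > 0.0:
                    oh = OH[u, v]
                    if no_lp:
                        OG[u + 1, v - 1] += oh * (w * hfac)
                        og = OG[u, v]
                        if og != 0.0:
                            OY[u + 1, v - 1] += og * w
                            OG[u + 1, v - 1] += og * w
                    else:
                        OZ[u + 1, v - 1] += oh * w
    ztot = Z[W - 1, s]
    P = np.zeros((W, W))
    for d in range(ml + 1, min(W - 1, span) + 1):
        for u in range(W - d):
            v = u + d
            if no_lp:
                num = OH[u, v] * H[d, s + u] + OG[u, v] * G[d, s + u]
            else:
                num = OH[u, v] * H[d, s + u]
            if num != 0.0:
                P[u, v] = num / ztot
    return P
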