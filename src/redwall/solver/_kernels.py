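"""Optional numba-compiled inner loops (pure-numpy fallbacks elsewhere).

The batched tridiagonal sweeps of the ADI solver and the 4-point-kernel
scatter/gather of the immersed-boundary coupling dominate the per-step cost;
both are simple loops that JIT well.  Import failures (or NUMBA_DISABLE_JIT
environments) degrade gracefully to the numpy implementations.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def tridiag_batch(a, b, c, d):
    """Thomas solve along axis 0 for (n, m) batches, in place on d."""
    n, m = d.shape
    cp = np.empty((n, m))
    for j in range(m):
        cp[0, j] = c[0, j] / b[0, j]
        d[0, j] = d[0, j] / b[0, j]
        for i in range(1, n):
            denom = b[i, j] - a[i, j] * cp[i - 1, j]
            cp[i, j] = c[i, j] / denom
            d[i, j] = (d[i, j] - a[i, j] * d[i - 1, j]) / denom
        for i in range(n - 2, -1, -1):
            d[i, j] -= cp[i, j] * d[i + 1, j]
    return d


@njit(cache=True)
def tridiag_periodic_batch(a, b, c, d):
    """Cyclic Thomas (Sherman-Morrison) along axis 0 for (n, m) batches."""
    n, m = d.shape
    out = np.empty((n, m))
    for j in range(m):
        gamma = -b[0, j]
        bb = np.empty(n)
        for i in range(n):
            bb[i] = b[i, j]
        bb[0] = b[0, j] - gamma
        bb[n - 1] = b[n - 1, j] - a[0, j] * c[n - 1, j] / gamma
        # solve A' y = d and A' z = q
        y = np.empty(n)
        z = np.empty(n)
        q = np.zeros(n)
        q[0] = gamma
        q[n - 1] = c[n - 1, j]
        cp = np.empty(n)
        cp[0] = c[0, j] / bb[0]
        y[0] = d[0, j] / bb[0]
        z[0] = q[0] / bb[0]
        for i in range(1, n):
            denom = bb[i] - a[i, j] * cp[i - 1]
            cp[i] = c[i, j] / denom
            y[i] = (d[i, j] - a[i, j] * y[i - 1]) / denom
            z[i] = (q[i] - a[i, j] * z[i - 1]) / denom
        for i in range(n - 2, -1, -1):
            y[i] -= cp[i] * y[i + 1]
            z[i] -= cp[i] * z[i + 1]
        fact = (y[0] + a[0, j] * y[n - 1] / gamma) \
            / (1.0 + z[0] + a[0, j] * z[n - 1] / gamma)
        for i in range(n):
            out[i, j] = y[i] - fact * z[i]
    return out


@njit(cache=True)
def spread_points(base, wx, wy, wz, vals, out, periodic_x):
    """Scatter vals * kernel weights onto a face grid (adds in place)."""
    npts = base.shape[0]
    nx, ny, nz = out.shape
    for p in range(npts):
        for i in range(4):
            bi = base[p, 0] + i
            if periodic_x:
                bi = bi % nx
            wxi = wx[p, i]
            for j in range(4):
                bj = base[p, 1] + j
                wij = wxi * wy[p, j]
                for k in range(4):
                    bk = base[p, 2] + k
                    out[bi, bj, bk] += wij * wz[p, k] * vals[p]


@njit(cache=True)
def gather_points(base, wx, wy, wz, field, periodic_x):
    """Interpolate a face-grid field at kernel points."""
    npts = base.shape[0]
    nx = field.shape[0]
    out = np.zeros(npts)
    for p in range(npts):
        acc = 0.0
        for i in range(4):
            bi = base[p, 0] + i
            if periodic_x:
                bi = bi % nx
            wxi = wx[p, i]
            for j in range(4):
                bj = base[p, 1] + j
                wij = wxi * wy[p, j]
                for k in range(4):
                    acc += wij * wz[p, k] * field[bi, bj, base[p, 2] + k]
        out[p] = acc
    return out
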