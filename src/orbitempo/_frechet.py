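"""Dynamic-programming kernels for curve distances.

Numba-jitted when available; a pure-Python fallback keeps the package
importable without a working JIT.  All kernels operate on dense pairwise
distance matrices so the cyclic-shift search for closed curves can reuse
one matrix.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _frechet_dp_shift(C, shift):
    """Discrete Frechet value on cost matrix C with columns rolled by *shift*."""
    n, m = C.shape
    row = np.empty(m)
    prev = np.empty(m)
    for j in range(m):
        c = C[0, (j + shift) % m]
        prev[j] = max(c, prev[j - 1]) if j > 0 else c
    for i in range(1, n):
        for j in range(m):
            c = C[i, (j + shift) % m]
            if j == 0:
                best = prev[0]
            else:
                best = min(prev[j], prev[j - 1], row[j - 1])
            row[j] = max(c, best)
        for j in range(m):
            prev[j] = row[j]
    return prev[m - 1]


@njit(cache=False)
def _frechet_closed_scan(C, best0):
    """Minimum Frechet value over all cyclic shifts of the second curve.

    ``best0`` seeds the incumbent (e.g. from the unshifted orientation);
    shifts whose forced start pairing already exceeds the incumbent are
    pruned.
    """
    n, m = C.shape
    best = best0
    best_shift = -1
    for s in range(m):
        if C[0, s % m] >= best:
            continue
        v = _frechet_dp_shift(C, s)
        if v < best:
            best = v
            best_shift = s
    return best, best_shift


@njit(cache=False)
def _dtw_dp(C):
    """Classic accumulated-cost dynamic time warping on cost matrix C."""
    n, m = C.shape
    D = np.empty((n, m))
    D[0, 0] = C[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + C[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + C[i, 0]
        for j in range(1, m):
            D[i, j] = C[i, j] + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return D[n - 1, m - 1]


def frechet_witness(C, shift: int = 0):
    """Backtrack one optimal monotone coupling for a (shifted) cost matrix."""
    n, m = C.shape
    Cs = C[:, (np.arange(m) + shift) % m]
    D = np.empty((n, m))
    D[0, :] = np.maximum.accumulate(Cs[0, :])
    for i in range(1, n):
        D[i, 0] = max(Cs[i, 0], D[i - 1, 0])
        for j in range(1, m):
            D[i, j] = max(Cs[i, j], min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1]))
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            k = int(np.argmin([D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]]))
            if k == 0:
                i, j = i - 1, j - 1
            elif k == 1:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return [(i, (j + shift) % m) for i, j in path]
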