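"""Hot inner loops, JIT-compiled when numba is available.

Only the non-bonded pair sum lives here: it dominates the per-step cost
for any system big enough to matter.  The numpy implementation in
``forcefield`` remains the reference path and is used when numba is
absent; both paths are exercised against the same finite-difference
oracle in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally installed
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(fn):
            return fn

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False, fastmath=False)
def _nonbonded_kernel(x, pi, pj, eps, sig, qq, rc, rq, f):
    """Energy-shifted LJ + screened Coulomb over a pair list.

    Accumulates forces into ``f`` in place (single-threaded, so the
    result is deterministic) and returns (E_lj, E_coulomb).
    """
    e_lj = 0.0
    e_q = 0.0
    rc2 = rc * rc
    for m in range(pi.shape[0]):
        i = pi[m]
        j = pj[m]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2 or r2 <= 0.0:
            continue
        r = np.sqrt(r2)
        s2 = sig[m] * sig[m] / r2
        sr6 = s2 * s2 * s2
        sr12 = sr6 * sr6
        src3 = sig[m] / rc
        src6 = src3 * src3 * src3
        src6 = src6 * src6
        e_lj += 4.0 * eps[m] * (sr12 - sr6 - (src6 * src6 - src6))
        du = 4.0 * eps[m] * (-12.0 * sr12 + 6.0 * sr6) / r
        if r < rq:
            w = 1.0 - r / rq
            e_q += qq[m] / r * w * w
            du += qq[m] * (-(w * w) / r2 - 2.0 * w / (r * rq))
        g = du / r
        fx = g * dx
        fy = g * dy
        fz = g * dz
        f[j, 0] -= fx
        f[j, 1] -= fy
        f[j, 2] -= fz
        f[i, 0] += fx
        f[i, 1] += fy
        f[i, 2] += fz
    return e_lj, e_q
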