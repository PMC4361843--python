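"""Compiled pairwise force kernel.

The O(N^2) force loop dominates simulation cost; a numba-compiled kernel
makes production runs interactive. ``pair_forces_total`` computes, in one
pass, the WCA excluded-volume force between all lipid pairs and
lipid-anchor pairs plus the screened-Coulomb (Yukawa) force between charged
pairs, with the same linearised core as the reference numpy path (forces
evaluated at ``max(r, core_fraction * sigma)``).

If numba is unavailable the caller falls back to the vectorised numpy
implementation in :mod:`jmlipid.simulate`; results are identical to
floating-point round-off.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by which path runs
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def _accumulate(
    out: np.ndarray,
    pos: np.ndarray,
    q: np.ndarray,
    other_pos: np.ndarray,
    other_q: np.ndarray,
    box: float,
    sigma: float,
    eps_elec: float,
    lam: float,
    elec_cutoff: float,
    core_fraction: float,
    wca_eps: float,
    symmetric: bool,
) -> None:
    r_wca = 2.0 ** (1.0 / 6.0) * sigma
    r_core = core_fraction * sigma
    max_cut2 = max(r_wca, elec_cutoff) ** 2
    n = pos.shape[0]
    m = other_pos.shape[0]
    for i in range(n):
        j_start = i + 1 if symmetric else 0
        for j in range(j_start, m):
            dx = pos[i, 0] - other_pos[j, 0]
            dy = pos[i, 1] - other_pos[j, 1]
            dx -= box * np.round(dx / box)
            dy -= box * np.round(dy / box)
            r2 = dx * dx + dy * dy
            if r2 > max_cut2 or r2 < 1e-12:
                continue
            r = np.sqrt(r2)
            rs = r if r > r_core else r_core
            fmag = 0.0
            if r < r_wca:
                inv2 = (sigma / rs) ** 2
                inv6 = inv2 * inv2 * inv2
                fmag += 24.0 * wca_eps * (2.0 * inv6 * inv6 - inv6) / rs
            if eps_elec > 0.0 and r < elec_cutoff:
                qq = q[i] * other_q[j]
                if qq != 0.0:
                    fmag += (
                        eps_elec * qq * np.exp(-rs / lam)
                        * (1.0 / (rs * rs) + 1.0 / (lam * rs))
                    )
            fx = fmag * dx / r
            fy = fmag * dy / r
            out[i, 0] += fx
            out[i, 1] += fy
            if symmetric:
                out[j, 0] -= fx
                out[j, 1] -= fy
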