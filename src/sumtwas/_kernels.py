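"""Numba-compiled inner loops for the coordinate-ascent variational updates.

The Gauss-Seidel sweep below is shared by the summary-statistic model and
the individual-level-eQTL baseline: both have a posterior whose coordinate
updates take the form

    s2_k  = 1 / (a1 * D1_kk + a2 * D2_kk + 1/sigma2)
    mu_k <- s2_k * (b1 * z1_k + b2 * z2_k
                    - a1 * sum_{l != k} D1_kl mu_l
                    - a2 * sum_{l != k} D2_kl mu_l)

with model-specific scalar coefficients (a1, b1, a2, b2) and symmetric
matrices D1, D2.  The running products r1 = D1 @ mu and r2 = D2 @ mu are
updated incrementally so each coordinate costs O(m).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gauss_seidel_sweep(mu, s2, z1, z2, D1, D2, b1, a1, b2, a2, r1, r2):
    """One in-place ascending sweep of coordinate updates.

    ``r1`` and ``r2`` must enter as ``D1 @ mu`` and ``D2 @ mu``; they are
    kept consistent as ``mu`` changes, so consecutive sweeps can reuse them.
    """
    m = mu.shape[0]
    for k in range(m):
        old = mu[k]
        lin = (
            b1 * z1[k]
            + b2 * z2[k]
            - a1 * (r1[k] - D1[k, k] * old)
            - a2 * (r2[k] - D2[k, k] * old)
        )
        new = s2[k] * lin
        d = new - old
        if d != 0.0:
            for l in range(m):
                r1[l] += D1[l, k] * d
                r2[l] += D2[l, k] * d
            mu[k] = new
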