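"""Numba kernel for the exact Gillespie simulation of the repair network.

The reaction system per channel i is

    x + E_i --K_i-->  y_i          (recruitment, propensity K_i * x * E_i)
    y_i     --K'_i--> 0 + E_i      (ligation,    propensity K'_i * y_i)

with the enzyme pool conserved, E_i = C_i - y_i.  State is held piecewise
constant between events; snapshots are taken at the requested output grid.
The kernel also records every ligation event time (one per completed break),
which gives the exact per-break completion-time sample used by the
closed-form oracles.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ssa_core(x0, K, Kprime, C, t_grid, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_ch = K.shape[0]
    n_t = t_grid.shape[0]
    x = x0
    y = np.zeros(n_ch, np.int64)
    nrec = np.zeros(n_ch, np.int64)
    nlig = np.zeros(n_ch, np.int64)
    x_out = np.zeros(n_t, np.int64)
    y_out = np.zeros((n_t, n_ch), np.int64)
    nrec_out = np.zeros((n_t, n_ch), np.int64)
    nlig_out = np.zeros((n_t, n_ch), np.int64)
    lig_t = np.empty(x0, np.float64)
    lig_ch = np.empty(x0, np.int64)
    nl = 0
    a = np.empty(2 * n_ch, np.float64)
    t = 0.0
    gi = 0
    while gi < n_t:
        a_tot = 0.0
        for i in range(n_ch):
            a[i] = K[i] * x * (C[i] - y[i])
            a[n_ch + i] = Kprime[i] * y[i]
            a_tot += a[i] + a[n_ch + i]
        if a_tot <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / a_tot)
        # current state holds on [t, t_next): emit any grid points in there
        while gi < n_t and t_grid[gi] < t_next:
            x_out[gi] = x
            for i in range(n_ch):
                y_out[gi, i] = y[i]
                nrec_out[gi, i] = nrec[i]
                nlig_out[gi, i] = nlig[i]
            gi += 1
        if gi >= n_t or a_tot <= 0.0:
            break
        u = np.random.random() * a_tot
        acc = 0.0
        r = 2 * n_ch - 1
        for j in range(2 * n_ch):
            acc += a[j]
            if u < acc:
                r = j
                break
        if r < n_ch:
            x -= 1
            y[r] += 1
            nrec[r] += 1
        else:
            i = r - n_ch
            y[i] -= 1
            nlig[i] += 1
            lig_t[nl] = t_next
            lig_ch[nl] = i
            nl += 1
        t = t_next
    return x_out, y_out, nrec_out, nlig_out, lig_t[:nl], lig_ch[:nl]
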