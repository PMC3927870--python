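"""Numba-compiled ODE right-hand sides.

One generic kernel per model class, parameterised entirely by index and
value arrays, so each compiles once per process and serves every network.
Kept in lock-step with the numpy implementation in ``model._CompiledModel``
(property-tested against it); the log-space Hill evaluation with a clipped
exponent matches ``model._hill_power``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rhs_mrna_protein", "rhs_protein_only"]


@njit(cache=True, fastmath=False)
def _hill_terms(p, src, Kd, h, is_act, f):
    for j in range(src.shape[0]):
        P = p[src[j]]
        if P <= 0.0:
            x = 0.0
        else:
            lx = h[j] * (np.log(P) - np.log(Kd[j]))
            if lx > 700.0:
                lx = 700.0
            elif lx < -700.0:
                lx = -700.0
            x = np.exp(lx)
        f[j] = x / (1.0 + x) if is_act[j] else 1.0 / (1.0 + x)


@njit(cache=True, fastmath=False)
def rhs_mrna_protein(y, active, src, Kd, h, is_act, pair_reg, pair_tgt,
                     pro, rbs, mdeg, pdeg):
    G = pro.shape[0]
    out = np.empty(2 * G)
    m = y[:G]
    p = y[G:]
    f = np.empty(src.shape[0])
    _hill_terms(p, src, Kd, h, is_act, f)
    regprod = np.ones(G)
    for k in range(pair_reg.shape[0]):
        regprod[pair_tgt[k]] *= f[pair_reg[k]]
    for i in range(G):
        out[i] = active[i] * pro[i] * regprod[i] - mdeg[i] * m[i]
        out[G + i] = active[i] * rbs[i] * m[i] - pdeg * p[i]
    return out


@njit(cache=True, fastmath=False)
def rhs_protein_only(y, active, src, Kd, h, is_act, pair_reg, pair_tgt,
                     syn, deg, basal):
    G = deg.shape[0]
    f = np.empty(src.shape[0])
    _hill_terms(y, src, Kd, h, is_act, f)
    production = basal.copy()
    for k in range(pair_reg.shape[0]):
        production[pair_tgt[k]] += syn[pair_reg[k]] * f[pair_reg[k]]
    out = np.empty(G)
    for i in range(G):
        out[i] = active[i] * production[i] - deg[i] * y[i]
    return out
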