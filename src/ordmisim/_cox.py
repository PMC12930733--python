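"""Numba kernel for the Efron-tie Cox partial likelihood.

Rows arrive sorted by ascending time; risk-set sums are accumulated from the
latest event time downwards, and each tied-death group contributes through
the Efron fractional adjustment in closed group-level form.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def efron_quantities(X, eta, start, d_group, e_sorted):
    """Log-likelihood, gradient and negative Hessian at ``eta = X @ beta``."""
    n, p = X.shape
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    T1 = np.zeros(p)
    T2 = np.zeros((p, p))
    G = len(start)
    for g in range(G - 1, -1, -1):
        lo = start[g]
        hi = start[g + 1] if g + 1 < G else n
        for i in range(lo, hi):
            wi = w[i]
            S0 += wi
            for a in range(p):
                wa = wi * X[i, a]
                S1[a] += wa
                for b in range(p):
                    S2[a, b] += wa * X[i, b]
        d = int(d_group[g])
        if d == 0:
            continue
        T0 = 0.0
        for a in range(p):
            T1[a] = 0.0
            for b in range(p):
                T2[a, b] = 0.0
        for i in range(lo, hi):
            if e_sorted[i] > 0:
                wi = w[i]
                T0 += wi
                ll += eta[i]
                for a in range(p):
                    wa = wi * X[i, a]
                    T1[a] += wa
                    grad[a] += X[i, a]
                    for b in range(p):
                        T2[a, b] += wa * X[i, b]
        sa = 0.0
        sb = 0.0
        sc = 0.0
        se = 0.0
        sf = 0.0
        for l in range(d):
            frac = l / d
            denom = S0 - frac * T0
            ll -= np.log(denom)
            inv = 1.0 / denom
            sa += inv
            sb += frac * inv
            sc += inv * inv
            se += frac * inv * inv
            sf += frac * frac * inv * inv
        for a in range(p):
            grad[a] -= sa * S1[a] - sb * T1[a]
            for b in range(p):
                hess[a, b] += (sa * S2[a, b] - sb * T2[a, b]
                               - sc * S1[a] * S1[b]
                               + se * (S1[a] * T1[b] + T1[a] * S1[b])
                               - sf * T1[a] * T1[b])
    return ll, grad, hess
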