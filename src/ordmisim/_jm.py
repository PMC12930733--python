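"""Numba kernel for the latent-normal joint-model Gibbs sampler.

The 5-category ordinal variable is represented by 4 latent normal scores
(category = argmax against 0).  For rows with an observed category the
latents are truncated: category 0 pins every score below 0; category c > 0
pins score c above max(0, the other scores) and the others below it.  The
kernel performs one systematic Gibbs sweep over the four components for all
observed rows, using inverse-CDF truncated-normal draws written to avoid
catastrophic cancellation in the tails.
"""

import math

import numpy as np
from numba import njit

_SQRT1_2 = 0.7071067811865476


@njit(cache=True, inline="always")
def _phi(x):
    """Standard normal CDF via erfc (accurate in both tails)."""
    return 0.5 * math.erfc(-x * _SQRT1_2)


@njit(cache=True)
def _ndtri(p):
    """Inverse standard normal CDF (Acklam's rational approximation,
    ~1e-9 relative accuracy -- ample for Monte-Carlo draws)."""
    if p <= 0.0:
        return -38.0
    if p >= 1.0:
        return 38.0
    a = (-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
         1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00)
    b = (-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
         6.680131188771972e+01, -1.328068155288572e+01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
         -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00)
    d = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
         3.754408661907416e+00)
    p_low = 0.02425
    if p < p_low:
        q = math.sqrt(-2.0 * math.log(p))
        x = (((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
            ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    elif p <= 1.0 - p_low:
        q = p - 0.5
        r = q * q
        x = (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * q / \
            (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r + 1.0)
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -(((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
            ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    return x


@njit(cache=True, inline="always")
def _trunc_below(m, sd, b, u):
    """Draw from N(m, sd^2) truncated to (-inf, b]."""
    pb = _phi((b - m) / sd)
    p = u * pb
    if p < 1e-300:
        p = 1e-300
    return m + sd * _ndtri(p)


@njit(cache=True, inline="always")
def _trunc_above(m, sd, a, u):
    """Draw from N(m, sd^2) truncated to [a, inf); symmetric reflection keeps
    tail precision."""
    pb = _phi((m - a) / sd)
    p = u * pb
    if p < 1e-300:
        p = 1e-300
    return m - sd * _ndtri(p)


@njit(cache=True)
def run_chain(Xo, Xm, yo, m, burnin, between, ridge, seed,
              estimate_cov=False):
    """Full Gibbs chain of the latent-normal joint model.

    Returns ``(imputed, trace)``: imputed categories (m, n_mis) drawn at the
    scheduled extraction iterations, and the per-iteration mean latent trace
    (total_iters, 4) for convergence diagnostics.  All randomness comes from
    numba's internal PRNG seeded with ``seed``.
    """
    np.random.seed(seed)
    n_obs, p = Xo.shape
    n_mis = Xm.shape[0]
    q = 4
    nu0 = q + 2

    XtX = Xo.T @ Xo + ridge * np.eye(p)
    Lx = np.linalg.cholesky(XtX)
    others = np.empty((q, 3), dtype=np.int64)
    for c in range(q):
        k = 0
        for j in range(q):
            if j != c:
                others[c, k] = j
                k += 1

    Z = np.full((n_obs, q), -0.5)
    for i in range(n_obs):
        if yo[i] > 0:
            Z[i, yo[i] - 1] = 0.5
    B = np.zeros((p, q))
    # fixed latent residual covariance (1 on the diagonal, 1/2 off-diagonal):
    # the identification constraint of the latent-normal representation of a
    # single categorical variable; with estimate_cov it is only the start
    Sigma = 0.5 * (np.eye(q) + np.ones((q, q)))
    coef = np.empty((q, 3))
    csd = np.empty(q)

    total_iters = burnin + (m - 1) * between
    trace = np.empty((total_iters, q))
    imputed = np.empty((m, n_mis), dtype=np.int64)
    ext = 0
    XB = Xo @ B

    for it in range(1, total_iters + 1):
        # conditional coefficients from the precision matrix
        P = np.linalg.inv(Sigma)
        for c in range(q):
            for k in range(3):
                coef[c, k] = -P[c, others[c, k]] / P[c, c]
            v = 1.0 / P[c, c]
            csd[c] = math.sqrt(v if v > 1e-12 else 1e-12)

        U = np.random.random_sample((n_obs, q))
        gibbs_sweep(Z, XB, others, coef, csd, yo, U)

        # conjugate coefficient draw: vec(B) ~ N(vec(Bhat), Sigma (x) XtX^-1)
        Bhat = np.linalg.solve(XtX, Xo.T @ Z)
        Ls = np.linalg.cholesky(Sigma)
        G = np.random.standard_normal((p, q))
        # solve Lx.T @ H = G  (upper-triangular back substitution)
        H = np.empty((p, q))
        for col in range(q):
            for i in range(p - 1, -1, -1):
                s = G[i, col]
                for j in range(i + 1, p):
                    s -= Lx[j, i] * H[j, col]
                H[i, col] = s / Lx[i, i]
        B = Bhat + H @ Ls.T
        XB = Xo @ B

        if estimate_cov:
            # inverse-Wishart draw of the latent covariance (Bartlett); only
            # proper when several incomplete variables share the latents --
            # with one categorical variable the covariance is not identified
            R = Z - XB
            S = np.eye(q) + R.T @ R
            Lw = np.linalg.cholesky(np.linalg.inv(S))
            A = np.zeros((q, q))
            df = nu0 + n_obs
            for i in range(q):
                A[i, i] = math.sqrt(np.random.chisquare(df - i))
                for j in range(i):
                    A[i, j] = np.random.standard_normal()
            W = Lw @ A
            W = W @ W.T
            Sigma = np.linalg.inv(W)
            Sigma = 0.5 * (Sigma + Sigma.T)

            # the category pattern is invariant to a global rescaling of
            # (Z, B, Sigma); pin trace(Sigma) = q so the chain mixes over an
            # identified section instead of random-walking along the ridge
            s2 = np.trace(Sigma) / q
            s = math.sqrt(s2)
            Sigma = Sigma / s2
            B = B / s
            for i in range(n_obs):
                for c in range(q):
                    Z[i, c] /= s
                    XB[i, c] /= s

        for c in range(q):
            trace[it - 1, c] = Z[:, c].mean()

        if it >= burnin and (it - burnin) % between == 0 and ext < m:
            Ls = np.linalg.cholesky(Sigma)
            Gm = np.random.standard_normal((n_mis, q))
            Zm = Xm @ B + Gm @ Ls.T
            for i in range(n_mis):
                top = 0.0
                arg = 0
                for c in range(q):
                    if Zm[i, c] > top:
                        top = Zm[i, c]
                        arg = c + 1
                imputed[ext, i] = arg
            ext += 1

    return imputed, trace


@njit(cache=True)
def gibbs_sweep(Z, mu, others, coef, csd, cat, U):
    """One Gibbs sweep over the 4 latent components of every observed row.

    Z (n,4) is updated in place.  mu = X @ B; ``others``/``coef``/``csd``
    encode each component's conditional distribution given the rest under
    the current latent covariance; ``cat`` holds the observed categories and
    U (n,4) the uniform variates for this sweep.
    """
    n = Z.shape[0]
    for c in range(4):
        o0, o1, o2 = others[c, 0], others[c, 1], others[c, 2]
        b0, b1, b2 = coef[c, 0], coef[c, 1], coef[c, 2]
        sd = csd[c]
        for i in range(n):
            m = (mu[i, c]
                 + b0 * (Z[i, o0] - mu[i, o0])
                 + b1 * (Z[i, o1] - mu[i, o1])
                 + b2 * (Z[i, o2] - mu[i, o2]))
            k = cat[i]
            if k == 0:
                Z[i, c] = _trunc_below(m, sd, 0.0, U[i, c])
            elif k == c + 1:
                lo = 0.0
                if Z[i, o0] > lo:
                    lo = Z[i, o0]
                if Z[i, o1] > lo:
                    lo = Z[i, o1]
                if Z[i, o2] > lo:
                    lo = Z[i, o2]
                Z[i, c] = _trunc_above(m, sd, lo, U[i, c])
            else:
                Z[i, c] = _trunc_below(m, sd, Z[i, k - 1], U[i, c])
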