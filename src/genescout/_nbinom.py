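"""Negative-binomial utilities shared by the simulator, batch correction and DE.

Parameterization follows the RNA-seq convention: mean ``mu`` and dispersion
``alpha`` with variance ``mu + alpha * mu**2``.  This maps onto scipy's
``nbinom(n, p)`` via ``n = 1/alpha`` and ``p = n / (n + mu)``; ``alpha -> 0``
recovers the Poisson limit, which is handled by flooring ``alpha`` at a tiny
positive value (scipy's betainc-based CDF stays accurate for n up to ~1e10).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln

ALPHA_FLOOR = 1e-10


def _np_params(mu, alpha):
    mu = np.asarray(mu, dtype=float)
    alpha = np.maximum(np.asarray(alpha, dtype=float), ALPHA_FLOOR)
    n = 1.0 / alpha
    p = n / (n + mu)
    return n, p


def nb_cdf(y, mu, alpha):
    """P(Y <= y) for NB(mean=mu, dispersion=alpha); y < 0 gives 0."""
    n, p = _np_params(mu, alpha)
    y = np.asarray(y, dtype=float)
    out = stats.nbinom.cdf(y, n, p)
    return np.where(y < 0, 0.0, out)


def nb_ppf(q, mu, alpha):
    """Smallest integer y with CDF(y) >= q."""
    n, p = _np_params(mu, alpha)
    return stats.nbinom.ppf(q, n, p)


def nb_logpmf(y, mu, alpha):
    """Log PMF, vectorized, written out via gammaln (cheap in tight loops)."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.maximum(np.asarray(alpha, dtype=float), ALPHA_FLOOR)
    y = np.asarray(y, dtype=float)
    n = 1.0 / alpha
    return (
        gammaln(y + n)
        - gammaln(n)
        - gammaln(y + 1.0)
        + n * np.log(n / (n + mu))
        + y * np.log(mu / (n + mu))
    )


def nb_rvs(rng: np.random.Generator, mu, alpha):
    """Draw NB counts with the given mean/dispersion (Poisson when alpha~0)."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson_like = alpha < 1e-8
    if np.any(poisson_like):
        out[poisson_like] = rng.poisson(mu[poisson_like])
    if np.any(~poisson_like):
        a = alpha[~poisson_like]
        m = mu[~poisson_like]
        n = 1.0 / a
        p = n / (n + m)
        out[~poisson_like] = rng.negative_binomial(n, p)
    return out


def fit_alpha_ml(y: np.ndarray, mu: np.ndarray, lo: float = 1e-8, hi: float = 50.0,
                 iters: int = 60):
    """Profile-ML dispersion per row of ``y`` with fixed per-entry means ``mu``.

    Vectorized golden-section search over log(alpha) across all rows at once.
    Returns (alpha_hat, at_bound) where at_bound flags rows whose optimum sits
    on the search boundary (flat or degenerate rows).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    G = y.shape[0]

    def negll(log_a):
        a = np.exp(log_a)[:, None]
        return -nb_logpmf(y, mu, np.broadcast_to(a, y.shape)).sum(axis=1)

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a_lo = np.full(G, np.log(lo))
    a_hi = np.full(G, np.log(hi))
    c = a_hi - invphi * (a_hi - a_lo)
    d = a_lo + invphi * (a_hi - a_lo)
    fc, fd = negll(c), negll(d)
    for _ in range(iters):
        shrink_right = fc < fd
        a_hi = np.where(shrink_right, d, a_hi)
        a_lo = np.where(shrink_right, a_lo, c)
        c = a_hi - invphi * (a_hi - a_lo)
        d = a_lo + invphi * (a_hi - a_lo)
        # recompute both ends; vectorized over all rows so the extra eval is cheap
        fc, fd = negll(c), negll(d)
    log_a = (a_lo + a_hi) / 2.0
    alpha = np.exp(log_a)
    at_bound = (alpha <= lo * 1.05) | (alpha >= hi * 0.95)
    return alpha, at_bound
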