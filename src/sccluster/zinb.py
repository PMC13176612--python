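"""Zero-inflated negative binomial probability mass and loss.

The ZINB mixes a point mass at zero (dropout probability pi) with a negative
binomial in mean/dispersion form:

    NB(k | mu, theta) = Gamma(k+theta) / (Gamma(theta) k!)
                        * (theta/(theta+mu))^theta * (mu/(theta+mu))^k

    ZINB(k) = pi + (1-pi) * NB(0 | mu, theta)   if k = 0
            = (1-pi) * NB(k | mu, theta)        if k > 0

All loss evaluation happens in log space (log-sum-exp at k = 0) so that tiny
probabilities never underflow to -inf.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["nb_log_pmf", "zinb_pmf", "zinb_log_pmf", "zinb_loss"]

_EPS = 1e-10


def nb_log_pmf(k, mu, theta) -> np.ndarray:
    """Log pmf of the negative binomial in mean/dispersion parameterization."""
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    if np.any(k < 0) or np.any(k != np.round(k)):
        raise ValueError("k must be a nonnegative integer")
    return (
        gammaln(k + theta)
        - gammaln(theta)
        - gammaln(k + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + k * (np.log(mu) - np.log(theta + mu))
    )


def zinb_log_pmf(k, pi, mu, theta) -> np.ndarray:
    """Elementwise log ZINB pmf, stable for pi in [0, 1]."""
    k = np.asarray(k, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("pi must lie in [0, 1]")
    nb_ll = nb_log_pmf(k, mu, theta)
    # k > 0 branch: log(1-pi) + nb_ll
    log_1mpi = np.log(np.maximum(1.0 - pi, _EPS))
    positive = log_1mpi + nb_ll
    # k = 0 branch: logaddexp(log pi, log(1-pi) + nb_ll(0))
    log_pi = np.log(np.maximum(pi, _EPS))
    zero = np.logaddexp(log_pi, log_1mpi + nb_ll)
    out = np.where(k == 0, zero, positive)
    # exact degenerate endpoints (avoid the eps floor distorting pi = 0 or 1)
    out = np.where((k == 0) & (pi == 1.0), 0.0, out)
    out = np.where((k > 0) & (pi == 1.0), -np.inf, out)
    out = np.where((pi == 0.0), nb_ll, out)
    return out


def zinb_pmf(k, pi, mu, theta) -> np.ndarray | float:
    """ZINB probability mass; scalar in, scalar out."""
    res = np.exp(zinb_log_pmf(k, pi, mu, theta))
    return float(res) if np.isscalar(k) or np.ndim(res) == 0 else res


def zinb_loss(x, pi, mu, theta) -> float:
    """Negative log-likelihood sum over all entries: L = sum_ij -log ZINB(X_ij).

    Raises on non-finite parameters; returns a finite nonnegative value for
    valid inputs (individual -log pmf terms are each >= 0).
    """
    for name, arr in (("pi", pi), ("mu", mu), ("theta", theta)):
        if not np.all(np.isfinite(np.asarray(arr, dtype=float))):
            raise ValueError(f"non-finite values in {name}")
    ll = zinb_log_pmf(x, pi, mu, theta)
    return float(-np.sum(ll))
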