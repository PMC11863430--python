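"""Zero-inflated negative binomial likelihood and Gaussian KL divergence.

The observation model for a raw UMI count ``x`` of one gene in one cell is a
mixture of a point mass at zero (dropout, probability ``pi``) and a negative
binomial with mean ``d * mu_prime`` (``d`` = the cell's sequencing depth,
``mu_prime`` = depth-corrected mean) and dispersion ``r``:

    P(x) = pi * [x == 0] + (1 - pi) * NB(x; d * mu_prime, r)

with the NB parameterized so that variance = m + m^2 / r for mean m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln


@dataclass
class ZINBParams:
    """Per-gene decoder outputs for one cell (or a batch of cells)."""

    mu_prime: np.ndarray      # depth-corrected mean, > 0
    dispersion: np.ndarray    # NB dispersion r, > 0
    dropout_logit: np.ndarray  # logit of dropout probability pi

    def __post_init__(self):
        self.mu_prime = np.asarray(self.mu_prime, dtype=np.float64)
        self.dispersion = np.asarray(self.dispersion, dtype=np.float64)
        self.dropout_logit = np.asarray(self.dropout_logit, dtype=np.float64)
        if np.any(self.mu_prime <= 0) or not np.all(np.isfinite(self.mu_prime)):
            raise ValueError("mu_prime must be positive and finite")
        if np.any(self.dispersion <= 0) or not np.all(np.isfinite(self.dispersion)):
            raise ValueError("dispersion must be positive and finite")
        if not np.all(np.isfinite(self.dropout_logit)):
            raise ValueError("dropout_logit must be finite")


@dataclass
class LatentPosterior:
    """Diagonal-Gaussian posterior q(z | X, b, s, t) for one or more cells."""

    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.log_variance = np.asarray(self.log_variance, dtype=np.float64)
        if not (np.all(np.isfinite(self.mean))
                and np.all(np.isfinite(self.log_variance))):
            raise ValueError("posterior parameters must be finite")


def _nb_logpmf(x, mean, r):
    """Log pmf of NB with mean `mean` and dispersion `r` (var = m + m^2/r)."""
    return (gammaln(x + r) - gammaln(r) - gammaln(x + 1.0)
            + r * (np.log(r) - np.log(r + mean))
            + x * (np.log(mean) - np.log(r + mean)))


def zinb_neg_loglik(x, depth, params: ZINBParams) -> np.ndarray:
    """Negative log-likelihood of raw counts under the ZINB model.

    Parameters
    ----------
    x
        Non-negative integer count(s).
    depth
        Sequencing depth ``d``; the NB mean is ``d * mu_prime``.
    params
        ZINB parameters (broadcastable against ``x``).

    Returns
    -------
    ``-log P(x)`` elementwise, computed in log space so it stays finite for
    large counts and extreme dropout logits.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    depth = np.asarray(depth, dtype=np.float64)
    if np.any(depth <= 0):
        raise ValueError("depth must be positive")

    mean = depth * params.mu_prime
    r = params.dispersion
    s = params.dropout_logit

    # log(1 - pi) = -softplus(s);  log pi = -softplus(-s)
    log1m_pi = -np.logaddexp(0.0, s)
    nb0 = r * (np.log(r) - np.log(r + mean))  # NB log pmf at zero
    # log(pi + (1 - pi) e^{nb0}) = -softplus(-s) + softplus(nb0 - s)
    log_mix0 = -np.logaddexp(0.0, -s) + np.logaddexp(0.0, nb0 - s)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_pos = log1m_pi + _nb_logpmf(np.maximum(x, 1.0), mean, r)
    ll = np.where(x == 0, log_mix0, log_pos)
    return -ll


def kl_divergence(post: LatentPosterior) -> np.ndarray:
    """KL(q || N(0, I)) for a diagonal Gaussian, summed over latent dims.

    Uses the closed form 0.5 * sum(mu^2 + sigma^2 - log sigma^2 - 1) over the
    last axis; one value per cell.
    """
    mu, logvar = post.mean, post.log_variance
    return 0.5 * np.sum(mu ** 2 + np.exp(logvar) - logvar - 1.0, axis=-1)
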