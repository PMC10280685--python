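"""Low-level sampling primitives shared by the Gibbs samplers.

Numerically stable truncated-normal draws (inverse-CDF in log space, so tail
truncations far in either direction do not underflow), small batched
multivariate-normal draws, and an inverse-Wishart wrapper.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtri_exp
from scipy.stats import invwishart

_TINY = 1e-300
_CLIP = 38.0  # standard normal draws never exceed this in magnitude


def truncnorm_positive(mu, rng: np.random.Generator, sd=1.0) -> np.ndarray:
    """Draw X ~ N(mu, sd^2) conditional on X > 0 (elementwise)."""
    mu = np.asarray(mu, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mu.shape)
    u = np.clip(rng.random(mu.shape), _TINY, 1.0)
    z = ndtri_exp(np.log(u) + log_ndtr(mu / sd))
    return mu - sd * np.clip(z, -_CLIP, _CLIP)


def truncnorm_negative(mu, rng: np.random.Generator, sd=1.0) -> np.ndarray:
    """Draw X ~ N(mu, sd^2) conditional on X < 0 (elementwise)."""
    mu = np.asarray(mu, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mu.shape)
    u = np.clip(rng.random(mu.shape), _TINY, 1.0)
    z = ndtri_exp(np.log(u) + log_ndtr(-mu / sd))
    return mu + sd * np.clip(z, -_CLIP, _CLIP)


def truncnorm_sign(mu, positive, rng: np.random.Generator, sd=1.0) -> np.ndarray:
    """Truncate above zero where ``positive`` is True, below zero elsewhere."""
    mu = np.asarray(mu, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mu.shape)
    sgn = np.where(positive, 1.0, -1.0)
    u = np.clip(rng.random(mu.shape), _TINY, 1.0)
    z = ndtri_exp(np.log(u) + log_ndtr(sgn * mu / sd))
    return mu - sgn * sd * np.clip(z, -_CLIP, _CLIP)


def mvn_batch(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from a batch of p-variate normals.

    ``mean`` has shape (n, p) and ``cov`` shape (n, p, p); one draw per row
    via batched Cholesky factors.
    """
    chol = np.linalg.cholesky(cov)
    eps = rng.standard_normal(mean.shape)
    return mean + np.einsum("nij,nj->ni", chol, eps)


def mvn2_from_precision(
    prec11, prec22, prec12, lin1, lin2, rng: np.random.Generator
):
    """Vectorized bivariate normal draws from precision form.

    Posterior precision ``[[prec11, prec12], [prec12, prec22]]`` and linear
    term ``(lin1, lin2)``; returns samples and the posterior means, each as a
    pair of 1-d arrays.  All inputs broadcast elementwise over persons.
    """
    det = prec11 * prec22 - prec12**2
    if np.any(det <= 0):
        raise np.linalg.LinAlgError("singular bivariate precision matrix")
    c11 = prec22 / det
    c22 = prec11 / det
    c12 = -prec12 / det
    m1 = c11 * lin1 + c12 * lin2
    m2 = c12 * lin1 + c22 * lin2
    # closed-form 2x2 Cholesky of the covariance
    l11 = np.sqrt(c11)
    l21 = c12 / l11
    l22 = np.sqrt(np.maximum(c22 - l21**2, 1e-30))
    e1 = rng.standard_normal(np.shape(m1))
    e2 = rng.standard_normal(np.shape(m2))
    return m1 + l11 * e1, m2 + l21 * e1 + l22 * e2, m1, m2


def draw_invwishart(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One inverse-Wishart draw with mean ``scale / (df - p - 1)``."""
    return invwishart.rvs(df=df, scale=scale, random_state=rng)


def geometric_mean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))
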