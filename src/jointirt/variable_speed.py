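"""Differential working-speed joint model (latent growth in speed).

Working speed is allowed to change over the course of the test: each person
has a random intercept (initial speed), a linear trend, and a quadratic
component, evaluated on an equidistant time scale built from the order in
which items are solved (position 1 maps to time 0, position K to (K-1)/K).
The expected log-RT of cell (i, k) is

    lam_k - phi_k * (zeta0_i + zeta1_i * X_ik + zeta2_i * X_ik^2)

and ability is related to the speed components through a 4-variate person
model.  By default the covariances among the speed components themselves are
restricted to zero (they are picked up by the time discriminations) while
the ability-speed covariances stay free; this is parameterized as
independent normal speed components plus a conjugate normal regression of
ability on them, which is positive definite by construction.  When all time
discriminations are fixed to one, the full 4x4 covariance can instead be
estimated freely (``full_covariance=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._mcmc import draw_invwishart, geometric_mean, truncnorm_positive
from .data import TestData
from .sampler import (
    FixedParameters,
    GibbsState,
    MCMCConfig,
    impute_missing,
    sample_augmented_responses,
    sample_item_parameters,
)

__all__ = [
    "GrowthPersonParameters",
    "TimeScale",
    "GrowthConfig",
    "GrowthDraws",
    "build_time_scale",
    "speed_at",
    "fit_growth_model",
]

_COMPONENTS = {"intercept": 1, "linear": 2, "quadratic": 3}


@dataclass
class GrowthPersonParameters:
    """Ability plus the three speed growth components of one person."""

    theta: float
    zeta0: float
    zeta1: float = 0.0
    zeta2: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("theta", "zeta0", "zeta1", "zeta2"):
            if not np.isfinite(getattr(self, nm)):
                raise ValueError(f"{nm} must be finite")


@dataclass
class TimeScale:
    """N x K matrix of time positions in [0, (K-1)/K).

    Each row is a permutation of {0, 1/K, ..., (K-1)/K}; the first item a
    person solves sits at time 0.
    """

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        k = self.x.shape[1]
        expected = np.arange(k) / k
        for i, row in enumerate(self.x):
            if not np.array_equal(np.sort(row), expected):
                raise ValueError(f"row {i} is not a permutation of the equidistant scale")


def build_time_scale(order: np.ndarray, k: int) -> TimeScale:
    """Map solve-order positions (1..K) onto the equidistant time scale.

    ``order`` is an N x K matrix (or a single row) whose entry gives the
    position at which the item was solved; the time value is
    ``(position - 1) / K``.
    """
    order = np.atleast_2d(np.asarray(order))
    if order.shape[1] != k:
        raise ValueError(f"order must have {k} columns")
    expected = np.arange(1, k + 1)
    for i, row in enumerate(order):
        if not np.array_equal(np.sort(row), expected):
            raise ValueError(f"order row {i} is not a permutation of 1..{k}")
    return TimeScale(x=(order - 1.0) / k)


def speed_at(person: GrowthPersonParameters, x) -> np.ndarray | float:
    """Speed of a person at time position x: zeta0 + zeta1*x + zeta2*x^2."""
    x = np.asarray(x, dtype=float)
    out = person.zeta0 + person.zeta1 * x + person.zeta2 * x**2
    return float(out) if out.ndim == 0 else out


@dataclass
class GrowthConfig(MCMCConfig):
    """Run configuration of the differential-speed sampler.

    ``components`` selects how much of the growth structure is estimated
    ('intercept' reduces to the constant-speed model, 'linear' adds the
    trend, 'quadratic' the full model).  ``ident=1`` (default) centers the
    difficulties and leaves the mean ability free; ``ident=2`` fixes the
    mean ability at zero.
    """

    ident: int = 1
    components: str = "quadratic"
    full_covariance: bool = False
    var_z_shape: float = 1.0
    var_z_scale: float = 0.1
    tau2_shape: float = 1.0
    tau2_scale: float = 0.1
    nu_growth: float = 6.0
    v_growth: np.ndarray = field(default_factory=lambda: np.eye(4) * 0.1)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.components not in _COMPONENTS:
            raise ValueError(f"components must be one of {sorted(_COMPONENTS)}")
        if self.guess:
            raise ValueError("guessing is not supported in the differential-speed model")
        self.v_growth = np.asarray(self.v_growth, dtype=float)


class GrowthState(GibbsState):
    """Gibbs state of the differential-speed model."""

    def __init__(self, data, config, fixed, rng, timescale: TimeScale) -> None:
        self.x = None  # set below; GibbsState.__init__ calls _init_values
        super().__init__(
            data, config, None, fixed, rng, allow_empty_records=True
        )
        x = timescale.x
        if x.shape[0] == 1:
            x = np.broadcast_to(x, (self.n, self.k))
        if x.shape != (self.n, self.k):
            raise ValueError("time scale shape does not match the data")
        self.x = np.asarray(x, dtype=float)
        self.common_x = bool(np.all(self.x == self.x[0]))
        self.m = _COMPONENTS[config.components]
        # basis per cell: (N, K, m) -> columns 1, X, X^2 (active subset)
        self.basis = np.stack([self.x**j for j in range(self.m)], axis=2)
        self.zs = np.zeros((self.n, 3))
        self.zs[:, 0] = self.zeta
        self.mu_theta = 0.0
        self.gamma = np.zeros(self.m)
        self.tau2 = 1.0
        self.var_z = np.array([0.25, 0.1, 0.05])[: self.m].copy()
        self.sigma_growth = np.eye(self.m + 1)

    def speed_matrix(self) -> np.ndarray:
        z = self.zs[:, : self.m]
        return np.einsum("nkc,nc->nk", self.basis, z)

    def person_covariance(self) -> np.ndarray:
        """Implied (1+m) x (1+m) covariance of (theta, active zetas)."""
        if self.config.full_covariance:
            return self.sigma_growth
        d = np.diag(self.var_z[: self.m])
        top = self.gamma @ d
        cov = np.zeros((self.m + 1, self.m + 1))
        cov[0, 0] = self.tau2 + self.gamma @ d @ self.gamma
        cov[0, 1:] = top
        cov[1:, 0] = top
        cov[1:, 1:] = d
        return cov


def _sample_growth_persons(state: GrowthState) -> None:
    """Batched (1+m)-variate normal person update."""
    m = state.m
    wz = state.wy * state.s_know
    a, b = state.a, state.b
    prec_t = wz @ (a**2)
    lin_t = (wz * state.z) @ a + wz @ (a * b)

    w_over_s2 = state.wrt / state.sigma2
    bphi = state.basis * state.phi[None, :, None]  # phi_k * basis
    d_resp = state.lam - state.rt
    bw = bphi * w_over_s2[:, :, None]
    u = np.einsum("nkc,nkd->ncd", bw, bphi)
    v = np.einsum("nkc,nk->nc", bw, d_resp)

    cov_prior = state.person_covariance()
    omega = np.linalg.inv(cov_prior)
    mean0 = np.zeros(m + 1)
    mean0[0] = state.mu_theta
    lin0 = omega @ mean0

    prec = np.broadcast_to(omega, (state.n, m + 1, m + 1)).copy()
    prec[:, 0, 0] += prec_t
    prec[:, 1:, 1:] += u
    lin = np.tile(lin0, (state.n, 1))
    lin[:, 0] += lin_t
    lin[:, 1:] += v

    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, lin[..., None])[..., 0]
    eps = state.rng.standard_normal((state.n, m + 1))
    draw = mean + np.linalg.solve(np.swapaxes(chol, 1, 2), eps[..., None])[..., 0]
    state.theta = draw[:, 0]
    state.zs[:, :m] = draw[:, 1:]
    state.zeta = state.zs[:, 0]


def _sample_growth_hyper(state: GrowthState) -> None:
    cfg, rng, m = state.config, state.rng, state.m
    z = state.zs[:, :m]
    if cfg.full_covariance:
        p = np.column_stack([state.theta, z])
        mu = np.zeros(m + 1)
        mu[0] = state.mu_theta
        if cfg.ident == 1:
            omega = np.linalg.inv(state.sigma_growth)
            mu_hat = p.mean(0) @ omega[:, 0] / omega[0, 0]
            sd = 1.0 / np.sqrt(state.n * omega[0, 0])
            state.mu_theta = rng.normal(mu_hat, sd)
            mu[0] = state.mu_theta
        resid = p - mu
        v = cfg.v_growth[: m + 1, : m + 1]
        state.sigma_growth = np.atleast_2d(
            draw_invwishart(cfg.nu_growth + state.n, v + resid.T @ resid, rng)
        )
        return
    # independent speed-component variances
    ssz = (z**2).sum(0)
    shape = cfg.var_z_shape + state.n / 2.0
    state.var_z[:m] = (cfg.var_z_scale + ssz / 2.0) / rng.gamma(shape, 1.0, size=m)
    # conjugate regression of ability on the speed components
    intercept = cfg.ident == 1
    design = np.column_stack([np.ones(state.n), z]) if intercept else z
    q = design.shape[1]
    prec = design.T @ design / state.tau2 + np.eye(q) / cfg.beta_prior_var
    rhs = design.T @ state.theta / state.tau2
    mean = np.linalg.solve(prec, rhs)
    chol = np.linalg.cholesky(prec)
    coef = mean + np.linalg.solve(chol.T, rng.standard_normal(q))
    if intercept:
        state.mu_theta, state.gamma = float(coef[0]), coef[1:]
    else:
        state.mu_theta, state.gamma = 0.0, coef
    resid = state.theta - design @ coef
    state.tau2 = float(
        (cfg.tau2_scale + resid @ resid / 2.0)
        / rng.gamma(cfg.tau2_shape + state.n / 2.0, 1.0)
    )


def _apply_growth_identification(state: GrowthState) -> None:
    m = state.m
    if state.free["a"]:
        g = geometric_mean(state.a)
        state.a /= g
        state.theta *= g
        state.mu_theta *= g
        state.tau2 *= g**2
        state.gamma *= g
        if state.config.full_covariance:
            state.sigma_growth[0, :] *= g
            state.sigma_growth[:, 0] *= g
    if state.free["phi"]:
        g = geometric_mean(state.phi)
        state.phi /= g
        state.zs[:, :m] *= g
        state.var_z[:m] *= g**2
        if state.gamma.size:
            state.gamma /= g
        if state.config.full_covariance:
            state.sigma_growth[1:, :] *= g
            state.sigma_growth[:, 1:] *= g
    if state.config.ident == 1 and state.free["b"]:
        t = -state.b.sum() / state.a.sum()
        state.b = state.b + state.a * t
        state.theta = state.theta + t
        state.mu_theta += t
    # center each speed component; compensate the time intensities using the
    # (common) time-scale row so the likelihood is unchanged
    if state.free["lam"]:
        means = state.zs[:, :m].mean(0)
        state.zs[:, :m] -= means
        if state.common_x:
            shift = state.basis[0] @ means  # (K,)
        else:
            shift = state.basis.mean(axis=0) @ means
        state.lam = state.lam - state.phi * shift
        state.mu_theta += float(state.gamma @ means) if state.gamma.size == m else 0.0
    state.zeta = state.zs[:, 0]


@dataclass
class GrowthDraws:
    """Chains of the differential-speed model.

    ``zeta`` has shape (n_iter, N, m) for the active growth components;
    ``person_cov`` is the implied covariance of (theta, speed components).
    """

    a: np.ndarray
    b: np.ndarray
    phi: np.ndarray
    lam: np.ndarray
    sigma2: np.ndarray
    theta: np.ndarray
    zeta: np.ndarray
    mu_theta: np.ndarray
    person_cov: np.ndarray
    config: GrowthConfig
    timescale: TimeScale

    @property
    def n_burnin(self) -> int:
        return self.config.n_burnin

    def retained(self, name: str) -> np.ndarray:
        return getattr(self, name)[self.n_burnin :]

    def eap(self, name: str) -> np.ndarray:
        return self.retained(name).mean(axis=0)

    def posterior_sd(self, name: str) -> np.ndarray:
        return self.retained(name).std(axis=0, ddof=1)

    def person_effects(self) -> np.ndarray:
        """EAP of (theta, zeta0[, zeta1, zeta2]) per person, N x (1+m)."""
        return np.concatenate(
            [self.eap("theta")[:, None], self.eap("zeta")], axis=1
        )


def fit_growth_model(
    data: TestData,
    timescale: Optional[TimeScale] = None,
    config: Optional[GrowthConfig] = None,
    fixed: Optional[FixedParameters] = None,
) -> GrowthDraws:
    """Fit the differential working-speed joint model by Gibbs sampling.

    When no time scale is given the administration (column) order is used
    for every person.  Records that are entirely missing are allowed: their
    person effects are drawn under the population model, which shrinks them
    to the population averages.
    """
    config = config or GrowthConfig()
    rng = np.random.default_rng(config.seed)
    if timescale is None:
        k = data.y.shape[1]
        timescale = build_time_scale(np.arange(1, k + 1), k)
    state = GrowthState(data, config, fixed, rng, timescale)

    xg, n, k, m = config.n_iter, state.n, state.k, state.m
    out = {
        "a": np.empty((xg, k)),
        "b": np.empty((xg, k)),
        "phi": np.empty((xg, k)),
        "lam": np.empty((xg, k)),
        "sigma2": np.empty((xg, k)),
        "theta": np.empty((xg, n)),
        "zeta": np.empty((xg, n, m)),
        "mu_theta": np.empty(xg),
        "person_cov": np.empty((xg, m + 1, m + 1)),
    }
    for it in range(xg):
        sample_augmented_responses(state)
        _sample_growth_persons(state)
        sample_item_parameters(state)
        _sample_growth_hyper(state)
        _apply_growth_identification(state)
        impute_missing(state)
        for nm in ("a", "b", "phi", "lam", "sigma2", "theta"):
            out[nm][it] = getattr(state, nm)
        out["zeta"][it] = state.zs[:, :m]
        out["mu_theta"][it] = state.mu_theta
        out["person_cov"][it] = state.person_covariance()
    return GrowthDraws(config=config, timescale=timescale, **out)
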