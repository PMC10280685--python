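"""Gibbs sampler for the constant-speed joint RA/RT model.

The joint posterior is explored by data augmentation: each binary response is
backed by a latent continuous propensity ``Z_ik ~ N(a_k*theta_i - b_k, 1)``
whose sign matches the observed response, so that every full conditional is a
(truncated) normal linear-model update.  The blocks, in fixed order per
iteration, are

1. augmentation (latent propensities; guessing indicators under the 3PL),
2. person parameters (theta_i, zeta_i) from bivariate-normal conditionals,
3. item parameters (a_k, b_k, phi_k, lam_k) from a coordinate scan of the
   4-variate normal conditional, with a and phi positive-truncated,
4. residual variances sigma2_k (inverse-gamma) and guessing c_k (Beta),
5. hyperparameters: person covariance (inverse-Wishart), item mean/covariance
   (normal-inverse-Wishart), regression coefficients (conjugate normal),
6. identification (rescaling/shifting to the active identification rule),
7. imputation of missing-at-random cells from their predictive distributions.

Identification: the latent scales are fixed by restricting the product of the
discriminations and of the time discriminations to one.  Rule 1 additionally
forces the difficulties and time intensities to sum to zero (with
likelihood-invariant compensating shifts of the person parameters); rule 2
instead fixes the population means of ability and speed at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

from ._mcmc import (
    draw_invwishart,
    geometric_mean,
    mvn2_from_precision,
    truncnorm_positive,
    truncnorm_sign,
)
from .data import TestData
from .measurement import Parameterization

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "FixedParameters",
    "Predictors",
    "PosteriorDraws",
    "GibbsState",
    "fit_joint_model",
    "sample_augmented_responses",
    "sample_person_parameters",
    "sample_item_parameters",
    "sample_hyperparameters",
    "apply_identification",
    "impute_missing",
    "beta_prior_moments",
]

_PARAM_NAMES = ("a", "b", "phi", "lam")


def beta_prior_moments(shape1: float = 20.0, shape2: float = 80.0) -> tuple[float, float]:
    """Mean and SD of the Beta guessing prior (default Beta(20, 80))."""
    s = shape1 + shape2
    mean = shape1 / s
    sd = float(np.sqrt(shape1 * shape2 / (s**2 * (s + 1.0))))
    return mean, sd


@dataclass
class MCMCConfig:
    """Run configuration of the Gibbs sampler.

    ``n_iter`` is the total number of iterations including burn-in
    (``burnin`` is a percentage).  ``ident`` selects the identification rule
    (1: sum of difficulties/time intensities zero; 2: person means zero).
    ``par1`` reports difficulties on the ability scale; ``td`` frees the time
    discrimination; ``wl`` uses the reciprocal-error-SD time discrimination.
    ``residual`` switches on the within-run fit/residual accumulation after
    ``n_resid_start`` iterations.
    """

    n_iter: int = 1000
    burnin: float = 10.0
    ident: int = 2
    guess: bool = False
    par1: bool = False
    td: bool = True
    wl: bool = False
    residual: bool = False
    n_resid_start: int = 1000
    seed: Optional[int] = None
    # hyperprior constants
    nu_p: float = 3.0
    v_p: np.ndarray = field(default_factory=lambda: np.eye(2))
    nu_i: float = 5.0
    v_i: np.ndarray = field(default_factory=lambda: np.eye(4))
    mu0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 1.0, 3.7]))
    kappa: float = 1.0
    guess_shapes: tuple[float, float] = (20.0, 80.0)
    sigma2_shape: float = 1.0
    sigma2_scale: float = 0.1
    beta_prior_var: float = 100.0
    # anchoring options (used e.g. for oracle validation and sensitivity runs)
    fixed_sigma_p: Optional[np.ndarray] = None
    store_persons: bool = True

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ValueError("n_iter must be positive")
        if not 0.0 <= self.burnin < 100.0:
            raise ValueError("burnin percentage must lie in [0, 100)")
        if self.ident not in (1, 2):
            raise ValueError("ident must be 1 or 2")
        if self.residual and self.n_iter <= self.n_resid_start:
            raise ValueError("residual analysis requires n_iter > n_resid_start")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if min(self.guess_shapes) <= 0:
            raise ValueError("Beta guessing shapes must be positive")
        self.v_p = np.asarray(self.v_p, dtype=float)
        self.v_i = np.asarray(self.v_i, dtype=float)
        self.mu0 = np.asarray(self.mu0, dtype=float).reshape(4)
        if self.fixed_sigma_p is not None:
            self.fixed_sigma_p = np.asarray(self.fixed_sigma_p, dtype=float).reshape(2, 2)

    @property
    def n_burnin(self) -> int:
        return int(np.floor(self.n_iter * self.burnin / 100.0))

    @property
    def parameterization(self) -> Parameterization:
        return Parameterization(bracketed_ra=self.par1, wl=self.wl)


@dataclass
class FixedParameters:
    """Pre-specified item parameter vectors; fixed values are never updated."""

    alpha: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None
    phi: Optional[np.ndarray] = None
    lam: Optional[np.ndarray] = None
    sigma2: Optional[np.ndarray] = None

    def check(self, k: int) -> None:
        for name in ("alpha", "beta", "phi", "lam", "sigma2"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float).reshape(-1)
                if v.shape[0] != k:
                    raise ValueError(f"fixed {name} must have length {k}")
                setattr(self, name, v)


@dataclass
class Predictors:
    """Optional dummy-coded predictor matrices.

    ``xpa``/``xpt`` predict ability/speed (N rows); ``xia``/``xit`` predict
    item difficulty/time intensity (K rows).  Predictors for the
    discriminations are deliberately not supported.
    """

    xpa: Optional[np.ndarray] = None
    xpt: Optional[np.ndarray] = None
    xia: Optional[np.ndarray] = None
    xit: Optional[np.ndarray] = None

    def check(self, n: int, k: int) -> None:
        for name, rows in (("xpa", n), ("xpt", n), ("xia", k), ("xit", k)):
            v = getattr(self, name)
            if v is not None:
                v = np.atleast_2d(np.asarray(v, dtype=float))
                if v.shape[0] != rows:
                    raise ValueError(f"{name} must have {rows} rows")
                setattr(self, name, v)


class GibbsState:
    """Mutable state of one Gibbs run (current draws plus bookkeeping)."""

    def __init__(
        self,
        data: TestData,
        config: MCMCConfig,
        predictors: Optional[Predictors],
        fixed: Optional[FixedParameters],
        rng: np.random.Generator,
        allow_empty_records: bool = False,
    ) -> None:
        self.config = config
        self.rng = rng
        self.n, self.k = data.y.shape
        fixed = fixed or FixedParameters()
        fixed.check(self.k)
        self.fixed = fixed
        predictors = predictors or Predictors()
        predictors.check(self.n, self.k)
        self.predictors = predictors
        data.validate_for_fit(allow_empty_records=allow_empty_records)
        self.data = data

        self.obs_y = data.observed_y
        self.obs_rt = data.observed_rt
        self.use_y = ~data.mbd_y
        self.use_rt = ~data.mbd_rt
        self.mar_y = data.mar_y
        self.mar_rt = data.mar_rt
        self.wy = self.use_y.astype(float)
        self.wrt = self.use_rt.astype(float)

        # which item parameters are free
        self.free = {
            "a": fixed.alpha is None,
            "b": fixed.beta is None,
            "phi": fixed.phi is None and config.td and not config.wl,
            "lam": fixed.lam is None,
            "sigma2": fixed.sigma2 is None,
        }
        self.free_idx = [i for i, nm in enumerate(_PARAM_NAMES) if self.free[nm]]
        d = len(self.free_idx)
        if d and config.nu_i <= d - 1:
            raise ValueError(
                f"item inverse-Wishart degrees of freedom {config.nu_i} must exceed {d - 1}"
            )
        if config.nu_p <= 1:
            raise ValueError("person inverse-Wishart degrees of freedom must exceed 1")

        self._init_designs()
        self._init_values()

    # ------------------------------------------------------------------ setup
    def _init_designs(self) -> None:
        cfg, pr = self.config, self.predictors
        ones = np.ones((self.n, 1))
        blocks_a = [ones] if cfg.ident == 1 else []
        blocks_t = [ones] if cfg.ident == 1 else []
        if pr.xpa is not None:
            blocks_a.append(pr.xpa)
        if pr.xpt is not None:
            blocks_t.append(pr.xpt)
        self.da = np.hstack(blocks_a) if blocks_a else np.zeros((self.n, 0))
        self.dt = np.hstack(blocks_t) if blocks_t else np.zeros((self.n, 0))
        self.beta_theta = np.zeros(self.da.shape[1])
        self.beta_zeta = np.zeros(self.dt.shape[1])
        # item mean designs over the free coordinates: intercept always,
        # predictors only for difficulty / time intensity
        ones_k = np.ones((self.k, 1))
        self.item_designs = {}
        for name in _PARAM_NAMES:
            x = ones_k
            if name == "b" and pr.xia is not None:
                x = np.hstack([ones_k, pr.xia])
            elif name == "lam" and pr.xit is not None:
                x = np.hstack([ones_k, pr.xit])
            self.item_designs[name] = x
        self.has_item_predictors = pr.xia is not None or pr.xit is not None

    def _init_values(self) -> None:
        cfg, rng, fx = self.config, self.rng, self.fixed
        y, rt = self.data.y, self.data.log_rt
        ny = np.maximum(self.obs_y.sum(0), 1)
        p_k = np.clip(np.nansum(np.where(self.obs_y, y, 0.0), axis=0) / ny, 0.05, 0.95)
        nrt = np.maximum(self.obs_rt.sum(0), 1)
        lam0 = np.nansum(np.where(self.obs_rt, rt, 0.0), axis=0) / nrt
        dev = np.where(self.obs_rt, rt - lam0, 0.0)
        s2 = np.clip((dev**2).sum(0) / np.maximum(nrt - 1, 1), 0.05, None)

        self.a = fx.alpha if fx.alpha is not None else np.exp(rng.normal(0, 0.15, self.k))
        self.b = (
            fx.beta
            if fx.beta is not None
            else -ndtri(p_k) + rng.normal(0, 0.1, self.k)
        )
        self.phi = (
            fx.phi
            if fx.phi is not None
            else (
                np.exp(rng.normal(0, 0.15, self.k))
                if self.free["phi"]
                else np.ones(self.k)
            )
        )
        self.lam = fx.lam if fx.lam is not None else lam0 + rng.normal(0, 0.1, self.k)
        self.sigma2 = fx.sigma2 if fx.sigma2 is not None else s2
        self.c = np.full(self.k, 0.2 if cfg.guess else 0.0)

        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-missing rows
            score = np.nanmean(np.where(self.obs_y, y, np.nan), axis=1)
            mrt = np.nanmean(np.where(self.obs_rt, rt - lam0, np.nan), axis=1)
        score = np.where(np.isnan(score), 0.5, score)
        z = (score - score.mean()) / max(score.std(), 1e-6)
        self.theta = z + rng.normal(0, 0.3, self.n)
        mrt = np.where(np.isnan(mrt), 0.0, mrt)
        sd = max(mrt.std(), 1e-6)
        self.zeta = -(mrt - mrt.mean()) / sd * 0.5 + rng.normal(0, 0.2, self.n)

        self.sigma_p = (
            cfg.fixed_sigma_p.copy() if cfg.fixed_sigma_p is not None else np.eye(2)
        )
        d = len(self.free_idx)
        self.mu_i = cfg.mu0[self.free_idx].copy() if d else np.zeros(0)
        self.sigma_i = np.eye(d)
        self.item_beta = {
            "b": np.zeros(self.item_designs["b"].shape[1]),
            "lam": np.zeros(self.item_designs["lam"].shape[1]),
        }
        self.item_beta["b"][:1] = self.mu_i[self.free_idx.index(1)] if self.free["b"] else 0.0
        if self.free["lam"]:
            self.item_beta["lam"][:1] = self.mu_i[self.free_idx.index(3)]

        # working data with imputations for missing-at-random cells
        self.y = np.where(self.mar_y, rng.random(y.shape) < p_k, y)
        self.y = np.where(self.use_y, np.nan_to_num(self.y), 0.0)
        self.rt = np.where(self.mar_rt, lam0 + 0.0, rt)
        self.rt = np.where(self.use_rt, np.nan_to_num(self.rt), 0.0)

        self.s_know = np.ones((self.n, self.k))  # guessing indicator (1 = not guessed)
        self.z = np.zeros((self.n, self.k))

    # --------------------------------------------------------------- utilities
    def eta(self) -> np.ndarray:
        """Probit-scale linear predictor, persons by items."""
        return self.theta[:, None] * self.a - self.b

    def speed_matrix(self) -> np.ndarray:
        """Effective speed per cell (constant across items here; the
        differential-speed state overrides this with a trajectory)."""
        return np.broadcast_to(self.zeta[:, None], (self.n, self.k))

    def rt_mean(self) -> np.ndarray:
        return self.lam - self.phi * self.speed_matrix()

    def person_prior_mean(self) -> np.ndarray:
        m = np.zeros((self.n, 2))
        if self.da.shape[1]:
            m[:, 0] = self.da @ self.beta_theta
        if self.dt.shape[1]:
            m[:, 1] = self.dt @ self.beta_zeta
        return m

    def item_prior_mean(self) -> np.ndarray:
        """K x d prior mean of the free item coordinates."""
        d = len(self.free_idx)
        m = np.tile(self.mu_i, (self.k, 1)) if d else np.zeros((self.k, 0))
        for j, idx in enumerate(self.free_idx):
            name = _PARAM_NAMES[idx]
            if name in ("b", "lam") and self.item_designs[name].shape[1] > 1:
                m[:, j] = self.item_designs[name] @ self.item_beta[name]
        return m

    def item_values(self) -> np.ndarray:
        full = np.column_stack([self.a, self.b, self.phi, self.lam])
        return full[:, self.free_idx]


# ------------------------------------------------------------------ block updates
def sample_augmented_responses(state: GibbsState) -> None:
    """Draw latent propensities Z (and guessing indicators under the 3PL).

    Z is truncated to (0, inf) for non-guessed correct responses and to
    (-inf, 0) for incorrect ones; a correct response is attributed to a
    random guess with posterior odds ``c : (1-c)*Phi(a*theta-b)``.  Guessed
    cells are uninformative for the IRT component.
    """
    rng = state.rng
    eta = state.eta()
    if state.config.guess:
        p_know = (1.0 - state.c) * ndtr(eta)
        p_s1 = p_know / (state.c + p_know + 1e-300)
        correct = state.use_y & (state.y == 1.0)
        s = np.ones((state.n, state.k))
        s[correct] = (rng.random(int(correct.sum())) < p_s1[correct]).astype(float)
        state.s_know = s
    else:
        state.s_know = np.ones((state.n, state.k))
    positive = state.y == 1.0
    state.z = truncnorm_sign(eta, positive, rng)


def sample_person_parameters(state: GibbsState) -> None:
    """Bivariate normal conditional per person.

    The probit likelihood (through Z) informs theta, the log-RT likelihood
    informs zeta, and the bivariate person prior ties the two together.
    """
    wz = state.wy * state.s_know
    a, b, phi, lam, s2 = state.a, state.b, state.phi, state.lam, state.sigma2
    prec_t = wz @ (a**2)
    lin_t = (wz * state.z) @ a + wz @ (a * b)
    phw = phi / s2
    prec_z = state.wrt @ (phi * phw)
    lin_z = state.wrt @ (lam * phw) - (state.wrt * state.rt) @ phw

    omega = np.linalg.inv(state.sigma_p)
    pm = state.person_prior_mean()
    prior_lin = pm @ omega.T
    theta, zeta, _, _ = mvn2_from_precision(
        omega[0, 0] + prec_t,
        omega[1, 1] + prec_z,
        np.full(state.n, omega[0, 1]),
        prior_lin[:, 0] + lin_t,
        prior_lin[:, 1] + lin_z,
        state.rng,
    )
    state.theta, state.zeta = theta, zeta


def _prior_conditionals(state: GibbsState):
    """Per-coordinate conditional prior (weights and variance) of the free
    item coordinates under N_d(mu, Sigma_I); shared across items."""
    d = len(state.free_idx)
    out = {}
    sig = state.sigma_i
    for j in range(d):
        others = [i for i in range(d) if i != j]
        if others:
            s_oo = sig[np.ix_(others, others)]
            w = np.linalg.solve(s_oo, sig[others, j])
            v = sig[j, j] - sig[j, others] @ w
        else:
            w = np.zeros(0)
            v = sig[j, j]
        out[j] = (others, w, max(float(v), 1e-12))
    return out


def sample_item_parameters(state: GibbsState) -> None:
    """Coordinate scan of the 4-variate item conditional, then sigma2 and c.

    Each free coordinate is drawn from its univariate normal conditional
    given the other coordinates (prior cross-terms included); a and phi are
    positive-truncated.  sigma2 is conjugate inverse-gamma and the guessing
    probability conjugate Beta.
    """
    rng, cfg = state.rng, state.config
    wz = state.wy * state.s_know
    th = state.theta
    sp = state.speed_matrix()
    swz = wz.sum(0)
    swzt = th @ wz
    swzt2 = (th**2) @ wz
    swzZ = (wz * state.z).sum(0)
    swztZ = th @ (wz * state.z)
    srt = state.wrt.sum(0)
    srz = (state.wrt * sp).sum(0)
    srz2 = (state.wrt * sp**2).sum(0)
    srtRT = (state.wrt * state.rt).sum(0)
    srzRT = (state.wrt * sp * state.rt).sum(0)

    if state.free_idx:
        cond = _prior_conditionals(state)
        prior_mean = state.item_prior_mean()
        mu = prior_mean  # K x d
        for j, idx in enumerate(state.free_idx):
            name = _PARAM_NAMES[idx]
            others, w, v = cond[j]
            x = state.item_values()
            m_cond = mu[:, j] + (x[:, others] - mu[:, others]) @ w if others else mu[:, j]
            if name == "a":
                prec_lik = swzt2
                lin_lik = swztZ + state.b * swzt
            elif name == "b":
                prec_lik = swz
                lin_lik = state.a * swzt - swzZ
            elif name == "phi":
                prec_lik = srz2 / state.sigma2
                lin_lik = (state.lam * srz - srzRT) / state.sigma2
            else:  # lam
                prec_lik = srt / state.sigma2
                lin_lik = (srtRT + state.phi * srz) / state.sigma2
            prec = prec_lik + 1.0 / v
            mean = (lin_lik + m_cond / v) / prec
            sd = 1.0 / np.sqrt(prec)
            if name in ("a", "phi"):
                draw = truncnorm_positive(mean, rng, sd)
            else:
                draw = mean + sd * rng.standard_normal(state.k)
            setattr(state, name, draw)

    if state.free["sigma2"]:
        resid = state.rt - state.rt_mean()
        sse = (state.wrt * resid**2).sum(0)
        shape = cfg.sigma2_shape + srt / 2.0
        scale = cfg.sigma2_scale + sse / 2.0
        state.sigma2 = scale / rng.gamma(shape, 1.0, size=state.k)

    if cfg.guess:
        n_guess = ((state.s_know == 0) & state.use_y).sum(0)
        n_know = ((state.s_know == 1) & state.use_y).sum(0)
        g1, g2 = cfg.guess_shapes
        state.c = rng.beta(g1 + n_guess, g2 + n_know)


def _sample_person_regression(state: GibbsState) -> None:
    """Seemingly-unrelated conjugate update of the person mean coefficients."""
    qa, qt = state.da.shape[1], state.dt.shape[1]
    q = qa + qt
    if q == 0:
        return
    omega = np.linalg.inv(state.sigma_p)
    prec = np.zeros((q, q))
    rhs = np.zeros(q)
    da, dt = state.da, state.dt
    if qa:
        prec[:qa, :qa] = omega[0, 0] * (da.T @ da)
        rhs[:qa] = omega[0, 0] * (da.T @ state.theta) + omega[0, 1] * (da.T @ state.zeta)
    if qt:
        prec[qa:, qa:] = omega[1, 1] * (dt.T @ dt)
        rhs[qa:] = omega[0, 1] * (dt.T @ state.theta) + omega[1, 1] * (dt.T @ state.zeta)
    if qa and qt:
        cross = omega[0, 1] * (da.T @ dt)
        prec[:qa, qa:] = cross
        prec[qa:, :qa] = cross.T
    prec += np.eye(q) / state.config.beta_prior_var
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    draw = mean + np.linalg.solve(chol.T, state.rng.standard_normal(q))
    state.beta_theta, state.beta_zeta = draw[:qa], draw[qa:]


def _sample_item_hyper(state: GibbsState) -> None:
    d = len(state.free_idx)
    if d == 0:
        return
    cfg, rng = state.config, state.rng
    x = state.item_values()
    k = state.k
    mu0 = cfg.mu0[state.free_idx]
    v_i = cfg.v_i[np.ix_(state.free_idx, state.free_idx)]
    if not state.has_item_predictors:
        xbar = x.mean(0)
        s0 = (x - xbar).T @ (x - xbar)
        dev = xbar - mu0
        scale = v_i + s0 + (cfg.kappa * k / (cfg.kappa + k)) * np.outer(dev, dev)
        state.sigma_i = np.atleast_2d(draw_invwishart(cfg.nu_i + k, scale, rng))
        mean = (cfg.kappa * mu0 + k * xbar) / (cfg.kappa + k)
        cov = state.sigma_i / (cfg.kappa + k)
        state.mu_i = rng.multivariate_normal(mean, cov, method="svd")
        # keep reporting coefficients in sync with the sampled means
        if state.free["b"]:
            state.item_beta["b"][:1] = state.mu_i[state.free_idx.index(1)]
        if state.free["lam"]:
            state.item_beta["lam"][:1] = state.mu_i[state.free_idx.index(3)]
        return
    # with item predictors: GLS for all mean parameters, vague normal prior
    omega = np.linalg.inv(state.sigma_i)
    designs = []
    sizes = []
    for j, idx in enumerate(state.free_idx):
        name = _PARAM_NAMES[idx]
        xj = state.item_designs[name] if name in ("b", "lam") else np.ones((k, 1))
        designs.append(xj)
        sizes.append(xj.shape[1])
    q = sum(sizes)
    prec = np.eye(q) / cfg.beta_prior_var
    rhs = np.zeros(q)
    starts = np.cumsum([0] + sizes)
    for j1 in range(d):
        for j2 in range(d):
            blk = omega[j1, j2] * (designs[j1].T @ designs[j2])
            prec[starts[j1] : starts[j1 + 1], starts[j2] : starts[j2 + 1]] += blk
        rhs[starts[j1] : starts[j1 + 1]] += designs[j1].T @ (x @ omega[:, j1])
    mean = np.linalg.solve(prec, rhs)
    chol = np.linalg.cholesky(prec)
    draw = mean + np.linalg.solve(chol.T, rng.standard_normal(q))
    coefs = [draw[starts[j] : starts[j + 1]] for j in range(d)]
    mu_i = np.zeros(d)
    means_k = np.zeros((k, d))
    for j, idx in enumerate(state.free_idx):
        name = _PARAM_NAMES[idx]
        means_k[:, j] = designs[j] @ coefs[j]
        mu_i[j] = coefs[j][0]
        if name in ("b", "lam"):
            state.item_beta[name] = coefs[j]
    state.mu_i = mu_i
    resid = x - means_k
    state.sigma_i = np.atleast_2d(
        draw_invwishart(cfg.nu_i + k, v_i + resid.T @ resid, rng)
    )


def sample_hyperparameters(state: GibbsState) -> None:
    """Population-level updates: regressions, person and item covariances."""
    cfg = state.config
    _sample_person_regression(state)
    if cfg.fixed_sigma_p is None:
        resid = np.column_stack([state.theta, state.zeta]) - state.person_prior_mean()
        scale = cfg.v_p + resid.T @ resid
        state.sigma_p = draw_invwishart(cfg.nu_p + state.n, scale, state.rng)
    _sample_item_hyper(state)


def apply_identification(state: GibbsState) -> None:
    """Rescale/shift the current draw onto the identified scale.

    All transformations leave the likelihood invariant: rescaling a
    discrimination vector is compensated on the corresponding latent scale,
    and the rule-1 location shifts use ``b <- b + a*t`` with ``t`` chosen so
    the difficulties sum to zero exactly (idem for time intensities).
    """
    if np.any(state.a <= 0) or np.any(state.phi <= 0):
        raise ValueError("invalid state: discriminations must be positive")
    if state.free["a"]:
        g = geometric_mean(state.a)
        state.a /= g
        state.theta *= g
        state.beta_theta *= g
        state.sigma_p[0, 0] *= g**2
        state.sigma_p[0, 1] *= g
        state.sigma_p[1, 0] *= g
    if state.free["phi"]:
        g = geometric_mean(state.phi)
        state.phi /= g
        state.zeta *= g
        state.beta_zeta *= g
        state.sigma_p[1, 1] *= g**2
        state.sigma_p[0, 1] *= g
        state.sigma_p[1, 0] *= g
    if state.config.ident == 1:
        if state.free["b"]:
            t = -state.b.sum() / state.a.sum()
            state.b = state.b + state.a * t
            state.theta = state.theta + t
            if state.beta_theta.size:
                state.beta_theta[0] += t
        if state.free["lam"]:
            s = -state.lam.sum() / state.phi.sum()
            state.lam = state.lam + state.phi * s
            state.zeta = state.zeta + s
            if state.beta_zeta.size:
                state.beta_zeta[0] += s


def impute_missing(state: GibbsState) -> None:
    """Refresh missing-at-random cells from their predictive distributions."""
    rng = state.rng
    if state.mar_y.any():
        p = state.c + (1.0 - state.c) * ndtr(state.eta())
        draw = (rng.random(p.shape) < p).astype(float)
        state.y = np.where(state.mar_y, draw, state.y)
    if state.mar_rt.any():
        mu = state.rt_mean()
        draw = mu + np.sqrt(state.sigma2) * rng.standard_normal(mu.shape)
        state.rt = np.where(state.mar_rt, draw, state.rt)


# ------------------------------------------------------------------ driver
@dataclass
class PosteriorDraws:
    """Per-iteration chains of all parameters plus run metadata.

    Item chains have shape (n_iter, K), person chains (n_iter, N).  Stored
    draws are post-identification.  The difficulty chain is always on the
    ``a*theta - b`` scale; use :meth:`difficulty_same_scale` for the
    bracketed convention.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    phi: np.ndarray
    lam: np.ndarray
    sigma2: np.ndarray
    theta: np.ndarray
    zeta: np.ndarray
    mu_p: np.ndarray
    sigma_p: np.ndarray
    mu_i: np.ndarray
    sigma_i: np.ndarray
    beta_theta: np.ndarray
    beta_zeta: np.ndarray
    config: MCMCConfig
    free: dict
    free_idx: list
    fit_report: object | None = None

    @property
    def n_iter(self) -> int:
        return self.a.shape[0]

    @property
    def n_burnin(self) -> int:
        return self.config.n_burnin

    def retained(self, name: str) -> np.ndarray:
        return getattr(self, name)[self.n_burnin :]

    def eap(self, name: str) -> np.ndarray:
        return self.retained(name).mean(axis=0)

    def posterior_sd(self, name: str) -> np.ndarray:
        return self.retained(name).std(axis=0, ddof=1)

    def difficulty_same_scale(self) -> np.ndarray:
        """Difficulty chain on the ability scale (bracketed convention)."""
        return self.b / self.a

    def time_intensity_same_scale(self) -> np.ndarray:
        return self.lam / self.phi

    def time_discrimination_reported(self) -> np.ndarray:
        """Time-discrimination chain; reciprocal error SD under ``wl``."""
        if self.config.wl:
            return 1.0 / np.sqrt(self.sigma2)
        return self.phi

    def person_correlation(self) -> np.ndarray:
        """Chain of the ability-speed correlation implied by Sigma_P."""
        sp = self.sigma_p
        return sp[:, 0, 1] / np.sqrt(sp[:, 0, 0] * sp[:, 1, 1])


def fit_joint_model(
    data: TestData,
    config: MCMCConfig | None = None,
    predictors: Optional[Predictors] = None,
    fixed: Optional[FixedParameters] = None,
    fit_config=None,
) -> PosteriorDraws:
    """Fit the constant-speed joint model by Gibbs sampling.

    Parameters
    ----------
    data : TestData
        Accuracy and log-RT matrices with missingness masks.
    config : MCMCConfig
        Run configuration; ``config.seed`` controls all randomness,
        including the random starting values.
    predictors : Predictors, optional
        Dummy-coded explanatory variables for ability/speed/difficulty/time
        intensity.
    fixed : FixedParameters, optional
        Pre-specified item parameter vectors (never updated).
    fit_config : FitConfig, optional
        Thresholds of the residual analysis (only used when
        ``config.residual``).

    Returns
    -------
    PosteriorDraws
        All chains plus, when requested, the fit/residual report.
    """
    config = config or MCMCConfig()
    rng = np.random.default_rng(config.seed)
    state = GibbsState(data, config, predictors, fixed, rng)
    n_obs_degenerate = np.nansum(np.abs(np.diff(np.where(state.obs_y, state.data.y, np.nan), axis=0)), axis=0)
    degenerate = np.nonzero(n_obs_degenerate == 0)[0]
    if degenerate.size:
        logger.warning(
            "items %s have constant observed responses; the item prior regularizes them",
            degenerate.tolist(),
        )

    xg, n, k = config.n_iter, state.n, state.k
    out = {
        "a": np.empty((xg, k)),
        "b": np.empty((xg, k)),
        "c": np.empty((xg, k)),
        "phi": np.empty((xg, k)),
        "lam": np.empty((xg, k)),
        "sigma2": np.empty((xg, k)),
        "theta": np.empty((xg, n)) if config.store_persons else np.empty((0, n)),
        "zeta": np.empty((xg, n)) if config.store_persons else np.empty((0, n)),
        "mu_p": np.empty((xg, 2)),
        "sigma_p": np.empty((xg, 2, 2)),
        "mu_i": np.full((xg, 4), np.nan),
        "sigma_i": np.full((xg, 4, 4), np.nan),
        "beta_theta": np.empty((xg, state.da.shape[1])),
        "beta_zeta": np.empty((xg, state.dt.shape[1])),
    }

    accumulator = None
    if config.residual:
        from .modelfit import FitConfig, ResidualAccumulator

        accumulator = ResidualAccumulator(state, fit_config or FitConfig())

    fi = state.free_idx
    for it in range(xg):
        sample_augmented_responses(state)
        sample_person_parameters(state)
        sample_item_parameters(state)
        sample_hyperparameters(state)
        apply_identification(state)
        impute_missing(state)
        for nm in ("a", "b", "c", "phi", "lam", "sigma2"):
            out[nm][it] = getattr(state, nm)
        if config.store_persons:
            out["theta"][it] = state.theta
            out["zeta"][it] = state.zeta
        out["mu_p"][it] = [
            state.beta_theta[0] if (config.ident == 1 and state.beta_theta.size) else 0.0,
            state.beta_zeta[0] if (config.ident == 1 and state.beta_zeta.size) else 0.0,
        ]
        out["sigma_p"][it] = state.sigma_p
        if fi:
            out["mu_i"][it, fi] = state.mu_i
            out["sigma_i"][np.ix_([it], fi, fi)] = state.sigma_i
        out["beta_theta"][it] = state.beta_theta
        out["beta_zeta"][it] = state.beta_zeta
        if accumulator is not None and it >= config.n_resid_start:
            accumulator.update(state)

    draws = PosteriorDraws(
        config=config,
        free=state.free,
        free_idx=fi,
        fit_report=accumulator.finalize() if accumulator is not None else None,
        **out,
    )
    if config.wl:
        draws.phi = 1.0 / np.sqrt(draws.sigma2)
    return draws
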