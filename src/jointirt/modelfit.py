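"""Person-fit, item-fit, residual and distributional diagnostics.

All statistics are computed *inside* the MCMC run: at each retained draw the
statistic is evaluated at the current parameter values, a dichotomous
extreme/not-extreme classification is made against a fixed critical value,
and the indicators are averaged over draws.  The reported quantities are
therefore posterior probabilities of aberrance given the data.

Statistics implemented:

* RA person fit: the negative log-likelihood of a response pattern,
  standardized by its conditional mean and SD (the classical l_z
  construction), approximately standard normal under the model; guessed
  responses are excluded under the 3PL.
* RT person fit: the sum of squared standardized log-RT errors,
  chi-square with (number of observed cells) degrees of freedom.
* Item fit: the same two statistics across an item's column.
* Latent RA residuals: Rao-Blackwellized truncated-normal means, with
  two-sided tail probabilities of exceeding a threshold.
* RT residuals: observed minus expected log-RT with two-sided normal tail
  probabilities.
* A Kolmogorov-Smirnov check of the normality of each item's standardized
  RT residuals (and its latent-RA analogue, which has essentially no power
  and is reported for completeness only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import kolmogorov, ndtr, ndtri
from scipy.stats import chi2, kstest, norm

__all__ = [
    "FitConfig",
    "FitReport",
    "ResidualAccumulator",
    "person_fit_ra",
    "person_fit_rt",
    "joint_person_flag",
    "item_fit_ra",
    "item_fit_rt",
    "latent_residual",
    "rt_residual",
    "ks_test_rt_residuals",
    "ra_critical_value",
    "rt_critical_value",
]

_PCLIP = 1e-12


def ra_critical_value(alpha: float = 0.05) -> float:
    """Standard-normal critical value for the standardized RA statistic."""
    return float(ndtri(1.0 - alpha))


def rt_critical_value(df: int, alpha: float = 0.05) -> float:
    """Chi-square critical value for the RT statistic with ``df`` cells."""
    return float(chi2.ppf(1.0 - alpha, df))


@dataclass
class FitConfig:
    """Thresholds of the fit/residual analysis."""

    alpha: float = 0.05
    c_resid: float = 2.0
    flag_probability: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.c_resid <= 0:
            raise ValueError("c_resid must be positive")

    @property
    def c_ra(self) -> float:
        return ra_critical_value(self.alpha)


# --------------------------------------------------------------- single draw
def _ra_moments(p: np.ndarray, w: np.ndarray, axis: int):
    p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    logit = np.log(p / (1.0 - p))
    m = (w * -(p * np.log(p) + (1.0 - p) * np.log(1.0 - p))).sum(axis=axis)
    v = (w * p * (1.0 - p) * logit**2).sum(axis=axis)
    return m, v


def _ra_stat(y: np.ndarray, p: np.ndarray, w: np.ndarray, axis: int):
    """(raw statistic, standardized statistic) of the RA log-likelihood."""
    p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    ll = w * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    l = -ll.sum(axis=axis)
    m, v = _ra_moments(p, w, axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        ls = np.where(v > 0, (l - m) / np.sqrt(v), np.nan)
    return l, ls


def person_fit_ra(y_row, theta, items, guess_indicators=None, par=None):
    """RA person-fit statistic for one response pattern at one draw.

    Returns ``(statistic, standardized, tail_probability)`` where the tail
    probability is the standard-normal probability of a more extreme
    (larger) standardized statistic.  Missing responses and guessed cells
    (``guess_indicators == 0``) are excluded; with no usable items all
    three values are NaN (with a warning).
    """
    from .measurement import PersonParameters, success_probability

    y = np.asarray(y_row, dtype=float).reshape(-1)
    w = ~np.isnan(y)
    if guess_indicators is not None:
        w = w & (np.asarray(guess_indicators) != 0)
    if not w.any():
        warnings.warn("person has no usable items; RA person fit undefined")
        return np.nan, np.nan, np.nan
    items2 = _strip_guessing(items)
    p = np.atleast_1d(success_probability(PersonParameters(theta=theta), items2, par))
    l, ls = _ra_stat(np.where(w, y, 0.0), p, w.astype(float), axis=0)
    return float(l), float(ls), float(ndtr(-ls)) if np.isfinite(ls) else np.nan


def _strip_guessing(items):
    from .measurement import ItemParameters

    if np.all(np.asarray(items.c) == 0):
        return items
    return ItemParameters(
        a=items.a, b=items.b, c=0.0, phi=items.phi, lam=items.lam, sigma2=items.sigma2
    )


def person_fit_rt(rt_row, zeta, items, par=None):
    """RT person-fit statistic (sum of squared standardized errors).

    Chi-square with one degree of freedom per observed cell; missing cells
    are dropped and reduce the degrees of freedom.
    """
    from .measurement import PersonParameters, expected_log_rt, rt_error_sd

    rt = np.asarray(rt_row, dtype=float).reshape(-1)
    w = ~np.isnan(rt)
    if not w.any():
        warnings.warn("person has no observed RTs; RT person fit undefined")
        return np.nan, np.nan
    mu = np.atleast_1d(expected_log_rt(PersonParameters(theta=0.0, zeta=zeta), items, par))
    sd = rt_error_sd(items, par)
    stat = float(np.sum(((rt[w] - mu[w]) / np.broadcast_to(sd, mu.shape)[w]) ** 2))
    return stat, float(chi2.sf(stat, int(w.sum())))


def joint_person_flag(ra_flags, rt_flags) -> float:
    """Posterior probability that both patterns are extreme.

    ``ra_flags`` and ``rt_flags`` are per-draw 0/1 indicator streams; the
    joint indicator is their product, averaged over draws.
    """
    ra = np.asarray(ra_flags, dtype=float)
    rt = np.asarray(rt_flags, dtype=float)
    if ra.shape != rt.shape:
        raise ValueError("indicator streams must have equal length")
    return float(np.mean(ra * rt))


def item_fit_ra(y_col, p_col):
    """RA item-fit statistic over an item's column at one draw."""
    y = np.asarray(y_col, dtype=float).reshape(-1)
    w = ~np.isnan(y)
    l, ls = _ra_stat(np.where(w, y, 0.0), np.asarray(p_col), w.astype(float), axis=0)
    return float(l), float(ls), float(ndtr(-ls)) if np.isfinite(ls) else np.nan


def item_fit_rt(rt_col, mu_col, sigma2):
    """RT item-fit statistic over an item's column at one draw."""
    rt = np.asarray(rt_col, dtype=float).reshape(-1)
    w = ~np.isnan(rt)
    stat = float(np.sum((rt[w] - np.asarray(mu_col)[w]) ** 2) / sigma2)
    return stat, float(chi2.sf(stat, int(w.sum())))


def latent_residual(y, theta, item, c_resid: float = 2.0):
    """Rao-Blackwellized latent RA residual and its outlier probability.

    The latent propensity is normal with unit SD around ``a*theta - b`` and
    truncated by the observed response; the conditional mean of the residual
    and the two-sided probability that it exceeds ``c_resid`` in magnitude
    follow from the truncated normal distribution.
    """
    eta = np.asarray(item.a, dtype=float) * theta - np.asarray(item.b, dtype=float)
    return _latent_residual_core(np.asarray(y, dtype=float), eta, c_resid)


def _latent_residual_core(y, eta, c):
    phi_eta = norm.pdf(eta)
    upper = ndtr(eta)  # P(correct)
    lower = ndtr(-eta)
    e_mean = np.where(y == 1.0, phi_eta / np.maximum(upper, _PCLIP),
                      -phi_eta / np.maximum(lower, _PCLIP))
    phi_mc = ndtr(-c)
    # two-sided tail of the truncated standard normal residual
    p1 = (np.minimum(phi_mc, upper) + np.maximum(0.0, phi_mc - lower)) / np.maximum(upper, _PCLIP)
    p0 = (np.minimum(phi_mc, lower) + np.maximum(0.0, lower - ndtr(c))) / np.maximum(lower, _PCLIP)
    prob = np.clip(np.where(y == 1.0, p1, p0), 0.0, 1.0)
    return e_mean, prob


def rt_residual(rt, zeta, item, c_resid: float = 2.0):
    """Observed-minus-expected log-RT residual and its outlier probability.

    The probability is ``Phi(-C - e/s) + 1 - Phi(C - e/s)`` with ``e`` the
    residual and ``s`` the residual SD — the two-sided normal tail of a new
    error at least as extreme as the threshold given the observed residual.
    """
    lam = np.asarray(item.lam, dtype=float)
    phi = np.asarray(item.phi, dtype=float)
    sd = np.sqrt(np.asarray(item.sigma2, dtype=float))
    eps = np.asarray(rt, dtype=float) - (lam - phi * zeta)
    z = eps / sd
    prob = ndtr(-c_resid - z) + 1.0 - ndtr(c_resid - z)
    return eps, prob


def ks_test_rt_residuals(residuals, sigma):
    """Kolmogorov-Smirnov test of standardized RT residuals against N(0,1).

    Returns the supremum distance D and its significance probability from
    the Kolmogorov distribution.  Fewer than 10 residuals triggers a
    warning; constant residuals are degenerate and return ``(nan, nan)``.
    """
    res = np.asarray(residuals, dtype=float)
    res = res[~np.isnan(res)]
    if res.size < 10:
        warnings.warn("fewer than 10 residuals; KS test is unreliable")
    if res.size == 0 or np.ptp(res) == 0:
        warnings.warn("degenerate (constant) residuals; KS test undefined")
        return np.nan, np.nan
    stat = kstest(res / sigma, "norm")
    return float(stat.statistic), float(stat.pvalue)


# ----------------------------------------------------------- vectorized core
def _ks_columns(x: np.ndarray, mask: np.ndarray):
    """Column-wise KS distance and asymptotic p against N(0,1).

    ``x`` standardized values, ``mask`` valid cells; columns with fewer than
    2 valid values return NaN.
    """
    n_col = mask.sum(axis=0)
    xx = np.where(mask, x, np.inf)
    xs = np.sort(xx, axis=0)
    f = ndtr(xs)
    idx = np.arange(1, x.shape[0] + 1, dtype=float)[:, None]
    nn = np.maximum(n_col, 1).astype(float)
    valid = idx <= n_col
    d_plus = np.where(valid, idx / nn - f, -np.inf).max(axis=0)
    d_minus = np.where(valid, f - (idx - 1.0) / nn, -np.inf).max(axis=0)
    d = np.maximum(d_plus, d_minus)
    p = kolmogorov(np.sqrt(nn) * d)
    bad = n_col < 2
    return np.where(bad, np.nan, d), np.where(bad, np.nan, p)


@dataclass
class FitReport:
    """Posterior fit summaries (persons, items, cells).

    Person-level: ``pfl`` (mean standardized RA statistic), ``pflp`` and
    ``lzp`` (posterior significance probabilities, RA and RT), ``lzpt``
    (mean RT statistic), ``lzpa`` (latent-residual RA test; no power),
    ``eapcp1``/``eapcp2``/``eapcp3`` (posterior probabilities that the RT,
    RA, and joint patterns are extreme).  Item-level: ``ifl``, ``iflp``,
    ``lzi``, ``eap_ks``, ``eap_ks_ra``.  Cell-level: ``eap_resid`` (RT),
    ``eap_resid_ra`` (latent RA), ``eap_l0`` (log-likelihood contribution).
    """

    pfl: np.ndarray
    pflp: np.ndarray
    lzp: np.ndarray
    lzpt: np.ndarray
    lzpa: np.ndarray
    eapcp1: np.ndarray
    eapcp2: np.ndarray
    eapcp3: np.ndarray
    ifl: np.ndarray
    iflp: np.ndarray
    lzi: np.ndarray
    eap_ks: np.ndarray
    eap_ks_ra: np.ndarray
    eap_resid: np.ndarray
    eap_resid_ra: np.ndarray
    eap_l0: np.ndarray
    n_draws: int
    config: FitConfig = field(default_factory=FitConfig)

    def person_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "PFl": self.pfl,
                "PFlp": self.pflp,
                "lZP": self.lzp,
                "lZPT": self.lzpt,
                "lZPA": self.lzpa,
                "EAPCP1": self.eapcp1,
                "EAPCP2": self.eapcp2,
                "EAPCP3": self.eapcp3,
            }
        )

    def item_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "IFl": self.ifl,
                "IFlp": self.iflp,
                "lZI": self.lzi,
                "EAPKS": self.eap_ks,
                "EAPKSA": self.eap_ks_ra,
            }
        )

    def extreme_rt_fraction(self) -> float:
        """Fraction of RT cells extreme with high posterior probability."""
        v = self.eap_resid[~np.isnan(self.eap_resid)]
        return float(np.mean(v >= self.config.flag_probability)) if v.size else np.nan

    def extreme_ra_fraction(self) -> float:
        v = self.eap_resid_ra[~np.isnan(self.eap_resid_ra)]
        return float(np.mean(v >= self.config.flag_probability)) if v.size else np.nan


class ResidualAccumulator:
    """Accumulates per-draw fit statistics during the Gibbs run."""

    def __init__(self, state, fit_config: FitConfig) -> None:
        self.cfg = fit_config
        self.n, self.k = state.n, state.k
        self.obs_y = state.obs_y
        self.obs_rt = state.obs_rt
        self.df_rt_person = self.obs_rt.sum(axis=1)
        self.df_rt_item = self.obs_rt.sum(axis=0)
        alpha = fit_config.alpha
        with np.errstate(invalid="ignore"):
            self.crit_rt_person = chi2.ppf(1 - alpha, np.maximum(self.df_rt_person, 1))
            self.crit_rt_item = chi2.ppf(1 - alpha, np.maximum(self.df_rt_item, 1))
        self.c_ra = fit_config.c_ra
        self.n_draws = 0
        z = np.zeros
        self.sums = {
            "pfl": z(self.n), "pflp": z(self.n), "lzp": z(self.n), "lzpt": z(self.n),
            "lzpa": z(self.n), "flag_rt": z(self.n), "flag_ra": z(self.n),
            "flag_joint": z(self.n),
            "ifl": z(self.k), "iflp": z(self.k), "lzi": z(self.k),
            "ks": z(self.k), "ks_ra": z(self.k),
            "resid": z((self.n, self.k)), "resid_ra": z((self.n, self.k)),
            "l0": z((self.n, self.k)),
        }
        self.counts_ra_cell = z((self.n, self.k))

    def update(self, state) -> None:
        cfg = self.cfg
        eta = state.eta()
        p2 = ndtr(eta)
        wz = (self.obs_y & (state.s_know == 1)).astype(float)
        y = np.where(self.obs_y, state.data.y, 0.0)

        # RA person fit
        l_p, ls_p = _ra_stat(y, p2, wz, axis=1)
        pval_ra = ndtr(-ls_p)
        flag_ra = (ls_p > self.c_ra).astype(float)
        # RT person fit
        mu_rt = state.rt_mean()
        w_rt = self.obs_rt.astype(float)
        z2 = np.where(self.obs_rt, (state.data.log_rt - mu_rt), 0.0) ** 2 / state.sigma2
        stat_rt = (w_rt * z2).sum(axis=1)
        pval_rt = chi2.sf(stat_rt, np.maximum(self.df_rt_person, 1))
        flag_rt = (stat_rt > self.crit_rt_person).astype(float)

        s = self.sums
        s["pfl"] += np.nan_to_num(ls_p)
        s["pflp"] += np.nan_to_num(pval_ra)
        s["lzpt"] += stat_rt
        s["lzp"] += pval_rt
        s["flag_ra"] += flag_ra
        s["flag_rt"] += flag_rt
        s["flag_joint"] += flag_ra * flag_rt

        # item fit (transposed)
        _, ls_i = _ra_stat(y, p2, wz, axis=0)
        s["ifl"] += np.nan_to_num(ls_i)
        s["iflp"] += np.nan_to_num(ndtr(-ls_i))
        stat_it = (w_rt * z2).sum(axis=0)
        s["lzi"] += chi2.sf(stat_it, np.maximum(self.df_rt_item, 1))

        # cell-level residuals
        e_mean, p_out = _latent_residual_core(y, eta, cfg.c_resid)
        s["resid_ra"] += wz * p_out
        self.counts_ra_cell += wz
        p_clip = np.clip(p2, _PCLIP, 1 - _PCLIP)
        s["l0"] += wz * (y * np.log(p_clip) + (1 - y) * np.log(1 - p_clip))

        sd = np.sqrt(state.sigma2)
        z_rt = np.where(self.obs_rt, (state.data.log_rt - mu_rt) / sd, 0.0)
        s["resid"] += w_rt * (ndtr(-cfg.c_resid - z_rt) + 1.0 - ndtr(cfg.c_resid - z_rt))

        # latent-residual RA person test (documented as powerless)
        stat_a = (wz * e_mean**2).sum(axis=1)
        s["lzpa"] += chi2.sf(stat_a, np.maximum(wz.sum(axis=1), 1))

        # KS tests per item
        _, p_ks = _ks_columns(z_rt, self.obs_rt)
        s["ks"] += np.nan_to_num(p_ks < cfg.alpha)
        e_std = e_mean / np.maximum(np.sqrt(np.clip(1 + eta * e_mean - e_mean**2, 1e-6, None)), 1e-3)
        _, p_ksa = _ks_columns(e_std, wz.astype(bool))
        s["ks_ra"] += np.nan_to_num(p_ksa < cfg.alpha)
        self.n_draws += 1

    def finalize(self) -> FitReport:
        if self.n_draws == 0:
            raise RuntimeError("no draws accumulated; increase n_iter beyond n_resid_start")
        d = self.n_draws
        s = self.sums
        with np.errstate(invalid="ignore", divide="ignore"):
            resid = np.where(self.obs_rt, s["resid"] / d, np.nan)
            resid_ra = np.where(self.counts_ra_cell > 0, s["resid_ra"] / np.maximum(self.counts_ra_cell, 1), np.nan)
            l0 = np.where(self.counts_ra_cell > 0, s["l0"] / np.maximum(self.counts_ra_cell, 1), np.nan)
        return FitReport(
            pfl=s["pfl"] / d,
            pflp=s["pflp"] / d,
            lzp=s["lzp"] / d,
            lzpt=s["lzpt"] / d,
            lzpa=s["lzpa"] / d,
            eapcp1=s["flag_rt"] / d,
            eapcp2=s["flag_ra"] / d,
            eapcp3=s["flag_joint"] / d,
            ifl=s["ifl"] / d,
            iflp=s["iflp"] / d,
            lzi=s["lzi"] / d,
            eap_ks=s["ks"] / d,
            eap_ks_ra=s["ks_ra"] / d,
            eap_resid=resid,
            eap_resid_ra=resid_ra,
            eap_l0=l0,
            n_draws=d,
            config=self.cfg,
        )
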