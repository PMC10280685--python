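"""Posterior summaries and single-chain MCMC diagnostics.

Summaries are EAP (posterior mean) and posterior SD per parameter, computed
after discarding the burn-in (default 10% of the run).  Chain diagnostics
are implemented internally: effective sample size via the
initial-positive-sequence truncation of the autocorrelation function, the
Monte Carlo standard error ``MCSE = SD / sqrt(ESS)`` (so an ESS of 400 puts
the MCSE at 5% of the posterior SD), the naive SE, and a Geweke-style
single-chain mean-difference statistic.  Multi-chain diagnostics are left to
repeated runs with different seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SummaryTable", "ChainDiagnostics", "summarize", "ess_and_mcse", "effective_sample_size"]


@dataclass
class SummaryTable:
    """EAP/SD tables for items, persons, and the population parameters."""

    items: pd.DataFrame
    persons: pd.DataFrame
    population: dict
    n_retained: int
    convention: str = "eta = a*theta - b; E[log RT] = lambda - phi*zeta"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"Joint RA/RT model summary ({self.n_retained} retained draws)",
            f"convention: {self.convention}",
            "",
            "--- Item parameter estimates (EAP / SD) ---",
            self.items.round(3).to_string(),
            "",
            "--- Population parameters ---",
        ]
        for key, val in self.population.items():
            lines.append(f"{key}:")
            lines.append(np.array_str(np.asarray(val), precision=3))
        return "\n".join(lines)


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    return cov / np.outer(sd, sd)


def summarize(draws, burnin_percent: float | None = None) -> SummaryTable:
    """Summarize posterior draws after discarding the burn-in.

    ``burnin_percent`` overrides the percentage stored in the run
    configuration.  Difficulties are reported on the bracketed (ability)
    scale when the run was configured that way.
    """
    cfg = draws.config
    pct = cfg.burnin if burnin_percent is None else burnin_percent
    if not 0 <= pct < 100:
        raise ValueError("burn-in percentage must lie in [0, 100)")
    n_iter = draws.a.shape[0]
    lo = int(np.floor(n_iter * pct / 100.0))
    if lo >= n_iter:
        raise ValueError("burn-in discards every draw")

    def eap_sd(arr):
        r = arr[lo:]
        return r.mean(axis=0), r.std(axis=0, ddof=1)

    item_cols = {}
    b_chain = draws.b
    convention = "eta = a*theta - b; E[log RT] = lambda - phi*zeta"
    if getattr(cfg, "par1", False):
        b_chain = draws.b / draws.a
        convention = "eta = a*(theta - b); E[log RT] = lambda - phi*zeta"
    if getattr(cfg, "wl", False):
        convention += " (phi = reciprocal residual SD)"
    pieces = [("a", draws.a), ("b", b_chain), ("phi", draws.phi),
              ("lam", draws.lam), ("sigma2", draws.sigma2)]
    if hasattr(draws, "c") and np.any(draws.c != 0):
        pieces.insert(2, ("c", draws.c))
    for name, arr in pieces:
        m, s = eap_sd(arr)
        item_cols[f"{name}_eap"] = m
        item_cols[f"{name}_sd"] = s
    items = pd.DataFrame(item_cols)
    items.index.name = "item"

    person_cols = {}
    if draws.theta.size:
        m, s = eap_sd(draws.theta)
        person_cols["theta_eap"], person_cols["theta_sd"] = m, s
        z = draws.zeta
        if z.ndim == 3:  # growth model: components stacked
            for j in range(z.shape[2]):
                m, s = eap_sd(z[:, :, j])
                person_cols[f"zeta{j}_eap"], person_cols[f"zeta{j}_sd"] = m, s
        else:
            m, s = eap_sd(z)
            person_cols["zeta_eap"], person_cols["zeta_sd"] = m, s
    persons = pd.DataFrame(person_cols)
    persons.index.name = "person"

    population = {}
    if hasattr(draws, "mu_i"):
        mu_i, mu_i_sd = eap_sd(draws.mu_i)
        population["mu_I (mu_a, mu_b, mu_phi, mu_lam)"] = mu_i
        population["mu_I SD"] = mu_i_sd
        sig_i = draws.sigma_i[lo:].mean(axis=0)
        population["Sigma_I"] = sig_i
        with np.errstate(invalid="ignore"):
            population["Corr_I"] = _cov_to_corr(np.nan_to_num(sig_i, nan=np.nan))
    if hasattr(draws, "mu_p"):
        mu_p, _ = eap_sd(draws.mu_p)
        population["mu_P (mu_theta, mu_zeta)"] = mu_p
        sig_p = draws.sigma_p[lo:].mean(axis=0)
        population["Sigma_P"] = sig_p
        population["Corr_P"] = _cov_to_corr(sig_p)
    if hasattr(draws, "person_cov"):
        pc = draws.person_cov[lo:].mean(axis=0)
        population["Sigma_(theta,zeta0..)"] = pc
        population["Corr_(theta,zeta0..)"] = _cov_to_corr(pc)
        population["mu_theta"] = draws.mu_theta[lo:].mean()
    return SummaryTable(
        items=items, persons=persons, population=population,
        n_retained=n_iter - lo, convention=convention,
    )


@dataclass
class ChainDiagnostics:
    """Single-chain diagnostics: ESS, MCSE, naive SE, Geweke z."""

    ess: float
    mcse: float
    naive_se: float
    geweke_z: float
    n: int
    sd: float


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    x = x - x.mean()
    f = np.fft.rfft(x, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    return acf / acf[0]


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS by Geyer's initial-positive-sequence truncation."""
    x = np.asarray(chain, dtype=float).reshape(-1)
    n = x.shape[0]
    if n < 4 or x.std() == 0:
        return np.nan
    rho = _autocorrelation(x)
    pair_sums = rho[: 2 * (n // 2)].reshape(-1, 2).sum(axis=1)
    neg = np.nonzero(pair_sums <= 0)[0]
    stop = neg[0] if neg.size else pair_sums.shape[0]
    tau = max(-1.0 + 2.0 * pair_sums[:stop].sum(), 1e-8)
    return float(min(n / tau, n))


def ess_and_mcse(chain: np.ndarray) -> ChainDiagnostics:
    """Diagnostics of one parameter chain (length >= 100 recommended).

    The MCSE is ``SD / sqrt(ESS)``; a constant chain has no defined ESS and
    is flagged by NaN (with a warning).
    """
    x = np.asarray(chain, dtype=float).reshape(-1)
    n = x.shape[0]
    if n < 100:
        warnings.warn("chain shorter than 100; diagnostics are unreliable")
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        warnings.warn("constant chain; ESS undefined")
        return ChainDiagnostics(np.nan, np.nan, 0.0, np.nan, n, 0.0)
    ess = effective_sample_size(x)
    mcse = sd / np.sqrt(ess)
    naive = sd / np.sqrt(n)
    # Geweke-style mean comparison: first 10% vs last 50%
    n1 = max(int(0.1 * n), 2)
    n2 = max(int(0.5 * n), 2)
    a, bseg = x[:n1], x[-n2:]
    var1 = a.var(ddof=1) / max(effective_sample_size(a), 1.0) if a.std() else 0.0
    var2 = bseg.var(ddof=1) / max(effective_sample_size(bseg), 1.0) if bseg.std() else 0.0
    denom = np.sqrt(var1 + var2)
    z = (a.mean() - bseg.mean()) / denom if denom > 0 else np.nan
    return ChainDiagnostics(ess, float(mcse), float(naive), float(z), n, sd)
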