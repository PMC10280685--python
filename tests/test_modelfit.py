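"""Fit diagnostics: person/item fit statistics against hand calculations and
independent oracles (truncated-normal moments, chi-square calibration,
Monte-Carlo checks of the residual tail probabilities)."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtr

import jointirt as j
from jointirt.modelfit import (
    _ks_columns,
    _latent_residual_core,
    item_fit_rt,
    joint_person_flag,
    ks_test_rt_residuals,
    latent_residual,
    person_fit_ra,
    person_fit_rt,
    ra_critical_value,
    rt_critical_value,
    rt_residual,
)

TN_MEAN_AT_ZERO = 0.7978845608  # phi(0)/Phi(0)


# --------------------------------------------------------------- RA person fit
def test_person_fit_ra_perfect_fit_is_zero():
    items = j.ItemParameters(a=np.ones(3), b=np.full(3, -40.0))  # p ~ 1
    stat, _, _ = person_fit_ra(np.ones(3), 0.0, items)
    assert stat == pytest.approx(0.0, abs=1e-6)


def test_person_fit_ra_hand_value():
    # two items with p = 0.5 and responses (1, 0): -2*ln(0.5) = 2 ln 2
    items = j.ItemParameters(a=np.ones(2), b=np.zeros(2))
    stat, ls, _ = person_fit_ra(np.array([1.0, 0.0]), 0.0, items)
    assert stat == pytest.approx(2 * np.log(2), abs=1e-9)
    assert np.isnan(ls)  # p=1/2 everywhere: zero standardization variance


def test_person_fit_ra_critical_value():
    assert ra_critical_value(0.05) == pytest.approx(1.645, abs=1e-3)


def test_person_fit_ra_guessed_cells_excluded():
    items = j.ItemParameters(a=np.ones(4), b=np.zeros(4), c=np.full(4, 0.2))
    y = np.array([1.0, 1.0, 0.0, 1.0])
    s = np.array([1, 0, 1, 1])  # second response was a guess
    stat_all, _, _ = person_fit_ra(y, 0.4, items)
    stat_wo, _, _ = person_fit_ra(y, 0.4, items, guess_indicators=s)
    items3 = j.ItemParameters(a=np.ones(3), b=np.zeros(3))
    stat_ref, _, _ = person_fit_ra(y[[0, 2, 3]], 0.4, items3)
    assert stat_wo == pytest.approx(stat_ref)
    assert stat_all != pytest.approx(stat_wo)


def test_person_fit_ra_no_items_warns():
    items = j.ItemParameters(a=np.ones(2), b=np.zeros(2))
    with pytest.warns(UserWarning):
        stat, _, _ = person_fit_ra(np.array([np.nan, np.nan]), 0.0, items)
    assert np.isnan(stat)


# --------------------------------------------------------------- RT person fit
def test_person_fit_rt_zero_residuals():
    items = j.ItemParameters(a=np.ones(3), b=np.zeros(3), phi=np.ones(3),
                             lam=np.full(3, 4.0), sigma2=np.ones(3))
    stat, p = person_fit_rt(np.full(3, 3.5), 0.5, items)
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_person_fit_rt_chi_square_reference():
    # with 170 observed cells the 5% critical value is 201.4
    assert rt_critical_value(170, 0.05) == pytest.approx(201.4, abs=0.05)
    assert stats.chi2.sf(rt_critical_value(170), 170) == pytest.approx(0.05)


def test_person_fit_rt_equals_bruteforce_loop():
    rng = np.random.default_rng(0)
    k = 7
    items = j.ItemParameters(
        a=np.ones(k), b=np.zeros(k), phi=rng.uniform(0.7, 1.3, k),
        lam=rng.normal(4, 0.3, k), sigma2=rng.uniform(0.1, 0.5, k),
    )
    rt = rng.normal(4, 1, k)
    rt[2] = np.nan
    zeta = 0.3
    stat, p = person_fit_rt(rt, zeta, items)
    acc = 0.0
    n = 0
    for kk in range(k):
        if np.isnan(rt[kk]):
            continue
        acc += (rt[kk] - (items.lam[kk] - items.phi[kk] * zeta)) ** 2 / items.sigma2[kk]
        n += 1
    assert stat == pytest.approx(acc, abs=1e-12)
    assert p == pytest.approx(stats.chi2.sf(acc, n))


def test_person_fit_rt_null_distribution():
    """Simulated null data: the statistic is chi-square with K df."""
    rng = np.random.default_rng(1)
    n, k = 2000, 20
    items = j.ItemParameters(a=np.ones(k), b=np.zeros(k),
                             phi=rng.uniform(0.8, 1.2, k),
                             lam=rng.normal(4, 0.3, k),
                             sigma2=rng.uniform(0.2, 0.4, k))
    zeta = rng.normal(0, 0.5, n)
    mu = items.lam - items.phi * zeta[:, None]
    rt = mu + rng.standard_normal((n, k)) * np.sqrt(items.sigma2)
    stats_ = ((rt - mu) ** 2 / items.sigma2).sum(axis=1)
    assert stats.kstest(stats_, "chi2", args=(k,)).pvalue > 0.01


# --------------------------------------------------------------- joint flag
def test_joint_person_flag():
    assert joint_person_flag(np.zeros(100), np.ones(100)) == 0.0
    assert joint_person_flag(np.ones(50), np.ones(50)) == 1.0
    rng = np.random.default_rng(2)
    ra = rng.random(200_000) < 0.5
    rt = rng.random(200_000) < 0.5
    assert joint_person_flag(ra, rt) == pytest.approx(0.25, abs=0.01)
    with pytest.raises(ValueError):
        joint_person_flag(np.ones(3), np.ones(4))


# --------------------------------------------------------------- latent residuals
def test_latent_residual_truncated_normal_mean():
    item = j.ItemParameters(a=1.0, b=0.0)
    e1, _ = latent_residual(1.0, 0.0, item)
    e0, _ = latent_residual(0.0, 0.0, item)
    assert e1 == pytest.approx(TN_MEAN_AT_ZERO, abs=1e-6)
    assert e0 == pytest.approx(-TN_MEAN_AT_ZERO, abs=1e-6)


def test_latent_residual_probability_bounds_and_monte_carlo(rng):
    # formula against direct simulation of the truncated latent residual
    for eta, y, c in [(0.0, 1.0, 2.0), (1.2, 0.0, 1.5), (-0.8, 1.0, 1.0), (0.5, 0.0, 2.5)]:
        _, prob = _latent_residual_core(np.array(y), np.array(eta), c)
        z = rng.standard_normal(2_000_000) + eta
        kept = z > 0 if y == 1.0 else z < 0
        e = z[kept] - eta
        mc = np.mean(np.abs(e) > c)
        assert 0.0 <= prob <= 1.0
        assert prob == pytest.approx(mc, abs=0.003)


def test_latent_residual_probability_always_valid():
    etas = np.linspace(-4, 4, 81)
    for c in (0.5, 1.0, 2.0, 3.0):
        for y in (0.0, 1.0):
            _, p = _latent_residual_core(np.full_like(etas, y), etas, c)
            assert np.all((p >= 0) & (p <= 1))


# --------------------------------------------------------------- RT residuals
def test_rt_residual_values():
    item = j.ItemParameters(a=1, b=0, phi=1.0, lam=4.0, sigma2=1.0)
    eps, p = rt_residual(4.0, 0.0, item, c_resid=0.0)
    assert eps == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    _, p196 = rt_residual(4.0, 0.0, item, c_resid=1.96)
    assert p196 == pytest.approx(2 * (1 - ndtr(1.96)), abs=1e-9)
    _, p_far = rt_residual(40.0, 0.0, item, c_resid=2.0)
    assert p_far == pytest.approx(1.0)


# --------------------------------------------------------------- KS test
def test_ks_detects_misspecification():
    rng = np.random.default_rng(3)
    rejections = 0
    for _ in range(20):
        uniform_resid = rng.uniform(0.0, 1.0, 200)  # grossly non-normal
        _, p = ks_test_rt_residuals(uniform_resid, 1.0)
        rejections += p < 0.05
    assert rejections == 20


def test_ks_null_calibration():
    rng = np.random.default_rng(4)
    pvals = [ks_test_rt_residuals(rng.standard_normal(150), 1.0)[1] for _ in range(300)]
    rate = np.mean(np.asarray(pvals) < 0.05)
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 300)


def test_ks_warnings():
    with pytest.warns(UserWarning):
        ks_test_rt_residuals(np.arange(5.0), 1.0)
    with pytest.warns(UserWarning):
        d, p = ks_test_rt_residuals(np.ones(20), 1.0)
    assert np.isnan(d) and np.isnan(p)


def test_vectorized_ks_matches_scipy():
    rng = np.random.default_rng(5)
    x = rng.standard_normal((300, 4))
    mask = rng.random((300, 4)) > 0.1
    d_vec, _ = _ks_columns(x, mask)
    for col in range(4):
        d_ref = stats.kstest(x[mask[:, col], col], "norm").statistic
        assert d_vec[col] == pytest.approx(d_ref, abs=1e-12)


# --------------------------------------------------------------- item fit
def test_item_fit_rt_uses_observed_rows_only():
    rng = np.random.default_rng(6)
    rt = rng.normal(4, 0.5, 50)
    rt[:10] = np.nan
    mu = np.full(50, 4.0)
    stat, p = item_fit_rt(rt, mu, 0.25)
    manual = np.nansum((rt - mu) ** 2) / 0.25
    assert stat == pytest.approx(manual)
    assert p == pytest.approx(stats.chi2.sf(manual, 40))


def test_item_fit_power_for_inflated_variance():
    """With the residual variances anchored at their true values, an item
    whose RT spread is doubled is flagged by the RT item-fit statistic, and
    heavy contamination of another item is caught by the KS check."""
    truth = j.simulate_joint_data(300, 10, seed=30)
    rt = truth.data.log_rt.copy()
    mu = truth.items.lam - truth.items.phi * truth.persons.zeta[:, None]
    rt[:, 0] = mu[:, 0] + (rt[:, 0] - mu[:, 0]) * 2.0  # double the SD of item 0
    rng = np.random.default_rng(31)
    bad = rng.random(300) < 0.15
    rt[bad, 1] += 2.5  # gross outliers -> non-normal residuals for item 1
    data = j.TestData(y=truth.data.y, log_rt=rt)
    cfg = j.MCMCConfig(n_iter=700, seed=13, residual=True, n_resid_start=200)
    draws = j.fit_joint_model(
        data, cfg, fixed=j.FixedParameters(sigma2=truth.items.sigma2)
    )
    rep = draws.fit_report
    assert rep.n_draws == 500
    # probabilities are probabilities
    for arr in (rep.lzp, rep.pflp, rep.eapcp1, rep.eapcp2, rep.eapcp3,
                rep.iflp, rep.lzi, rep.eap_ks):
        ok = arr[~np.isnan(arr)]
        assert np.all((ok >= 0) & (ok <= 1))
    # draw-wise conjunction can never exceed either marginal flag stream
    assert np.all(rep.eapcp3 <= rep.eapcp1 + 1e-12)
    assert np.all(rep.eapcp3 <= rep.eapcp2 + 1e-12)
    assert rep.lzi[0] < 0.01  # tiny significance probability = misfit
    assert rep.lzi[2:].mean() > 0.1
    assert rep.eap_ks[1] > 0.9
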