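"""Gibbs sampler contracts: augmentation truncation, identification
invariance, fixed parameters, missing-data handling, and agreement with a
brute-force numerical-integration oracle on a tiny instance."""

import numpy as np
import pytest
from scipy.special import ndtr

import jointirt as j
from jointirt._mcmc import truncnorm_negative, truncnorm_positive
from jointirt.sampler import GibbsState, apply_identification


def _ident_state(truth, ident=2, seed=0):
    cfg = j.MCMCConfig(n_iter=10, ident=ident, seed=seed)
    return GibbsState(truth.data, cfg, None, None, np.random.default_rng(seed))


# ----------------------------------------------------------- augmentation
def test_truncated_normal_sampler_moments(rng):
    # E[Z | Z > 0] at mean 0 is phi(0)/Phi(0) = 0.79788
    draws = truncnorm_positive(np.zeros(200_000), rng)
    assert draws.min() > 0
    assert draws.mean() == pytest.approx(0.7978845608, abs=0.01)
    # far-tail truncation stays finite and on the right side
    far = truncnorm_positive(np.full(1000, -30.0), rng)
    assert np.all(far > 0) and np.all(np.isfinite(far))
    neg = truncnorm_negative(np.full(1000, 25.0), rng)
    assert np.all(neg < 0) and np.all(np.isfinite(neg))


def test_augmentation_sign_contract(small_truth):
    state = _ident_state(small_truth)
    j.sampler.sample_augmented_responses(state)
    y = state.y
    assert np.all(state.z[y == 1.0] > 0)
    assert np.all(state.z[y == 0.0] < 0)


def test_no_guessing_limit(small_truth):
    state = _ident_state(small_truth)
    state.c = np.zeros(state.k)
    j.sampler.sample_augmented_responses(state)
    assert np.all(state.s_know == 1.0)


# ----------------------------------------------------------- identification
def test_identification_rescale_exact():
    a = np.array([2.0, 0.5])
    g = np.exp(np.mean(np.log(a)))
    assert np.prod(a / g) == pytest.approx(1.0, abs=1e-15)


@pytest.mark.parametrize("fit_name", ["small_fit_ident1", "small_fit_ident2"])
def test_identification_invariants_every_draw(fit_name, request):
    draws = request.getfixturevalue(fit_name)
    assert np.allclose(np.prod(draws.a, axis=1), 1.0, atol=1e-8)
    assert np.allclose(np.prod(draws.phi, axis=1), 1.0, atol=1e-8)
    if draws.config.ident == 1:
        assert np.allclose(draws.b.sum(axis=1), 0.0, atol=1e-8)
        assert np.allclose(draws.lam.sum(axis=1), 0.0, atol=1e-8)
    else:
        assert np.all(draws.mu_p == 0.0)


def test_identification_likelihood_invariant(small_truth):
    state = _ident_state(small_truth, ident=1)
    state.a = np.abs(np.random.default_rng(1).normal(1.2, 0.3, state.k)) + 0.2
    state.b = np.random.default_rng(2).normal(0.3, 1.0, state.k)
    p_before = ndtr(state.eta())
    mu_before = state.rt_mean()
    apply_identification(state)
    assert np.prod(state.a) == pytest.approx(1.0, abs=1e-12)
    assert state.b.sum() == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(ndtr(state.eta()), p_before, atol=1e-12)
    assert np.allclose(state.rt_mean(), mu_before, atol=1e-12)
    # idempotence
    snapshot = (state.a.copy(), state.b.copy(), state.theta.copy())
    apply_identification(state)
    assert np.allclose(state.a, snapshot[0], atol=1e-12)
    assert np.allclose(state.b, snapshot[1], atol=1e-12)


def test_invalid_state_rejected(small_truth):
    state = _ident_state(small_truth)
    state.a[0] = -1.0
    with pytest.raises(ValueError):
        apply_identification(state)


# ----------------------------------------------------------- fixed parameters
def test_fixed_item_parameters_never_updated(small_truth):
    fx = j.FixedParameters(alpha=small_truth.items.a)
    cfg = j.MCMCConfig(n_iter=80, seed=1)
    draws = j.fit_joint_model(small_truth.data, cfg, fixed=fx)
    assert np.all(draws.a == small_truth.items.a)
    assert draws.b.std(axis=0).max() > 0  # others still move


def test_td_false_fixes_time_discrimination(small_truth):
    cfg = j.MCMCConfig(n_iter=60, seed=2, td=False)
    draws = j.fit_joint_model(small_truth.data, cfg)
    assert np.all(draws.phi == 1.0)


def test_wl_reports_reciprocal_error_sd(small_truth):
    cfg = j.MCMCConfig(n_iter=60, seed=3, wl=True)
    draws = j.fit_joint_model(small_truth.data, cfg)
    assert np.allclose(draws.phi, 1.0 / np.sqrt(draws.sigma2))


# ----------------------------------------------------------- missing data
def test_all_missing_row_rejected():
    truth = j.simulate_joint_data(20, 6, seed=20)
    y = truth.data.y.copy()
    rt = truth.data.log_rt.copy()
    y[3] = np.nan
    rt[3] = np.nan
    with pytest.raises(ValueError, match="missing by design"):
        j.fit_joint_model(j.TestData(y=y, log_rt=rt), j.MCMCConfig(n_iter=10))


def test_mbd_covered_row_draws_from_prior():
    truth = j.simulate_joint_data(30, 6, seed=21)
    mbd = np.zeros((30, 6), dtype=bool)
    mbd[0] = True  # person 0 never administered anything
    data = j.TestData(
        y=np.where(mbd, np.nan, truth.data.y),
        log_rt=np.where(mbd, np.nan, truth.data.log_rt),
        mbd_y=mbd,
        mbd_rt=mbd,
    )
    sigma_p = np.array([[1.0, 0.2], [0.2, 0.25]])
    cfg = j.MCMCConfig(n_iter=1500, seed=4, fixed_sigma_p=sigma_p)
    draws = j.fit_joint_model(data, cfg, fixed=j.FixedParameters(
        alpha=truth.items.a, beta=truth.items.b, phi=truth.items.phi,
        lam=truth.items.lam, sigma2=truth.items.sigma2,
    ))
    th = draws.theta[200:, 0]
    ze = draws.zeta[200:, 0]
    # prior draws: mean 0, variances as in Sigma_P
    assert abs(th.mean()) < 4 / np.sqrt(len(th) / 10)
    assert th.var() == pytest.approx(1.0, rel=0.2)
    assert ze.var() == pytest.approx(0.25, rel=0.2)


def test_imputation_predictive_mean(small_truth):
    state = _ident_state(small_truth)
    state.mar_rt = np.zeros_like(state.mar_rt)
    state.mar_rt[0, 0] = True
    vals = []
    for _ in range(4000):
        j.sampler.impute_missing(state)
        vals.append(state.rt[0, 0])
    expected = state.lam[0] - state.phi[0] * state.zeta[0]
    se = np.sqrt(state.sigma2[0] / 4000)
    assert np.mean(vals) == pytest.approx(expected, abs=5 * se)


def test_no_missing_identical_with_and_without_imputation(small_truth):
    cfg = j.MCMCConfig(n_iter=50, seed=5)
    d1 = j.fit_joint_model(small_truth.data, cfg)
    d2 = j.fit_joint_model(small_truth.data, j.MCMCConfig(n_iter=50, seed=5))
    assert np.array_equal(d1.b, d2.b)
    assert np.array_equal(d1.theta, d2.theta)


def test_mar_cells_handled(small_truth):
    data = j.apply_missing_design(small_truth.data, mar_rate=0.1, seed=6)
    cfg = j.MCMCConfig(n_iter=120, seed=7)
    draws = j.fit_joint_model(data, cfg)
    assert np.isfinite(draws.b).all()
    assert np.isfinite(draws.lam).all()


# ----------------------------------------------------------- small-instance oracle
def _grid_posterior_means(y_row, rt_row, items, sigma_p, grid=None):
    """2-D numerical integration of the per-person posterior."""
    if grid is None:
        grid = np.linspace(-6, 6, 241)
    th, ze = np.meshgrid(grid, grid, indexing="ij")
    log_post = -0.5 * np.einsum(
        "ijk,kl,ijl->ij",
        np.stack([th, ze], axis=2),
        np.linalg.inv(sigma_p),
        np.stack([th, ze], axis=2),
    )
    for k in range(len(items.a)):
        p = ndtr(items.a[k] * th - items.b[k])
        p = np.clip(p, 1e-300, 1 - 1e-16)
        log_post += np.where(y_row[k] == 1.0, np.log(p), np.log1p(-p))
        mu = items.lam[k] - items.phi[k] * ze
        log_post += -0.5 * (rt_row[k] - mu) ** 2 / items.sigma2[k]
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    return float((w * th).sum()), float((w * ze).sum())


def test_small_instance_matches_grid_oracle():
    items = j.ItemParameters(
        a=np.array([0.8, 1.2, 1.0]),
        b=np.array([-0.5, 0.3, 0.0]),
        phi=np.array([1.1, 0.9, 1.0]),
        lam=np.array([4.0, 3.8, 4.2]),
        sigma2=np.array([0.3, 0.25, 0.2]),
    )
    sigma_p = np.array([[1.0, 0.25], [0.25, 0.49]])
    y = np.array([[1, 0, 1], [0, 0, 1], [1, 1, 1], [0, 1, 0]], dtype=float)
    rt = np.array(
        [[3.9, 3.6, 4.4], [4.5, 4.2, 4.8], [3.2, 3.1, 3.6], [4.0, 3.9, 4.1]]
    )
    data = j.TestData(y=y, log_rt=rt)
    cfg = j.MCMCConfig(n_iter=20000, burnin=10, seed=11, fixed_sigma_p=sigma_p)
    fx = j.FixedParameters(alpha=items.a, beta=items.b, phi=items.phi,
                           lam=items.lam, sigma2=items.sigma2)
    draws = j.fit_joint_model(data, cfg, fixed=fx)
    for i in range(4):
        th_or, ze_or = _grid_posterior_means(y[i], rt[i], items, sigma_p)
        assert draws.eap("theta")[i] == pytest.approx(th_or, abs=0.02)
        assert draws.eap("zeta")[i] == pytest.approx(ze_or, abs=0.02)


# ----------------------------------------------------------- misc contracts
def test_location_equivariance(small_truth):
    shift = 0.7
    rt2 = small_truth.data.log_rt.copy()
    rt2[:, 4] += shift
    d1 = j.fit_joint_model(small_truth.data, j.MCMCConfig(n_iter=600, seed=8))
    d2 = j.fit_joint_model(
        j.TestData(y=small_truth.data.y, log_rt=rt2), j.MCMCConfig(n_iter=600, seed=8)
    )
    diff = d2.eap("lam") - d1.eap("lam")
    assert diff[4] == pytest.approx(shift, abs=0.05)
    others = np.delete(diff, 4)
    assert np.all(np.abs(others) < 0.05)


def test_degenerate_column_warns_but_runs(caplog):
    truth = j.simulate_joint_data(40, 6, seed=22)
    y = truth.data.y.copy()
    y[:, 2] = 1.0  # everyone correct
    with caplog.at_level("WARNING"):
        draws = j.fit_joint_model(
            j.TestData(y=y, log_rt=truth.data.log_rt), j.MCMCConfig(n_iter=80, seed=9)
        )
    assert np.isfinite(draws.b).all()


def test_guessing_model_runs_and_recovers_scale():
    truth = j.simulate_joint_data(400, 15, seed=23, guessing=True)
    cfg = j.MCMCConfig(n_iter=600, seed=10, guess=True)
    draws = j.fit_joint_model(truth.data, cfg)
    c_eap = draws.eap("c")
    assert np.all((c_eap > 0.02) & (c_eap < 0.5))
    assert np.corrcoef(draws.eap("lam"), truth.items.lam)[0, 1] > 0.95


def test_person_predictors_recover_group_effect():
    rng = np.random.default_rng(24)
    n, k = 400, 12
    group = np.repeat([0.0, 1.0], n // 2)
    spec = j.PopulationSpec()
    persons = j.draw_persons(n, spec, seed=25)
    persons.theta += 0.6 * group  # ability gap between the groups
    items = j.draw_items(k, spec, seed=26)
    truth = j.generate_dataset(persons, items, seed=27)
    x = (group - group.mean())[:, None]  # effect coding
    draws = j.fit_joint_model(
        truth.data,
        j.MCMCConfig(n_iter=800, seed=12),
        predictors=j.Predictors(xpa=x),
    )
    beta = draws.beta_theta[200:, 0].mean()
    assert beta == pytest.approx(0.6, abs=0.25)
    _ = rng


def test_par1_reports_same_scale_difficulty(small_truth):
    from jointirt import diagnostics

    draws = j.fit_joint_model(small_truth.data, j.MCMCConfig(n_iter=120, seed=14, par1=True))
    table = diagnostics.summarize(draws)
    assert "a*(theta - b)" in table.convention
    lo = draws.n_burnin
    assert np.allclose(table.items["b_eap"], (draws.b / draws.a)[lo:].mean(0))
    # chains themselves stay on the non-bracketed scale (never mixed)
    assert np.allclose(draws.difficulty_same_scale(), draws.b / draws.a)


def test_item_predictors_run(small_truth):
    xia = np.linspace(-1, 1, small_truth.data.n_items)[:, None]
    draws = j.fit_joint_model(
        small_truth.data,
        j.MCMCConfig(n_iter=150, seed=15),
        predictors=j.Predictors(xia=xia, xit=xia),
    )
    assert np.isfinite(draws.b).all() and np.isfinite(draws.lam).all()
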