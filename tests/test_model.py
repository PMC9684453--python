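import numpy as np
import pytest
from scipy import stats

from phenoescape import (
    MCMCConfig,
    PhenologyModel,
    PriorSpec,
    RecordSet,
    SyntheticConfig,
    simulate_records,
)
from tests.conftest import SMALL_MCMC


def _model(sim_data, priors=None):
    rs, _ = sim_data
    return PhenologyModel.from_records(rs, priors=priors)


# --------------------------------------------------------------------- #
# log-posterior
# --------------------------------------------------------------------- #
def _oracle_log_posterior(y, X, coef, tau, priors):
    """Independent density oracle: scipy normal log-pdfs, term by term."""
    if not priors.tau_lower < tau <= priors.tau_upper:
        return -np.inf
    sigma = 1.0 / np.sqrt(tau)
    loglik = stats.norm.logpdf(y, loc=X @ coef, scale=sigma).sum()
    prior_sd = 1.0 / np.sqrt(priors.beta_precision)
    logprior = stats.norm.logpdf(coef, loc=priors.beta_mean, scale=prior_sd).sum()
    # uniform prior on tau contributes a constant; the model omits it too
    return loglik + logprior


def test_log_posterior_matches_scipy_oracle(sim_data):
    model = _model(sim_data)
    rng = np.random.default_rng(4)
    for _ in range(5):
        coef = rng.normal(0, 10, size=model.p)
        tau = rng.uniform(0.01, 1.0)
        ours = model.log_posterior(coef, tau)
        oracle = _oracle_log_posterior(model.y, model.X, coef, tau, model.priors)
        # both drop the same additive constant (the uniform tau prior)
        assert ours == pytest.approx(oracle, rel=1e-12)


def test_log_posterior_maximal_at_observed_doy():
    """With a single record, the likelihood peaks where mu equals the DOY."""
    y = np.array([120.0])
    X = np.array([[1.0]])
    model = PhenologyModel(y, X, ["beta0"], [], priors=PriorSpec())
    at_mode = model.log_posterior(np.array([120.0]), tau=0.1)
    for off in (-5.0, 5.0, 30.0):
        assert model.log_posterior(np.array([120.0 + off]), tau=0.1) < at_mode


def test_log_posterior_sigma_scaling_closed_form(sim_data):
    """Halving the precision at fixed residuals changes the log density by
    exactly n/2 * log(1/2) + (tau/2) * SSE/2 (Gaussian closed form)."""
    model = _model(sim_data)
    coef = np.zeros(model.p)
    tau = 0.04
    sse = model._sse(coef)
    delta = model.log_posterior(coef, tau) - model.log_posterior(coef, tau / 2)
    expected = 0.5 * model.n * np.log(2.0) - 0.5 * (tau / 2.0) * sse
    assert delta == pytest.approx(expected, rel=1e-10)


def test_tau_outside_uniform_support_is_rejected(sim_data):
    model = _model(sim_data)
    assert model.log_posterior(np.zeros(model.p), 150.0) == -np.inf
    assert model.log_posterior(np.zeros(model.p), -1.0) == -np.inf
    assert np.isfinite(model.log_posterior(np.zeros(model.p), 99.9))


# --------------------------------------------------------------------- #
# Gibbs sampler correctness
# --------------------------------------------------------------------- #
def test_fixed_tau_draws_match_conjugate_posterior():
    """At fixed residual precision the coefficient conditional is exactly
    multivariate normal; sample moments must match the closed form."""
    cfg = SyntheticConfig(n_species=4, n_per_species=100, seed=17)
    rs, man = simulate_records(cfg)
    model = PhenologyModel.from_records(rs)
    tau = 1.0 / cfg.sigma**2
    m, V = model.conjugate_coef_posterior(tau)
    n_draws = 4000
    res = model.fit(
        MCMCConfig(n_chains=1, n_iter=n_draws, n_burnin=0, thin=1, seed=2),
        fix_tau=tau,
    )
    draws = res.samples.coef.reshape(n_draws, model.p)
    se = np.sqrt(np.diag(V) / n_draws)
    assert np.all(np.abs(draws.mean(axis=0) - m) < 4 * se)


def test_prior_only_moments():
    """With no data the sampler reproduces the priors: coefficients
    N(0, 1000) and precision Uniform(0, 100)."""
    model = PhenologyModel(
        np.empty(0), np.empty((0, 2)), ["beta0", "beta1"], [], priors=PriorSpec()
    )
    res = model.fit(MCMCConfig(n_chains=1, n_iter=4000, n_burnin=0, thin=1, seed=8))
    coef = res.samples.coef.reshape(-1, 2)
    prior_sd = np.sqrt(1000.0)
    assert abs(coef.mean()) < 4 * prior_sd / np.sqrt(coef.size)
    assert coef.std() == pytest.approx(prior_sd, rel=0.05)
    tau = 1.0 / res.samples.sigma2.reshape(-1)
    assert tau.mean() == pytest.approx(50.0, abs=2.0)
    assert tau.min() > 0 and tau.max() <= 100.0


def test_species_without_records_keeps_its_prior():
    cfg = SyntheticConfig(n_species=3, n_per_species=60, seed=23)
    rs, _ = simulate_records(cfg)
    idx = dict(rs.species_index)
    idx["zz_ghost_species"] = len(idx) + 1
    rs_aug = RecordSet(rs.records, idx)
    model = PhenologyModel.from_records(rs_aug)
    res = model.fit(MCMCConfig(n_chains=1, n_iter=3000, n_burnin=0, thin=1, seed=5))
    ghost = res.samples.flat("alpha[zz_ghost_species]")
    assert abs(ghost.mean()) < 4 * np.sqrt(1000.0 / ghost.size)
    assert ghost.std() == pytest.approx(np.sqrt(1000.0), rel=0.1)


def test_seeded_runs_exactly_reproducible(sim_data):
    model = _model(sim_data)
    cfg = MCMCConfig(n_chains=2, n_iter=400, n_burnin=100, thin=2, seed=99)
    r1 = model.fit(cfg)
    r2 = model.fit(cfg)
    assert np.array_equal(r1.samples.coef, r2.samples.coef)
    assert np.array_equal(r1.samples.sigma2, r2.samples.sigma2)


def test_sigma2_draws_respect_uniform_precision_support(sim_data):
    model = _model(sim_data)
    res = model.fit(SMALL_MCMC)
    tau = 1.0 / res.samples.sigma2
    assert (tau > 0).all() and (tau <= 100.0).all()
    assert res.samples.coef.shape == (2, 500, model.p)  # (iter-burnin)/thin


def test_beta1_invariant_to_temperature_shift(sim_data):
    """Adding a constant to every temperature must leave the sensitivity
    posterior unchanged up to Monte-Carlo error."""
    rs, _ = sim_data
    df = rs.to_dataframe()
    df_shift = df.assign(spring_temp_c=df.spring_temp_c + 10.0)
    a = PhenologyModel.from_dataframe(df).fit(SMALL_MCMC)
    b = PhenologyModel.from_dataframe(df_shift).fit(SMALL_MCMC)
    sa = a.summarize()["beta1"]
    sb = b.summarize()["beta1"]
    mc_se = 3 * (sa.sd / np.sqrt(sa.ess) + sb.sd / np.sqrt(sb.ess))
    assert abs(sa.mean - sb.mean) < max(mc_se, 0.02)


def test_community_intercept_stable_under_species_relabelling(sim_data):
    """Only beta0 + mean(alpha) is identified; permuting species labels must
    not move the reported community intercept beyond Monte-Carlo error."""
    rs, _ = sim_data
    df = rs.to_dataframe()
    mapping = {sp: f"perm_{k:02d}_{sp}" for k, sp in
               enumerate(reversed(sorted(df.species.unique())))}
    df_perm = df.assign(species=df.species.map(mapping))
    a = PhenologyModel.from_dataframe(df).fit(SMALL_MCMC)
    b = PhenologyModel.from_dataframe(df_perm).fit(SMALL_MCMC)
    ca = a.samples.flat("community_intercept")
    cb = b.samples.flat("community_intercept")
    se = 3 * (ca.std() + cb.std()) / np.sqrt(min(ca.size, cb.size))
    assert abs(ca.mean() - cb.mean()) < max(se, 0.15)


def test_invalid_inputs_rejected(sim_data):
    rs, _ = sim_data
    with pytest.raises(ValueError, match="empty"):
        PhenologyModel.from_records(RecordSet([]))
    with pytest.raises(ValueError):
        MCMCConfig(n_iter=100, n_burnin=100)
    with pytest.raises(ValueError):
        PriorSpec(beta_precision=0.0)
    with pytest.raises(ValueError):
        PriorSpec(tau_upper=0.0)
    df = rs.to_dataframe().assign(spring_temp_c=5.0)
    with pytest.raises(ValueError, match="distinct"):
        PhenologyModel.from_dataframe(df)


def test_rank_deficient_design_warns_but_proceeds():
    cfg = SyntheticConfig(n_species=5, n_per_species=1, seed=31)
    rs, _ = simulate_records(cfg)
    # 5 records, 5 species + intercept + 2 slopes: fewer records than params
    idx = dict(rs.species_index)
    for k in range(6):
        idx[f"extra_{k}"] = len(idx) + 1
    rs_aug = RecordSet(rs.records, idx)
    with pytest.warns(UserWarning, match="fewer records than species"):
        model = PhenologyModel.from_records(rs_aug)
    res = model.fit(MCMCConfig(n_chains=1, n_iter=200, n_burnin=100, thin=1, seed=1))
    assert np.isfinite(res.samples.coef).all()
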