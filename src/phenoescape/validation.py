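"""Sampler-validation studies: conjugate-oracle equivalence, replicate
parameter recovery, and window-screen identifiability.

These routines quantify whether the Gibbs sampler and the screening
diagnostic behave as designed under the generative conditions the
synthetic module encodes.  They are ordinary package functionality (used
by the command-line report and the test suite alike), not test helpers:
each returns a plain dict of measured quantities.
"""

from __future__ import annotations

import numpy as np

from .model import MCMCConfig, PhenologyModel
from .simulate import SyntheticConfig, simulate_monthly, simulate_records
from .windows import MARCH_APRIL, screen_windows


def conjugate_check(
    n_records: int = 500,
    n_draws: int = 10_000,
    seed: int = 0,
) -> dict:
    """Compare fixed-precision Gibbs draws against the closed-form
    coefficient posterior.

    With the residual precision held at its true value the coefficient
    conditional is exactly N(m, V); every Gibbs iteration is then an
    independent draw from it.  Reports the largest z-score of the sample
    mean against m (SE = sqrt(V_jj / N)) and of the sample covariance
    against V (SE from the Gaussian fourth-moment formula).
    """
    n_species = 5
    cfg = SyntheticConfig(
        n_species=n_species,
        n_per_species=n_records // n_species,
        seed=seed,
    )
    rs, _ = simulate_records(cfg)
    model = PhenologyModel.from_records(rs)
    tau = 1.0 / cfg.sigma**2
    m, V = model.conjugate_coef_posterior(tau)
    res = model.fit(
        MCMCConfig(n_chains=1, n_iter=n_draws, n_burnin=0, thin=1, seed=seed + 1),
        fix_tau=tau,
    )
    draws = res.samples.coef.reshape(n_draws, model.p)
    se_mean = np.sqrt(np.diag(V) / n_draws)
    z_mean = np.abs(draws.mean(axis=0) - m) / se_mean
    S = np.cov(draws, rowvar=False)
    vj = np.diag(V)
    se_cov = np.sqrt((np.outer(vj, vj) + V**2) / n_draws)
    z_cov = np.abs(S - V) / se_cov
    return {
        "n_records": n_records,
        "n_draws": n_draws,
        "max_z_mean": float(z_mean.max()),
        "max_z_cov": float(z_cov.max()),
    }


def recovery_study(
    n_replicates: int = 100,
    beta1_true: float = -3.5,
    sigma: float = 5.0,
    n_species: int = 6,
    n_per_species: int = 200,
    mcmc: MCMCConfig | None = None,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Replicate simulation-and-refit study for the temperature sensitivity.

    Each replicate simulates a fresh dataset (default 1200 records) at the
    given true sensitivity, refits the model, and records the posterior
    mean and equal-tailed credible interval of beta1.  Reports the mean
    absolute error of the posterior mean (days per °C) and how many of the
    intervals cover the truth.
    """
    mcmc = mcmc or MCMCConfig(n_chains=2, n_iter=1200, n_burnin=400, thin=1)
    subseeds = np.random.SeedSequence(seed).generate_state(
        2 * n_replicates, dtype=np.uint32
    )
    a = (1.0 - level) / 2.0
    abs_err = []
    covered = 0
    for k in range(n_replicates):
        cfg = SyntheticConfig(
            n_species=n_species,
            n_per_species=n_per_species,
            beta1=beta1_true,
            sigma=sigma,
            seed=int(subseeds[2 * k]) % (2**31),
        )
        rs, _ = simulate_records(cfg)
        model = PhenologyModel.from_records(rs)
        from dataclasses import replace

        res = model.fit(replace(mcmc, seed=int(subseeds[2 * k + 1]) % (2**31)))
        b1 = res.samples.flat("beta1")
        post_mean = float(b1.mean())
        lo, hi = np.quantile(b1, [a, 1.0 - a])
        abs_err.append(abs(post_mean - beta1_true))
        if lo <= beta1_true <= hi:
            covered += 1
    return {
        "n_replicates": n_replicates,
        "n_records": n_species * n_per_species,
        "beta1_true": beta1_true,
        "mean_abs_bias": float(np.mean(abs_err)),
        "coverage_count": covered,
        "coverage_fraction": covered / n_replicates,
    }


def window_screen_study(
    n_replicates: int = 20,
    n_records: int = 2000,
    seed: int = 0,
) -> dict:
    """How often the March–April window wins the |r| screen when the data
    are generated from March–April forcing."""
    n_species = 5
    subseeds = np.random.SeedSequence(seed).generate_state(
        n_replicates, dtype=np.uint32
    )
    wins = 0
    for k in range(n_replicates):
        cfg = SyntheticConfig(
            n_species=n_species,
            n_per_species=n_records // n_species,
            seed=int(subseeds[k]) % (2**31),
        )
        rs, _ = simulate_records(cfg)
        monthly = simulate_monthly(cfg, rs)
        best = screen_windows(rs, monthly).best_window(cfg.stratum, cfg.continent)
        if best == MARCH_APRIL:
            wins += 1
    return {
        "n_replicates": n_replicates,
        "n_records": n_records,
        "march_april_wins": wins,
    }
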