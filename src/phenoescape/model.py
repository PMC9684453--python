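"""Hierarchical Bayesian phenology model and its Gibbs sampler.

The event day-of-year (DOY) of specimen ``i`` of species ``j`` is modelled
with a normal likelihood

    doy_{i,j} ~ N(mu_{i,j}, sigma^2)
    mu_{i,j}  = beta0 + beta1 * SpringT_i + beta2 * Elevation_i + alpha_j

with vague independent normal priors on every coefficient
(mean 0, precision 1e-3, i.e. variance 1000 — the precision
parameterisation conventional in BUGS/JAGS-style engines) and a uniform
prior on the residual precision, 1/sigma^2 ~ Uniform(0, 100).

One model is fitted per forest stratum × continent.  The sampler is a
two-block Gibbs scheme exploiting full conjugacy:

* coefficients | precision — one joint multivariate-normal draw from
  N(A^{-1} tau X'y, A^{-1}) with A = tau X'X + 1e-3 I (Cholesky solve);
* precision | coefficients — Gamma(n/2 + 1, rate SSE/2) truncated to
  (0, 100), drawn by inverse-CDF.

Only beta0 + alpha_j is likelihood-identified (the intercept and species
offsets are confounded under independent vague priors); downstream
reporting therefore carries the "community intercept"
beta0 + mean_j(alpha_j), which is stable across species relabelling.
Centering is applied at reporting time only, never to the chain state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammainc, gammaincinv

from .records import RecordSet

#: canonical covariate name → records-table column
COVARIATE_COLUMNS = {
    "spring_temp": "spring_temp_c",
    "elevation": "elev_m",
    "winter_temp": "winter_temp_c",
    "annual_precip": "annual_precip_mm",
    "spring_precip": "spring_precip_mm",
}

DEFAULT_COVARIATES = ("spring_temp", "elevation")

RHAT_WARN = 1.1


@dataclass(frozen=True)
class PriorSpec:
    """Priors: N(0, 1/beta_precision) on every coefficient and
    Uniform(tau_lower, tau_upper) on the residual precision tau = 1/sigma^2."""

    beta_mean: float = 0.0
    beta_precision: float = 1e-3
    tau_lower: float = 0.0
    tau_upper: float = 100.0

    def __post_init__(self) -> None:
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be > 0")
        if not self.tau_upper > self.tau_lower >= 0:
            raise ValueError("need tau_upper > tau_lower >= 0")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings.  Defaults: 3 chains of 20 000 iterations with 10 000
    burn-in, thinned by 10 (3 000 retained draws)."""

    n_chains: int = 3
    n_iter: int = 20_000
    n_burnin: int = 10_000
    thin: int = 10
    seed: int = 0
    init_strategy: str = "least_squares_jitter"  # or "prior_draw"

    def __post_init__(self) -> None:
        if not self.n_iter > self.n_burnin >= 0:
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.init_strategy not in ("least_squares_jitter", "prior_draw"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus convergence diagnostics.

    ``coef`` has shape (n_chains, n_draws, p); column order is the model's
    ``param_names`` (intercept, covariate slopes, species offsets).
    ``sigma2`` has shape (n_chains, n_draws).
    """

    coef: np.ndarray
    sigma2: np.ndarray
    param_names: list[str]
    species: list[str]
    config: MCMCConfig
    priors: PriorSpec

    def __post_init__(self) -> None:
        if (self.sigma2 <= 0).any():
            raise ValueError("sigma^2 draws must be positive")

    @property
    def n_draws(self) -> int:
        return self.coef.shape[0] * self.coef.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All draws of one parameter, chains concatenated."""
        if name == "sigma2":
            return self.sigma2.reshape(-1)
        if name == "community_intercept":
            return self.flat("beta0") + self.alpha_draws().mean(axis=1)
        j = self.param_names.index(name)
        return self.coef[:, :, j].reshape(-1)

    def alpha_draws(self) -> np.ndarray:
        """Species-offset draws, shape (total draws, J), chains concatenated."""
        idx = [self.param_names.index(f"alpha[{sp}]") for sp in self.species]
        return self.coef[:, :, idx].reshape(-1, len(idx))

    def to_arviz(self):
        import arviz as az

        post = {
            name: self.coef[:, :, j]
            for j, name in enumerate(self.param_names)
        }
        post["sigma2"] = self.sigma2
        return az.from_dict(posterior=post)

    def diagnostics(self) -> pd.DataFrame:
        """Split R-hat and bulk effective sample size per parameter."""
        import arviz as az

        idata = self.to_arviz()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        names = self.param_names + ["sigma2"]
        return pd.DataFrame(
            {
                "parameter": names,
                "rhat": [float(rhat[n].values) for n in names],
                "ess": [float(ess[n].values) for n in names],
            }
        )

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long-format draws: chain, iter, parameter, value."""
        n_chains, n_draws, p = self.coef.shape
        frames = []
        chain = np.repeat(np.arange(n_chains), n_draws)
        it = np.tile(np.arange(n_draws), n_chains)
        for j, name in enumerate(self.param_names):
            frames.append(
                pd.DataFrame(
                    {"chain": chain, "iter": it, "parameter": name,
                     "value": self.coef[:, :, j].reshape(-1)}
                )
            )
        frames.append(
            pd.DataFrame(
                {"chain": chain, "iter": it, "parameter": "sigma2",
                 "value": self.sigma2.reshape(-1)}
            )
        )
        return pd.concat(frames, ignore_index=True)


class PhenologyModel:
    """Hierarchical Bayesian linear phenology model for one
    stratum × continent group of specimen records.

    Parameters
    ----------
    doy:
        Observed event day-of-year, length n.
    design:
        Design matrix (n × p): intercept column, covariate columns, then
        one indicator column per species.
    param_names, species:
        Column labels; species offsets are named ``alpha[<species>]``.
    priors:
        Prior hyperparameters (vague normals + uniform precision).

    Use :meth:`from_records` / :meth:`from_dataframe` to construct from a
    specimen table; :meth:`fit` runs the Gibbs sampler and returns a
    :class:`~phenoescape.results.PhenologyResults`.
    """

    def __init__(
        self,
        doy: np.ndarray,
        design: np.ndarray,
        param_names: list[str],
        species: list[str],
        priors: PriorSpec | None = None,
        label: str = "",
    ) -> None:
        self.y = np.asarray(doy, dtype=float)
        self.X = np.asarray(design, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("design and response lengths differ")
        if self.X.shape[1] != len(param_names):
            raise ValueError("param_names does not match design columns")
        self.param_names = list(param_names)
        self.species = list(species)
        self.priors = priors or PriorSpec()
        self.label = label
        self.n, self.p = self.X.shape
        # sufficient statistics reused by every Gibbs iteration
        self._XtX = self.X.T @ self.X
        self._Xty = self.X.T @ self.y
        self._yty = float(self.y @ self.y)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_records(
        cls,
        records: RecordSet,
        priors: PriorSpec | None = None,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    ) -> "PhenologyModel":
        """Build the model for a single-group record set.

        Records must all share one stratum × continent (fits are run
        separately per group).  Requires at least two distinct spring
        temperatures when spring_temp is a covariate.
        """
        if len(records) == 0:
            raise ValueError("empty record set")
        groups = records.groups()
        if len(groups) > 1:
            raise ValueError(
                f"records span multiple stratum×continent groups: {groups}; "
                "fit each group separately (see fit_all_groups)"
            )
        df = records.to_dataframe()
        return cls.from_dataframe(
            df, priors=priors, covariates=covariates,
            species_order=records.species,
            label=f"{groups[0][0]}:{groups[0][1]}",
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        priors: PriorSpec | None = None,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        species_order: list[str] | None = None,
        label: str = "",
    ) -> "PhenologyModel":
        for cov in covariates:
            col = COVARIATE_COLUMNS.get(cov, cov)
            if col not in df.columns:
                raise ValueError(f"covariate {cov!r}: column {col!r} missing")
        if "spring_temp" in covariates:
            if df["spring_temp_c"].nunique() < 2:
                raise ValueError("need >= 2 distinct spring temperatures")
        species = species_order or sorted(df["species"].unique())
        j_index = {sp: j for j, sp in enumerate(species)}
        n = len(df)
        cols = [np.ones(n)]
        names = ["beta0"]
        std_slope = {"spring_temp": "beta1", "elevation": "beta2"}
        for cov in covariates:
            cols.append(df[COVARIATE_COLUMNS.get(cov, cov)].to_numpy(dtype=float))
            names.append(std_slope[cov] if cov in std_slope else f"beta[{cov}]")
        Z = np.zeros((n, len(species)))
        sp_codes = df["species"].map(j_index).to_numpy()
        Z[np.arange(n), sp_codes] = 1.0
        cols.append(Z)
        names.extend(f"alpha[{sp}]" for sp in species)
        X = np.column_stack(cols)
        if n < len(species):
            warnings.warn(
                "fewer records than species: design is prior-regularised",
                stacklevel=2,
            )
        return cls(df["doy"].to_numpy(dtype=float), X, names, species,
                   priors=priors, label=label)

    # ------------------------------------------------------------------ #
    def log_posterior(self, coef: np.ndarray, tau: float) -> float:
        """Unnormalised log posterior density at (coefficients, precision).

        Gaussian log-likelihood plus normal log-priors on the coefficients;
        tau outside the uniform prior support yields -inf.
        """
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (self.p,):
            raise ValueError(f"expected {self.p} coefficients")
        pr = self.priors
        if not pr.tau_lower < tau <= pr.tau_upper:
            return -np.inf
        sse = self._sse(coef)
        loglik = 0.5 * self.n * np.log(tau / (2.0 * np.pi)) - 0.5 * tau * sse
        logprior = 0.5 * self.p * np.log(pr.beta_precision / (2.0 * np.pi)) \
            - 0.5 * pr.beta_precision * np.sum((coef - pr.beta_mean) ** 2)
        return float(loglik + logprior)

    def _sse(self, coef: np.ndarray) -> float:
        return float(
            self._yty - 2.0 * coef @ self._Xty + coef @ self._XtX @ coef
        )

    def conjugate_coef_posterior(self, tau: float) -> tuple[np.ndarray, np.ndarray]:
        """Closed-form coefficient posterior N(m, V) at fixed precision tau:
        V = (tau X'X + k I)^{-1}, m = V tau X'y, with k the prior precision."""
        A = tau * self._XtX + self.priors.beta_precision * np.eye(self.p)
        V = np.linalg.inv(A)
        m = V @ (tau * self._Xty)
        return m, V

    # ------------------------------------------------------------------ #
    def fit(
        self,
        mcmc: MCMCConfig | None = None,
        fix_tau: float | None = None,
    ):
        """Run the Gibbs sampler; returns a PhenologyResults.

        ``fix_tau`` holds the residual precision fixed (no tau updates),
        in which case each coefficient draw is an exact independent draw
        from the conditional posterior — used for sampler validation.
        """
        from .results import PhenologyResults

        mcmc = mcmc or MCMCConfig()
        pr = self.priors
        n_keep = mcmc.n_draws_per_chain
        coef_out = np.empty((mcmc.n_chains, n_keep, self.p))
        sig_out = np.empty((mcmc.n_chains, n_keep))
        ss = np.random.SeedSequence(mcmc.seed)
        prior_prec_eye = pr.beta_precision * np.eye(self.p)

        for c, child in enumerate(ss.spawn(mcmc.n_chains)):
            rng = np.random.default_rng(child)
            tau = fix_tau if fix_tau is not None else self._init_tau(rng)
            coef = self._init_coef(rng, mcmc.init_strategy)
            k = 0
            for it in range(mcmc.n_iter):
                A = tau * self._XtX + prior_prec_eye
                L = np.linalg.cholesky(A)
                # mean solve + correlated noise in one pass
                m = np.linalg.solve(L.T, np.linalg.solve(L, tau * self._Xty))
                z = rng.standard_normal(self.p)
                coef = m + np.linalg.solve(L.T, z)
                if fix_tau is None:
                    tau = self._draw_tau(rng, self._sse(coef))
                if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                    coef_out[c, k] = coef
                    sig_out[c, k] = 1.0 / tau
                    k += 1
        samples = PosteriorSamples(
            coef=coef_out, sigma2=sig_out,
            param_names=self.param_names, species=self.species,
            config=mcmc, priors=pr,
        )
        return PhenologyResults(self, samples)

    def _init_tau(self, rng: np.random.Generator) -> float:
        lo, hi = self.priors.tau_lower, self.priors.tau_upper
        if self.n == 0:
            return float(0.5 * (lo + hi))
        resid_var = max(np.var(self.y), 1e-6)
        tau = 1.0 / resid_var
        return float(np.clip(tau, lo + 1e-9, hi))

    def _init_coef(self, rng: np.random.Generator, strategy: str) -> np.ndarray:
        if strategy == "prior_draw":
            sd = 1.0 / np.sqrt(self.priors.beta_precision)
            return rng.normal(self.priors.beta_mean, sd, size=self.p)
        A = self._XtX + self.priors.beta_precision * np.eye(self.p)
        theta = np.linalg.solve(A, self._Xty)
        scale = max(np.std(self.y), 1.0) if self.n else 1.0
        return theta + rng.normal(0.0, 0.1 * scale, size=self.p)

    def _draw_tau(self, rng: np.random.Generator, sse: float) -> float:
        """Inverse-CDF draw from Gamma(n/2 + 1, rate sse/2) truncated to the
        uniform prior's support (tau_lower, tau_upper)."""
        shape = 0.5 * self.n + 1.0
        rate = 0.5 * sse
        lo, hi = self.priors.tau_lower, self.priors.tau_upper
        if rate * hi < 1e-12 and self.n == 0:
            # no data: conditional reduces to the uniform prior itself
            return float(rng.uniform(max(lo, 1e-12), hi))
        rate = max(rate, 1e-300)
        c_lo = gammainc(shape, rate * lo)
        c_hi = gammainc(shape, rate * hi)
        u = rng.uniform(c_lo, c_hi)
        # guard the extreme tails of the incomplete-gamma inverse
        u = min(max(u, 1e-15), 1.0 - 1e-15)
        tau = float(gammaincinv(shape, u) / rate)
        return float(np.clip(tau, lo + 1e-12, hi))


def fit_all_groups(
    records: RecordSet,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> dict[tuple[str, str], "object"]:
    """One fit per stratum × continent present in ``records``.

    Per-group seeds are fanned out deterministically from the config seed.
    Returns {(stratum, continent): PhenologyResults}.
    """
    from dataclasses import replace

    mcmc = mcmc or MCMCConfig()
    out = {}
    groups = records.groups()
    subseeds = np.random.SeedSequence(mcmc.seed).generate_state(
        len(groups), dtype=np.uint32
    )
    for (stratum, continent), sub in zip(groups, subseeds):
        rs = records.subset(stratum=stratum, continent=continent)
        model = PhenologyModel.from_records(rs, priors=priors, covariates=covariates)
        res = model.fit(replace(mcmc, seed=int(sub) % (2**31)))
        out[(stratum, continent)] = res
    return out
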