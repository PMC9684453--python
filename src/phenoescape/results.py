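"""Posterior summaries, credible-interval comparisons, fit metrics, and
driver-combination model comparison.

Inference follows a single rule throughout: two parameters are declared
*different* if and only if their 95% equal-tailed Bayesian credible
intervals are disjoint (touching endpoints count as overlap).  No p-values
or multiplicity corrections are involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    COVARIATE_COLUMNS,
    MCMCConfig,
    PhenologyModel,
    PosteriorSamples,
    PriorSpec,
    RHAT_WARN,
)
from .records import RecordSet


@dataclass(frozen=True)
class ParameterSummary:
    """Posterior mean/median/sd and an equal-tailed credible interval."""

    name: str
    mean: float
    median: float
    sd: float
    lower: float
    upper: float
    level: float = 0.95
    rhat: float = float("nan")
    ess: float = float("nan")

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError(f"{self.name}: lower {self.lower} > upper {self.upper}")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    def excludes_zero(self) -> bool:
        """True if the credible interval does not overlap zero."""
        return self.upper < 0.0 or self.lower > 0.0


@dataclass(frozen=True)
class ComparisonResult:
    """Verdict of the interval-overlap rule for a pair of parameters."""

    a: ParameterSummary
    b: ParameterSummary
    verdict: str  # "different" | "not_different"

    @property
    def different(self) -> bool:
        return self.verdict == "different"


def summarize_draws(
    draws: np.ndarray,
    name: str,
    level: float = 0.95,
    rhat: float = float("nan"),
    ess: float = float("nan"),
) -> ParameterSummary:
    """Equal-tailed quantile summary of a 1-D array of posterior draws."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no draws")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a])
    return ParameterSummary(
        name=name,
        mean=float(draws.mean()),
        median=float(np.median(draws)),
        sd=float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
        lower=float(lo),
        upper=float(hi),
        level=level,
        rhat=rhat,
        ess=ess,
    )


def compare_intervals(a: ParameterSummary, b: ParameterSummary) -> ComparisonResult:
    """Different iff the credible intervals are disjoint; symmetric in its
    arguments; touching endpoints count as overlap (not different)."""
    if abs(a.level - b.level) > 1e-12:
        raise ValueError(f"mismatched interval levels: {a.level} vs {b.level}")
    disjoint = a.upper < b.lower or b.upper < a.lower
    return ComparisonResult(a, b, "different" if disjoint else "not_different")


class PhenologyResults:
    """Posterior of one fitted stratum × continent phenology model.

    Wraps the retained draws with summaries (`summarize`, `summary`),
    posterior-mean prediction (`predict`, `predictive_r2`), and the
    deviance information criterion (`dic`).  The reported "community
    intercept" is beta0 + mean_j(alpha_j), the likelihood-identified
    combination of the confounded intercept and species offsets.
    """

    def __init__(self, model: PhenologyModel, samples: PosteriorSamples) -> None:
        self.model = model
        self.samples = samples
        self._diag: pd.DataFrame | None = None

    # ------------------------------------------------------------------ #
    @property
    def param_names(self) -> list[str]:
        return self.samples.param_names + ["sigma2"]

    @property
    def params(self) -> pd.Series:
        """Posterior means, indexed by parameter name."""
        return pd.Series(
            {n: float(self.samples.flat(n).mean()) for n in self.param_names}
        )

    @property
    def community_intercept(self) -> float:
        """Posterior mean of beta0 + mean_j alpha_j."""
        return float(self.samples.flat("community_intercept").mean())

    def diagnostics(self) -> pd.DataFrame:
        if self._diag is None:
            self._diag = self.samples.diagnostics()
            bad = self._diag[self._diag.rhat > RHAT_WARN]
            if len(bad):
                warnings.warn(
                    f"{self.model.label or 'fit'}: R-hat > {RHAT_WARN} for "
                    f"{list(bad.parameter)}",
                    stacklevel=2,
                )
        return self._diag

    def summarize(self, level: float = 0.95) -> dict[str, ParameterSummary]:
        """Per-parameter posterior summaries at the given credible level,
        including the derived community intercept."""
        diag = self.diagnostics().set_index("parameter")
        out = {}
        for name in self.param_names:
            r = diag.loc[name] if name in diag.index else None
            out[name] = summarize_draws(
                self.samples.flat(name), name, level=level,
                rhat=float(r.rhat) if r is not None else float("nan"),
                ess=float(r.ess) if r is not None else float("nan"),
            )
        out["community_intercept"] = summarize_draws(
            self.samples.flat("community_intercept"), "community_intercept",
            level=level,
        )
        return out

    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        rows = [
            {
                "parameter": s.name, "mean": s.mean, "median": s.median,
                "sd": s.sd, "lower": s.lower, "upper": s.upper,
                "rhat": s.rhat, "ess": s.ess,
            }
            for s in self.summarize(level).values()
        ]
        return pd.DataFrame(rows)

    def summary(self, level: float = 0.95) -> str:
        """Plain-text summary table."""
        df = self.summary_frame(level)
        lines = [
            f"Phenology model fit [{self.model.label or 'unlabelled'}]",
            f"n = {self.model.n} records, {len(self.model.species)} species, "
            f"{self.samples.n_draws} retained draws",
            "",
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:10.4f}",
            ),
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------ #
    def predict(self, design: np.ndarray | None = None) -> np.ndarray:
        """Posterior-mean linear prediction (training design by default)."""
        X = self.model.X if design is None else np.asarray(design, dtype=float)
        theta = np.array(
            [self.params[n] for n in self.samples.param_names]
        )
        return X @ theta

    def predictive_r2(self) -> float:
        """Squared Pearson correlation of posterior-mean predictions vs
        observed DOY (NaN, with a warning, if either side is constant)."""
        fitted = self.predict()
        y = self.model.y
        if np.std(fitted) == 0 or np.std(y) == 0:
            warnings.warn("predictive r^2 undefined: zero variance", stacklevel=2)
            return float("nan")
        return float(np.corrcoef(fitted, y)[0, 1] ** 2)

    def r2_sse(self) -> float:
        """Alternative 1 − SSE/SST definition (reported alongside)."""
        fitted = self.predict()
        y = self.model.y
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            warnings.warn("r^2 undefined: zero variance", stacklevel=2)
            return float("nan")
        return 1.0 - float(np.sum((y - fitted) ** 2)) / sst

    def dic(self) -> tuple[float, float]:
        """Deviance information criterion and effective parameter count.

        DIC = Dbar + pD with pD = Dbar − D(posterior means); deviance is
        −2 × Gaussian log-likelihood.
        """
        coef = self.samples.coef.reshape(-1, self.model.p)
        sig2 = self.samples.sigma2.reshape(-1)
        m = self.model
        sse = (
            m._yty
            - 2.0 * coef @ m._Xty
            + np.einsum("ij,jk,ik->i", coef, m._XtX, coef)
        )
        dev = m.n * np.log(2.0 * np.pi * sig2) + sse / sig2
        dbar = float(dev.mean())
        theta_bar = coef.mean(axis=0)
        sig2_bar = float(sig2.mean())
        dhat = m.n * np.log(2.0 * np.pi * sig2_bar) + m._sse(theta_bar) / sig2_bar
        p_d = dbar - float(dhat)
        return dbar + p_d, p_d

    # ------------------------------------------------------------------ #
    def save_draws_csv(self, path) -> None:
        self.samples.to_long_dataframe().to_csv(path, index=False)

    def to_summary_json(self, level: float = 0.95) -> dict:
        return {
            "label": self.model.label,
            "n": self.model.n,
            "level": level,
            "parameters": {
                s.name: {
                    "mean": s.mean, "median": s.median, "sd": s.sd,
                    "lower": s.lower, "upper": s.upper,
                    "rhat": s.rhat, "ess": s.ess,
                }
                for s in self.summarize(level).values()
            },
        }


def model_compare(
    records: RecordSet,
    candidate_sets: list[tuple[str, ...]],
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> pd.DataFrame:
    """Fit one model per candidate covariate set and rank by DIC.

    Candidates draw from {spring_temp, winter_temp, annual_precip,
    spring_precip, elevation}; a candidate naming a column absent from the
    records table raises.  Predictive r² is reported alongside DIC; the
    table is sorted by DIC (smaller is better).
    """
    mcmc = mcmc or MCMCConfig()
    df = records.to_dataframe()
    rows = []
    subseeds = np.random.SeedSequence(mcmc.seed).generate_state(
        len(candidate_sets), dtype=np.uint32
    )
    from dataclasses import replace

    for cand, sub in zip(candidate_sets, subseeds):
        for cov in cand:
            if cov not in COVARIATE_COLUMNS:
                raise ValueError(f"unknown covariate {cov!r}")
            if COVARIATE_COLUMNS[cov] not in df.columns:
                raise ValueError(f"covariate {cov!r}: column missing from records")
        model = PhenologyModel.from_dataframe(
            df, priors=priors, covariates=tuple(cand),
            label="+".join(cand) or "intercept-only",
        )
        res = model.fit(replace(mcmc, seed=int(sub) % (2**31)))
        dic, p_d = res.dic()
        rows.append(
            {
                "candidate": "+".join(cand) or "(intercept only)",
                "dic": dic,
                "p_d": p_d,
                "predictive_r2": res.predictive_r2(),
            }
        )
    return (
        pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    )


def forest_plot(
    summaries: dict[str, ParameterSummary],
    path=None,
    title: str = "Spring temperature sensitivity",
):
    """Forest plot of posterior means and credible intervals (one row per
    labelled group), in the style of a cross-continent sensitivity figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.6 * len(summaries) + 1.5))
    labels = list(summaries)
    for i, lab in enumerate(labels):
        s = summaries[lab]
        ax.errorbar(
            s.mean, i,
            xerr=[[s.mean - s.lower], [s.upper - s.mean]],
            fmt="o", capsize=3, color="tab:blue",
        )
    ax.axvline(0.0, ls="--", color="grey", lw=1)
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels)
    ax.set_xlabel("days per °C")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
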