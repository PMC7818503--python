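"""Binomial-normal hierarchical model for sparse-event meta-analysis.

For trial i with arms j in {T, C} the model is

    r_ij ~ Binomial(pi_ij, n_ij)
    logit(pi_iT) = mu_i + 0.5 * delta_i
    logit(pi_iC) = mu_i - 0.5 * delta_i
    delta_i ~ N(delta, tau^2)

where ``delta`` is the overall treatment effect (log odds ratio), ``tau``
the between-study SD, and ``mu_i`` the trial-level baseline.  Priors:
``delta ~ N(0, 100)``, ``mu_i ~ N(mu0, 100)`` with a vague ``N(0, 1e6)``
hyperprior on the centring parameter ``mu0``, and one of the heterogeneity
priors from :mod:`sparsemeta.priors` on ``tau``.  Because the binomial
likelihood handles zero-event arms directly, no continuity correction is
ever applied.

Inference is by adaptive random-walk Metropolis-within-Gibbs
(:mod:`sparsemeta._engine`), with tau sampled on the prior's native scale
through an unconstrained reparameterisation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .data import MetaAnalysisDataset
from .priors import HeterogeneityPrior

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "ModelState",
    "PosteriorResult",
    "ConvergenceWarning",
    "log_joint",
    "fit",
    "summarize",
    "diagnostics",
    "beneficial_side_probability",
]

logger = logging.getLogger(__name__)


class ConvergenceWarning(UserWarning):
    """Emitted when split-Rhat or ESS indicates non-convergence."""


@dataclass(frozen=True)
class ModelSpec:
    """Priors of the hierarchical model.

    ``delta_prior_variance`` and ``mu_prior_variance`` default to 100
    (weakly diffuse on the logOR / logit scales); ``mu0_prior_variance``
    is the vague hyperprior variance on the baseline centring parameter.
    """

    heterogeneity_prior: HeterogeneityPrior
    delta_prior_variance: float = 100.0
    mu_prior_variance: float = 100.0
    mu0_prior_variance: float = 1.0e6

    def __post_init__(self) -> None:
        for name in ("delta_prior_variance", "mu_prior_variance", "mu0_prior_variance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings; defaults follow the simulation-grade settings of
    3 chains x 30 000 iterations, burn-in 4500, thinning 3."""

    chains: int = 3
    iterations: int = 30_000
    burn_in: int = 4_500
    thin: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    #: Long-run settings used for the packaged case studies.
    @classmethod
    def case_study(cls, seed: int = 0) -> "McmcConfig":
        return cls(chains=3, iterations=850_000, burn_in=150_000, thin=35, seed=seed)

    @classmethod
    def fast(cls, seed: int = 0) -> "McmcConfig":
        return cls(chains=3, iterations=30_000, burn_in=4_500, thin=3, seed=seed)


@dataclass
class ModelState:
    """One point in parameter space (tau via the unconstrained coordinate z)."""

    delta: float
    z: float
    mu0: float
    mu: np.ndarray
    d: np.ndarray


def log_joint(
    dataset: MetaAnalysisDataset,
    spec: ModelSpec,
    state: ModelState,
    include_likelihood: bool = True,
) -> float:
    """Unnormalised log posterior density at ``state``.

    The heterogeneity prior enters on its native scale g(tau) together
    with the Jacobian of the unconstrained reparameterisation, matching
    the target the sampler explores.  Binomial normalising constants are
    omitted.  A non-finite state evaluates to ``-inf``.
    """
    vals = np.concatenate(
        ([state.delta, state.z, state.mu0], state.mu, state.d)
    )
    if not np.all(np.isfinite(vals)):
        return -np.inf
    prior = spec.heterogeneity_prior
    code, params = prior.engine_code()
    tau, prior_lp = _engine._tau_and_logprior(code, params[0], params[1], state.z)
    tau = max(tau, 1e-12)

    lp = prior_lp
    lp += stats.norm.logpdf(state.delta, 0.0, np.sqrt(spec.delta_prior_variance))
    lp += stats.norm.logpdf(state.mu0, 0.0, np.sqrt(spec.mu0_prior_variance))
    lp += np.sum(
        stats.norm.logpdf(state.mu, state.mu0, np.sqrt(spec.mu_prior_variance))
    )
    lp += np.sum(stats.norm.logpdf(state.d, state.delta, tau))
    if include_likelihood:
        r_t, n_t, r_c, n_c = dataset.counts()
        eta_t = state.mu + 0.5 * state.d
        eta_c = state.mu - 0.5 * state.d
        lp += np.sum(
            r_t * (-np.logaddexp(0.0, -eta_t))
            + (n_t - r_t) * (-np.logaddexp(0.0, eta_t))
            + r_c * (-np.logaddexp(0.0, -eta_c))
            + (n_c - r_c) * (-np.logaddexp(0.0, eta_c))
        )
    return float(lp)


@dataclass
class PosteriorResult:
    """MCMC draws and metadata for one model fit.

    ``draws`` maps parameter names to arrays of shape ``(chains, n_draws)``
    for scalars (``delta``, ``tau``, ``mu0``) and ``(chains, n_draws, k)``
    for the per-trial ``mu`` and ``d`` (study-specific log odds ratios).
    """

    draws: dict[str, np.ndarray]
    labels: tuple[str, ...]
    spec: ModelSpec
    config: McmcConfig
    converged: bool = True
    convergence_message: str = ""
    _idata: az.InferenceData | None = field(default=None, repr=False, compare=False)

    @property
    def n_draws(self) -> int:
        return self.draws["delta"].shape[0] * self.draws["delta"].shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All retained draws of a scalar parameter, chains concatenated."""
        return self.draws[name].reshape(-1)

    def to_inference_data(self) -> az.InferenceData:
        if self._idata is None:
            self._idata = az.from_dict(
                posterior={
                    "delta": self.draws["delta"],
                    "tau": self.draws["tau"],
                    "mu0": self.draws["mu0"],
                    "mu": self.draws["mu"],
                    "d": self.draws["d"],
                },
                coords={"trial": list(self.labels)},
                dims={"mu": ["trial"], "d": ["trial"]},
            )
        return self._idata

    def draws_frame(self) -> pd.DataFrame:
        """Flattened draws, one column per scalar parameter."""
        cols = {
            "chain": np.repeat(
                np.arange(self.draws["delta"].shape[0]),
                self.draws["delta"].shape[1],
            ),
            "delta": self.flat("delta"),
            "tau": self.flat("tau"),
            "mu0": self.flat("mu0"),
        }
        for i, label in enumerate(self.labels):
            cols[f"mu[{label}]"] = self.draws["mu"][:, :, i].reshape(-1)
            cols[f"d[{label}]"] = self.draws["d"][:, :, i].reshape(-1)
        return pd.DataFrame(cols)

    def save_draws(self, path: str | Path) -> None:
        self.draws_frame().to_csv(path, index=False)

    def save_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(summarize(self), indent=2))


def _initial_state(
    dataset: MetaAnalysisDataset, spec: ModelSpec
) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    r_t, n_t, r_c, n_c = dataset.counts()
    # empirical pooled logits with a 0.5 correction keep the start finite
    events = r_t + r_c
    total = n_t + n_c
    mu = np.log((events + 0.5) / (total - events + 0.5))
    prior = spec.heterogeneity_prior
    if prior.family == "fixed":
        tau0 = prior.params[0]
    else:
        tau0 = float(np.clip(prior.summary().tau_median, 0.01, 5.0))
    z0 = prior.initial_unconstrained(tau0)
    return 0.0, float(np.mean(mu)), z0, mu, np.zeros(dataset.k)


def fit(
    dataset: MetaAnalysisDataset,
    spec: ModelSpec,
    config: McmcConfig = McmcConfig(),
    include_likelihood: bool = True,
    check_convergence: bool = True,
) -> PosteriorResult:
    """Sample the posterior; deterministic given ``config.seed``.

    With ``include_likelihood=False`` the binomial terms are switched off
    and the sampler explores the joint prior (useful to verify that the
    marginal of tau reproduces the heterogeneity prior).

    Non-convergence (split-Rhat > 1.05 or bulk ESS < 400 on delta or tau)
    flags the result and logs a warning; draws are always returned.
    """
    r_t, n_t, r_c, n_c = dataset.counts()
    code, params = spec.heterogeneity_prior.engine_code()
    delta0, mu00, z0, mu_init, d_init = _initial_state(dataset, spec)

    per_chain = []
    for chain in range(config.chains):
        chain_seed = int((config.seed * 1_000_003 + 7919 * chain + 1) % 2_147_483_647)
        jitter = np.random.default_rng(chain_seed)
        per_chain.append(
            _engine.run_chain(
                r_t.astype(np.float64),
                (n_t - r_t).astype(np.float64),
                r_c.astype(np.float64),
                (n_c - r_c).astype(np.float64),
                code,
                float(params[0]),
                float(params[1]),
                float(spec.delta_prior_variance),
                float(spec.mu_prior_variance),
                float(spec.mu0_prior_variance),
                1.0 if include_likelihood else 0.0,
                int(config.iterations),
                int(config.burn_in),
                int(config.thin),
                chain_seed,
                delta0 + 0.5 * jitter.standard_normal(),
                mu00 + 0.5 * jitter.standard_normal(),
                z0 + 0.5 * jitter.standard_normal(),
                mu_init + 0.2 * jitter.standard_normal(dataset.k),
                d_init + 0.2 * jitter.standard_normal(dataset.k),
            )
        )
    stacked = np.stack(per_chain)  # (chains, n_keep, 3 + 2k)
    k = dataset.k
    draws = {
        "delta": stacked[:, :, 0],
        "tau": stacked[:, :, 1],
        "mu0": stacked[:, :, 2],
        "mu": stacked[:, :, 3 : 3 + k],
        "d": stacked[:, :, 3 + k :],
    }
    result = PosteriorResult(
        draws=draws,
        labels=tuple(t.label for t in dataset.trials),
        spec=spec,
        config=config,
    )
    if check_convergence and config.chains >= 2:
        diag = diagnostics(result)
        bad = diag.loc[["delta", "tau"]]
        if (bad["rhat"] > 1.05).any() or (bad["ess_bulk"] < 400).any():
            result.converged = False
            result.convergence_message = (
                "non-convergence on delta/tau: "
                + bad[["rhat", "ess_bulk"]].to_string()
            )
            logger.warning(result.convergence_message)
    return result


def _mcse_median(x: np.ndarray) -> float:
    return float(az.mcse(x[None, :] if x.ndim == 1 else x, method="quantile", prob=0.5))


def summarize(result: PosteriorResult) -> dict:
    """Posterior medians, equal-tailed 95% CrIs, tail probabilities and
    Monte-Carlo standard errors for delta and tau."""
    if result.n_draws < 1000:
        raise ValueError("need at least 1000 retained draws to summarise")
    out: dict[str, dict] = {}
    for name in ("delta", "tau"):
        x = result.flat(name)
        lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
        out[name] = {
            "median": float(med),
            "cri_low": float(lo),
            "cri_high": float(hi),
            "p_positive": float(np.mean(x > 0)),
            "p_negative": float(np.mean(x < 0)),
            "mcse_median": _mcse_median(result.draws[name]),
        }
    out["converged"] = result.converged
    return out


def beneficial_side_probability(result: PosteriorResult) -> float:
    """Posterior mass of delta on the side of zero containing its median
    (the direction the data favour)."""
    x = result.flat("delta")
    if np.median(x) >= 0:
        return float(np.mean(x > 0))
    return float(np.mean(x < 0))


def diagnostics(result: PosteriorResult) -> pd.DataFrame:
    """Split-Rhat, bulk ESS and lag-1 autocorrelation per parameter.

    Requires at least two chains.  Zero-variance chains yield NaN Rhat,
    which callers should treat as a failed check.
    """
    if result.draws["delta"].shape[0] < 2:
        raise ValueError("diagnostics require at least two chains")
    idata = result.to_inference_data()
    rhat = az.rhat(idata)
    ess = az.ess(idata, method="bulk")
    rows = {}
    for name in ("delta", "tau", "mu0"):
        x = result.draws[name]
        rows[name] = {
            "rhat": float(rhat[name].values),
            "ess_bulk": float(ess[name].values),
            "lag1_autocorr": _lag_autocorr(x),
        }
    for i, label in enumerate(result.labels):
        for base in ("mu", "d"):
            x = result.draws[base][:, :, i]
            rows[f"{base}[{label}]"] = {
                "rhat": float(rhat[base].values[i]),
                "ess_bulk": float(ess[base].values[i]),
                "lag1_autocorr": _lag_autocorr(x),
            }
    return pd.DataFrame(rows).T


def _lag_autocorr(chains: np.ndarray, lag: int = 1) -> float:
    """Average within-chain lag-k autocorrelation."""
    acs = []
    for c in range(chains.shape[0]):
        x = chains[c]
        x = x - x.mean()
        denom = float(np.dot(x, x))
        if denom == 0.0:
            acs.append(np.nan)
        else:
            acs.append(float(np.dot(x[:-lag], x[lag:]) / denom))
    return float(np.mean(acs))
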