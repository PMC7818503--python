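"""Heterogeneity priors for the between-study standard deviation tau.

In a random-effects meta-analysis of a few small trials the posterior is
prior-driven, so the shape of the prior placed on the between-study SD
``tau`` (on the log odds ratio scale) matters.  This module implements a
registry of twelve priors that are specified on five different transformed
scales of tau:

================  ==========================================
scale             g(tau)
================  ==========================================
``precision``     1 / tau^2
``log_tau2``      log(tau^2)
``tau2``          tau^2
``tau``           tau
``shrinkage``     s0 / (s0 + tau)   (DuMouchel transform)
================  ==========================================

Each prior knows its density pushed forward to the tau scale, its CDF,
quantiles and an i.i.d. sampler, so prior medians and 95% ranges can be
tabulated and compared directly.  The two empirical priors (``E``, ``e``)
require a data-derived scale ``s0`` — the square root of the harmonic mean
of the within-study log-OR variances — computed by :func:`compute_s0`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .data import MetaAnalysisDataset, within_study_variances

__all__ = [
    "HeterogeneityPrior",
    "PriorSummary",
    "PRIOR_IDS",
    "make_prior",
    "fixed_tau",
    "compute_s0",
]

#: Registry order follows the conventional presentation: gamma-on-precision
#: pairs, uniforms on log tau^2, tau^2 and tau, half-normals on tau, then
#: the two empirical priors.
PRIOR_IDS = ("AG", "ag", "AU", "du", "B", "b", "C", "c", "DN", "dn", "E", "e")

# (scale, family, params, restrictiveness); empirical priors get params at
# construction time from s0.
_SPECS: dict[str, tuple[str, str, tuple[float, ...], str]] = {
    "AG": ("precision", "gamma", (0.001, 0.001), "less"),
    "ag": ("precision", "gamma", (0.1, 0.1), "more"),
    "AU": ("log_tau2", "uniform", (-10.0, 10.0), "less"),
    "du": ("log_tau2", "uniform", (-10.0, 1.386), "more"),
    "B": ("tau2", "uniform", (0.0, 1000.0), "less"),
    "b": ("tau2", "uniform", (0.0, 4.0), "more"),
    "C": ("tau", "uniform", (0.0, 100.0), "less"),
    "c": ("tau", "uniform", (0.0, 2.0), "more"),
    "DN": ("tau", "half_normal", (100.0,), "less"),
    "dn": ("tau", "half_normal", (1.0,), "more"),
    "E": ("shrinkage", "dumouchel", (), "empirical"),
    "e": ("tau2", "half_normal", (), "empirical"),
}

# Integer family/scale codes consumed by the numba MCMC kernels.
CODE_GAMMA_PRECISION = 0
CODE_UNIFORM_LOG_TAU2 = 1
CODE_UNIFORM_TAU2 = 2
CODE_UNIFORM_TAU = 3
CODE_HALFNORMAL_TAU = 4
CODE_DUMOUCHEL = 5
CODE_HALFNORMAL_TAU2 = 6
CODE_FIXED = 7


@dataclass(frozen=True)
class PriorSummary:
    """Prior median and equal-tailed 95% range of tau."""

    tau_median: float
    tau_q025: float
    tau_q975: float


@dataclass(frozen=True)
class HeterogeneityPrior:
    """A prior for the between-study SD, specified on a transformed scale.

    Attributes
    ----------
    id
        Registry identifier (``AG`` ... ``e``) or ``fixed``.
    scale
        The transformed scale ``g(tau)`` the distribution lives on.
    family
        Distribution family of ``g(tau)``.
    params
        Family hyperparameters: gamma ``(shape, rate)``; uniform
        ``(lower, upper)``; half-normal ``(variance,)``.  The half-normal
        is parameterised by its *variance* (SD = sqrt(variance)), the
        convention under which Half-normal(0, 100) on tau has median 6.75.
    restrictive
        ``"less"``, ``"more"`` or ``"empirical"``.
    s0
        Data-derived scale for the empirical priors, in log-OR (tau) units.
    """

    id: str
    scale: str
    family: str
    params: tuple[float, ...]
    restrictive: str
    s0: float | None = None

    def __post_init__(self) -> None:
        if self.family == "gamma":
            shape, rate = self.params
            if shape <= 0 or rate <= 0:
                raise ValueError("gamma shape and rate must be positive")
        elif self.family == "uniform":
            lo, hi = self.params
            if not lo < hi:
                raise ValueError("uniform lower bound must be below upper")
        elif self.family == "half_normal":
            (variance,) = self.params
            if variance <= 0:
                raise ValueError("half-normal variance must be positive")
        elif self.family == "dumouchel":
            if self.s0 is None:
                raise ValueError("DuMouchel prior requires s0")
        elif self.family == "fixed":
            (tau0,) = self.params
            if tau0 <= 0:
                raise ValueError("fixed tau must be positive")
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if self.s0 is not None and self.s0 <= 0:
            raise ValueError("s0 must be positive")

    # -- distribution of g(tau) on its native scale ----------------------

    def _native(self):
        if self.family == "gamma":
            shape, rate = self.params
            return stats.gamma(shape, scale=1.0 / rate)
        if self.family == "uniform":
            lo, hi = self.params
            return stats.uniform(lo, hi - lo)
        if self.family == "half_normal":
            (variance,) = self.params
            return stats.halfnorm(scale=np.sqrt(variance))
        if self.family == "dumouchel":
            return stats.uniform(0.0, 1.0)
        raise ValueError(f"no native distribution for family {self.family!r}")

    def _tau_from_native(self, g: np.ndarray) -> np.ndarray:
        if self.scale == "precision":
            return 1.0 / np.sqrt(g)
        if self.scale == "log_tau2":
            return np.exp(0.5 * g)
        if self.scale == "tau2":
            return np.sqrt(g)
        if self.scale == "tau":
            return np.asarray(g, dtype=float)
        if self.scale == "shrinkage":
            return self.s0 * (1.0 - g) / g
        raise ValueError(f"unknown scale {self.scale!r}")

    # -- tau-scale density / CDF / quantiles ------------------------------

    def log_density_tau(self, tau):
        """Log density of tau, including the Jacobian of ``g``.

        Outside the support the log density is ``-inf``; ``tau <= 0``
        raises, since tau is a standard deviation.
        """
        tau = np.asarray(tau, dtype=float)
        if np.any(tau <= 0):
            raise ValueError("tau must be positive")
        if self.family == "fixed":
            raise ValueError("a point mass has no density on the tau scale")
        dist = self._native()
        if self.scale == "precision":
            g, log_jac = tau**-2, np.log(2.0) - 3.0 * np.log(tau)
        elif self.scale == "log_tau2":
            g, log_jac = 2.0 * np.log(tau), np.log(2.0) - np.log(tau)
        elif self.scale == "tau2":
            g, log_jac = tau**2, np.log(2.0 * tau)
        elif self.scale == "tau":
            g, log_jac = tau, 0.0
        else:  # shrinkage
            g = self.s0 / (self.s0 + tau)
            log_jac = np.log(self.s0) - 2.0 * np.log(self.s0 + tau)
        return dist.logpdf(g) + log_jac

    def tau_cdf(self, tau):
        """P(tau <= t); handles decreasing transforms (precision, shrinkage)."""
        tau = np.asarray(tau, dtype=float)
        if self.family == "fixed":
            return np.where(tau >= self.params[0], 1.0, 0.0)
        dist = self._native()
        if self.scale == "precision":
            return dist.sf(tau**-2)
        if self.scale == "log_tau2":
            return dist.cdf(2.0 * np.log(tau))
        if self.scale == "tau2":
            return dist.cdf(tau**2)
        if self.scale == "tau":
            return dist.cdf(tau)
        # shrinkage, decreasing in tau
        return dist.sf(self.s0 / (self.s0 + tau))

    def tau_quantile(self, p):
        """Quantile of tau at probability ``p`` in (0, 1)."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("p must lie strictly inside (0, 1)")
        if self.family == "fixed":
            return np.full_like(p, self.params[0])
        dist = self._native()
        if self.scale == "precision":
            return 1.0 / np.sqrt(dist.isf(p))
        if self.scale == "log_tau2":
            return np.exp(0.5 * dist.ppf(p))
        if self.scale == "tau2":
            return np.sqrt(dist.ppf(p))
        if self.scale == "tau":
            return dist.ppf(p)
        u = dist.isf(p)  # shrinkage quantile at 1 - p
        return self.s0 * (1.0 - u) / u

    def sample(self, n: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
        """Draw ``n`` i.i.d. tau values."""
        rng = np.random.default_rng(rng)
        if self.family == "fixed":
            return np.full(n, self.params[0])
        g = self._native().rvs(size=n, random_state=rng)
        return self._tau_from_native(g)

    def summary(self) -> PriorSummary:
        q = self.tau_quantile(np.array([0.025, 0.5, 0.975]))
        return PriorSummary(tau_median=float(q[1]), tau_q025=float(q[0]),
                            tau_q975=float(q[2]))

    # -- engine interface --------------------------------------------------

    def engine_code(self) -> tuple[int, np.ndarray]:
        """Integer family code and parameter vector for the MCMC kernels."""
        if self.family == "fixed":
            return CODE_FIXED, np.array([self.params[0], 0.0])
        if self.family == "gamma":
            return CODE_GAMMA_PRECISION, np.array(self.params, dtype=float)
        if self.family == "dumouchel":
            return CODE_DUMOUCHEL, np.array([self.s0, 0.0])
        if self.family == "uniform":
            code = {
                "log_tau2": CODE_UNIFORM_LOG_TAU2,
                "tau2": CODE_UNIFORM_TAU2,
                "tau": CODE_UNIFORM_TAU,
            }[self.scale]
            return code, np.array(self.params, dtype=float)
        # half-normal
        code = CODE_HALFNORMAL_TAU if self.scale == "tau" else CODE_HALFNORMAL_TAU2
        return code, np.array([self.params[0], 0.0])

    def initial_unconstrained(self, tau: float) -> float:
        """Map a tau value to the sampler's unconstrained coordinate."""
        if self.family == "fixed":
            return 0.0
        eps = 1e-6
        if self.scale == "precision":
            return float(np.log(tau**-2))
        if self.scale == "log_tau2":
            lo, hi = self.params
            frac = np.clip((2 * np.log(tau) - lo) / (hi - lo), eps, 1 - eps)
            return float(logit(frac))
        if self.scale == "tau2":
            if self.family == "half_normal":
                return float(np.log(tau**2))
            lo, hi = self.params
            frac = np.clip((tau**2 - lo) / (hi - lo), eps, 1 - eps)
            return float(logit(frac))
        if self.scale == "tau":
            if self.family == "half_normal":
                return float(np.log(tau))
            lo, hi = self.params
            frac = np.clip((tau - lo) / (hi - lo), eps, 1 - eps)
            return float(logit(frac))
        u = np.clip(self.s0 / (self.s0 + tau), eps, 1 - eps)
        return float(logit(u))

    def tau_from_unconstrained(self, z):
        """Inverse of :meth:`initial_unconstrained` (vectorised)."""
        z = np.asarray(z, dtype=float)
        if self.family == "fixed":
            return np.full_like(z, self.params[0])
        if self.scale == "precision":
            return np.exp(-0.5 * z)
        if self.family == "uniform":
            lo, hi = self.params
            g = lo + (hi - lo) * expit(z)
            return self._tau_from_native(g)
        if self.family == "dumouchel":
            return self._tau_from_native(expit(z))
        # half-normal on tau or tau^2: z = log g
        return self._tau_from_native(np.exp(z))


def make_prior(prior_id: str, s0: float | None = None) -> HeterogeneityPrior:
    """Construct a registry prior by id.

    ``s0`` (the square root of the harmonic mean of within-study variances)
    is required for the empirical priors ``E`` and ``e`` and ignored
    otherwise.  Prior ``e`` is a half-normal on tau^2 whose variance
    parameter is ``z_0.75 / s0`` with ``z_0.75 ≈ 0.6745`` the standard
    normal upper quartile.
    """
    if prior_id not in _SPECS:
        raise KeyError(
            f"unknown prior id {prior_id!r}; valid ids: {', '.join(PRIOR_IDS)}"
        )
    scale, family, params, restrictive = _SPECS[prior_id]
    if restrictive == "empirical":
        if s0 is None or s0 <= 0:
            raise ValueError(f"prior {prior_id!r} requires a positive s0")
        if prior_id == "e":
            params = (float(stats.norm.ppf(0.75)) / s0,)
        return HeterogeneityPrior(prior_id, scale, family, params, restrictive, s0=s0)
    return HeterogeneityPrior(prior_id, scale, family, params, restrictive)


def fixed_tau(tau0: float) -> HeterogeneityPrior:
    """Degenerate prior fixing tau at ``tau0`` (for oracle checks)."""
    return HeterogeneityPrior("fixed", "tau", "fixed", (float(tau0),), "fixed")


def compute_s0(
    dataset: MetaAnalysisDataset, correction: float = 0.5
) -> float:
    """Scale of the empirical priors: sqrt of the harmonic mean of the
    within-study log-OR variances, ``sqrt(k / sum(1 / s_i^2))``.

    The square root puts ``s0`` on the tau (SD) scale, so the DuMouchel
    shrinkage ratio ``s0 / (s0 + tau)`` is dimensionless and the prior
    median of tau equals ``s0``.
    """
    s2 = within_study_variances(dataset, correction=correction)
    k = len(s2)
    return float(np.sqrt(k / np.sum(1.0 / s2)))
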