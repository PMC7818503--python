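"""Arm-level heterogeneity simulator for sparse-event meta-analyses.

Each simulated trial draws an equal per-arm sample size uniformly from an
integer range, then draws *independent* study-specific logits for the two
arms around fixed population values:

    theta_iC ~ N(logit(pi_c),          (tau/2)^2)
    theta_iT ~ N(logit(pi_c) + delta,  (tau/2)^2)
    r_ij     ~ Binomial(expit(theta_ij), n_ij)

Because the per-arm SD is tau/2 and the arms are independent, the SD of
the trial-specific log odds ratio theta_iT - theta_iC is tau/sqrt(2); the
mechanism is implemented literally as stated above.  Datasets with
zero-event arms — including all-zero datasets — are retained: they are the
point of the exercise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml
from scipy.special import expit, logit

from .data import MetaAnalysisDataset, TrialRecord

__all__ = ["Scenario", "simulate_dataset", "scenario_grid", "PRESETS"]

PRESETS = ("paper_full_factors", "desk_small")


@dataclass(frozen=True)
class Scenario:
    """One simulation condition."""

    k: int
    n_low: int
    n_high: int
    pi_c: float
    tau: float
    delta: float
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 1 <= self.n_low <= self.n_high:
            raise ValueError("need 1 <= n_low <= n_high")
        if not 0 < self.pi_c < 1:
            raise ValueError("pi_c must lie in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def rng(self, replicate: int) -> np.random.Generator:
        """Independent, reproducible substream for one replicate."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, replicate]))


def simulate_dataset(
    scenario: Scenario,
    replicate: int = 0,
    rng: np.random.Generator | None = None,
) -> MetaAnalysisDataset:
    """Generate one meta-analysis dataset under ``scenario``.

    ``replicate`` selects the RNG substream; passing an explicit ``rng``
    overrides it.  Zero-event arms and all-zero datasets are returned
    unchanged.
    """
    if rng is None:
        rng = scenario.rng(replicate)
    n = rng.integers(scenario.n_low, scenario.n_high + 1, size=scenario.k)
    base = logit(scenario.pi_c)
    sd = scenario.tau / 2.0
    theta_c = rng.normal(base, sd, size=scenario.k)
    theta_t = rng.normal(base + scenario.delta, sd, size=scenario.k)
    r_c = rng.binomial(n, expit(theta_c))
    r_t = rng.binomial(n, expit(theta_t))
    trials = tuple(
        TrialRecord(f"trial{i + 1}", int(r_t[i]), int(n[i]), int(r_c[i]), int(n[i]))
        for i in range(scenario.k)
    )
    return MetaAnalysisDataset(trials, name=f"sim_rep{replicate}")


def _load_presets() -> dict:
    text = resources.files("sparsemeta").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def scenario_grid(
    preset: str = "paper_full_factors",
    base_seed: int = 0,
    n_reps: int | None = None,
) -> list[Scenario]:
    """Ordered list of scenarios for a named preset.

    ``paper_full_factors`` crosses all design factor levels (162 cells);
    ``desk_small`` is a documented 12-cell subset with 200 replicates.
    Scenario seeds are derived deterministically from ``base_seed`` and
    the cell index; ``n_reps`` overrides the preset replicate count.
    """
    presets = _load_presets()
    if preset not in presets:
        raise KeyError(f"unknown preset {preset!r}; available: {sorted(presets)}")
    cfg = presets[preset]
    if "tau_delta" in cfg:
        tau_delta = [tuple(td) for td in cfg["tau_delta"]]
    else:
        tau_delta = list(itertools.product(cfg["tau"], cfg["delta"]))
    reps = int(n_reps if n_reps is not None else cfg["n_reps"])
    scenarios = []
    cells = itertools.product(cfg["k"], cfg["n_range"], cfg["pi_c"], tau_delta)
    for idx, (k, (n_low, n_high), pi_c, (tau, delta)) in enumerate(cells):
        scenarios.append(
            Scenario(
                k=int(k),
                n_low=int(n_low),
                n_high=int(n_high),
                pi_c=float(pi_c),
                tau=float(tau),
                delta=float(delta),
                n_reps=reps,
                seed=int((base_seed * 100_003 + idx) % 2_147_483_647),
            )
        )
    return scenarios


def with_reps(scenario: Scenario, n_reps: int) -> Scenario:
    """Copy of ``scenario`` with a different replicate count."""
    return replace(scenario, n_reps=n_reps)
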