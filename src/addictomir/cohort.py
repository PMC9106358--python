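"""Synthetic mouse cohorts: latent phenotypes, agents, and session plans."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .sessions import AgentParams, SessionLog, simulate_session


@dataclass
class CohortSpec:
    """Specification of a simulated operant cohort.

    ``phenotype_params`` maps phenotype label -> parameter name ->
    (mean, sd) of a truncated normal. Defaults mirror a 51-mouse
    palatable-food-trained cohort with ~25% latently vulnerable animals.
    """

    n_mice: int = defaults.DEFAULT_N_MICE
    vulnerable_fraction: float = defaults.DEFAULT_VULNERABLE_FRACTION
    seed: int = 0
    phenotype_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 defaults.PHENOTYPE_PARAMS.items()})
    session_plan: tuple[str, ...] = defaults.DEFAULT_SESSION_PLAN

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if not (0.0 <= self.vulnerable_fraction <= 1.0):
            raise ValueError("vulnerable_fraction must be in [0, 1]")
        if len(self.session_plan) == 0:
            raise ValueError("session plan must not be empty")


def draw_agent(phenotype: str, params: dict, rng: np.random.Generator) -> AgentParams:
    """Draw one agent's parameters from its phenotype distribution."""
    def trunc(mean: float, sd: float, lo: float = 0.0, hi: float = np.inf) -> float:
        for _ in range(100):
            x = rng.normal(mean, sd)
            if lo < x <= hi or (x == lo == 0.0):
                return x
        return float(np.clip(mean, lo + 1e-9, hi))

    return AgentParams(
        active_rate=trunc(*params["active_rate"]),
        inactive_rate=trunc(*params["inactive_rate"]),
        persistence_bias=trunc(*params["persistence_bias"]),
        motivation_cap=trunc(*params["motivation_cap"]),
        punishment_sensitivity=trunc(*params["punishment_sensitivity"],
                                     lo=0.0, hi=1.0),
        phenotype_label=phenotype,
    )


def simulate_cohort(spec: CohortSpec) -> tuple[dict[str, list[SessionLog]], pd.DataFrame]:
    """Simulate a cohort: full session plan per mouse plus latent labels.

    Returns ``(logs, labels)`` where ``logs`` maps mouse id to its session
    logs in plan order and ``labels`` records the latent phenotype of each
    mouse (kept separate from any downstream classification).  Vulnerable
    agents carry elevated persistence bias and motivation cap and reduced
    punishment sensitivity per the default phenotype parameters.
    """
    rng = np.random.default_rng(spec.seed)
    phenotypes = np.where(rng.random(spec.n_mice) < spec.vulnerable_fraction,
                          "vulnerable", "resilient")
    logs: dict[str, list[SessionLog]] = {}
    rows = []
    for i, pheno in enumerate(phenotypes):
        mouse_id = f"m{i + 1:03d}"
        agent = draw_agent(pheno, spec.phenotype_params[pheno], rng)
        mouse_logs = []
        for j, schedule in enumerate(spec.session_plan):
            session_seed = rng.integers(0, 2**31 - 1)
            log = simulate_session(agent, schedule,
                                   seed=int(session_seed))
            log.meta["mouse_id"] = mouse_id
            log.meta["session_index"] = j
            mouse_logs.append(log)
        logs[mouse_id] = mouse_logs
        rows.append({"mouse_id": mouse_id, "phenotype": pheno})
    labels = pd.DataFrame(rows)
    return logs, labels
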