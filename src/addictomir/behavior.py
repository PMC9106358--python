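"""Addiction-like criteria and phenotypic trait scores from session logs.

Three criteria define the addiction-like phenotype:

persistence
    Mean count of non-reinforced active responses during the signalled
    10-minute pellet-free window, over three consecutive FR5 sessions.
motivation (breaking point)
    The last fully completed requirement of the progressive-ratio ladder.
compulsion
    Total foot-shocks taken in the 50-minute shock-test session.

Four traits complement them: impulsivity (active responses during post-pellet
time-outs), cognitive-flexibility errors (perseverative presses on the
previously active lever after contingency reversal), appetitive cue
reactivity (post-cue minus pre-cue active responding in the cue probe), and
aversive cue reactivity (non-reinforced responding with the shock-grid floor
present).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .sessions import SessionLog

logger = logging.getLogger(__name__)

PR_LADDER = defaults.PR_LADDER


@dataclass
class CriterionScores:
    persistence: float
    breaking_point: float
    shocks: float


@dataclass
class TraitScores:
    impulsivity: float
    flexibility_errors: float
    appetitive_reactivity: float
    aversive_reactivity: float


def _active_events(log: SessionLog) -> pd.DataFrame:
    return log.events[log.events["lever"] == "active"]


def persistence_score(logs: Iterable[SessionLog]) -> float:
    """Mean pellet-free active-response count over the provided FR5 sessions."""
    counts = []
    for log in logs:
        ev = _active_events(log)
        n_pf = int((ev["period"] == "pellet_free").sum())
        if (log.events["period"] == "pellet_free").any() or \
                log.schedule == "FR5_PELLET_FREE":
            counts.append(n_pf)
    if not counts:
        raise ValueError("no sessions with a pellet-free period provided")
    return float(np.mean(counts))


def breaking_point(log: SessionLog,
                   ladder: Sequence[int] = PR_LADDER) -> int:
    """Ladder value of the last fully completed PR requirement (0 if none)."""
    if log.schedule != "PR":
        raise ValueError(f"breaking_point requires a PR session, got {log.schedule}")
    n_pellets = int((log.events["outcome"] == "pellet").sum())
    if n_pellets == 0:
        return 0
    return int(ladder[n_pellets - 1])


def compulsion_score(log: SessionLog) -> int:
    """Total number of shocks delivered in the shock-test session."""
    if log.schedule != "SHOCK":
        raise ValueError(f"compulsion_score requires a SHOCK session, got {log.schedule}")
    return int(log.events["outcome"].isin(["shock", "shock_pellet"]).sum())


def _impulsivity(logs: list[SessionLog]) -> float:
    """Active responses during the 10-s time-out periods of FR5 sessions."""
    fr5 = [l for l in logs if l.schedule in ("FR5", "FR5_PELLET_FREE")]
    if not fr5:
        return math.nan
    total = 0
    for log in fr5:
        ev = _active_events(log)
        total += int((ev["period"] == "timeout").sum())
    return float(total)


def _flexibility_errors(logs: list[SessionLog]) -> float:
    """Perseverative responses on the previously active lever after reversal."""
    rev = [l for l in logs if l.schedule == "REVERSAL"]
    if not rev:
        return math.nan
    # in a reversal session the previously-active lever is logged 'inactive'
    return float(sum(int((l.events["lever"] == "inactive").sum()) for l in rev))


def _appetitive_reactivity(logs: list[SessionLog]) -> float:
    """Active responses after the non-contingent cue minus equal-length baseline."""
    probes = [l for l in logs if l.schedule == "CUE_PROBE"]
    if not probes:
        return math.nan
    total = 0.0
    for log in probes:
        onset = defaults.CUE_ONSET_FRACTION * log.duration_s
        window = min(onset, log.duration_s - onset)
        ev = _active_events(log)
        post = int(((ev["time_s"] >= onset) & (ev["time_s"] < onset + window)).sum())
        base = int(((ev["time_s"] >= onset - window) & (ev["time_s"] < onset)).sum())
        total += post - base
    return float(total)


def _aversive_reactivity(logs: list[SessionLog]) -> float:
    """Non-reinforced active responses in the grid-extinction session."""
    grid = [l for l in logs if l.schedule == "GRID_EXTINCTION"]
    if not grid:
        return math.nan
    return float(sum(len(_active_events(l)) for l in grid))


def trait_scores(logs: Iterable[SessionLog]) -> TraitScores:
    """Compute the four phenotypic traits; missing probes yield NaN."""
    logs = list(logs)
    scores = TraitScores(
        impulsivity=_impulsivity(logs),
        flexibility_errors=_flexibility_errors(logs),
        appetitive_reactivity=_appetitive_reactivity(logs),
        aversive_reactivity=_aversive_reactivity(logs),
    )
    for name in ("impulsivity", "flexibility_errors",
                 "appetitive_reactivity", "aversive_reactivity"):
        if math.isnan(getattr(scores, name)):
            logger.warning("probe session for trait %r missing; score is NaN", name)
    return scores


def criterion_scores(logs: Iterable[SessionLog]) -> CriterionScores:
    """Compute the three addiction-like criteria from one mouse's sessions."""
    logs = list(logs)
    pf = [l for l in logs if l.schedule == "FR5_PELLET_FREE"]
    pr = [l for l in logs if l.schedule == "PR"]
    shock = [l for l in logs if l.schedule == "SHOCK"]
    if not pf or not pr or not shock:
        raise ValueError("criterion scoring needs FR5_PELLET_FREE, PR and SHOCK sessions")
    return CriterionScores(
        persistence=persistence_score(pf),
        breaking_point=float(breaking_point(pr[-1])),
        shocks=float(compulsion_score(shock[-1])),
    )


def score_cohort(logs: dict[str, list[SessionLog]]) -> pd.DataFrame:
    """Per-mouse criterion and trait scores for a whole cohort.

    Returns a DataFrame with columns ``mouse_id, persistence,
    breaking_point, shocks, impulsivity, flexibility_errors,
    appetitive_reactivity, aversive_reactivity``.
    """
    rows = []
    for mouse_id, mouse_logs in logs.items():
        crit = criterion_scores(mouse_logs)
        traits = trait_scores(mouse_logs)
        rows.append({
            "mouse_id": mouse_id,
            "persistence": crit.persistence,
            "breaking_point": crit.breaking_point,
            "shocks": crit.shocks,
            "impulsivity": traits.impulsivity,
            "flexibility_errors": traits.flexibility_errors,
            "appetitive_reactivity": traits.appetitive_reactivity,
            "aversive_reactivity": traits.aversive_reactivity,
        })
    return pd.DataFrame(rows)
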