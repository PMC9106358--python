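"""Operant-session schedule engine and stochastic session simulator.

The engine is a pure state machine: it maps a time-ordered stream of lever
presses onto schedule outcomes (pellets, cue lights, foot-shocks, time-outs).
:func:`replay_presses` exposes it deterministically for arbitrary press
sequences; :func:`simulate_session` drives it with a thinned-Poisson response
process parametrised by an :class:`AgentParams`.

Supported schedules
-------------------
FR1 / FR5
    Fixed ratio: one pellet (with cue light and a 10-s time-out) per 1 or 5
    active responses outside time-out.
FR5_PELLET_FREE
    FR5 whose final 10 minutes are a signalled pellet-free window: responses
    there are tagged ``period=pellet_free`` and never reinforced.
PR
    Progressive ratio over the 35-step ladder; ends at ladder exhaustion,
    the 5-h cap, or one hour without a response on either lever.
SHOCK
    50-min FR5 variant: the 4th active response of a cycle delivers a shock
    only, the 5th a shock plus pellet; the cycle resets if the 5th response
    does not follow the 4th within one minute.
CUE_PROBE
    Non-reinforced probe with a non-contingent cue light at mid-session.
GRID_EXTINCTION
    Non-reinforced probe with the shock-test grid floor present; no shock,
    no pellet, no cue.
REVERSAL
    FR5 with the lever contingency swapped; presses on the previously
    active (now inactive) lever are the perseverative errors scored by the
    cognitive-flexibility trait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import defaults

SCHEDULES = frozenset(defaults.SESSION_DURATION_S)

EVENT_COLUMNS = ["time_s", "lever", "outcome", "cue_light", "period"]


@dataclass
class AgentParams:
    """Latent behavioural parameters of one simulated mouse.

    Rates are responses per minute. ``persistence_bias`` multiplies the
    active-lever rate during non-reinforced periods (pellet-free window,
    time-outs, probes); ``motivation_cap`` is the largest single-reward
    requirement the agent will work through in a PR session;
    ``punishment_sensitivity`` in (0, 1] multiplies the active rate once per
    shock received within a shock session (1 = insensitive).
    """

    active_rate: float
    inactive_rate: float
    persistence_bias: float
    motivation_cap: float
    punishment_sensitivity: float
    phenotype_label: str = "resilient"

    def __post_init__(self) -> None:
        if self.active_rate < 0 or self.inactive_rate < 0:
            raise ValueError("response rates must be >= 0")
        if not (0.0 < self.punishment_sensitivity <= 1.0):
            raise ValueError("punishment_sensitivity must be in (0, 1]")
        if self.motivation_cap < 0:
            raise ValueError("motivation_cap must be >= 0")
        if self.persistence_bias < 0:
            raise ValueError("persistence_bias must be >= 0")


@dataclass
class SessionLog:
    """Time-ordered event log of one operant session."""

    schedule: str
    duration_s: float
    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def n_events(self, lever: str | None = None) -> int:
        if lever is None:
            return len(self.events)
        return int((self.events["lever"] == lever).sum())


def _canonical_schedule(name: str) -> str:
    canon = name.strip().upper()
    if canon not in SCHEDULES:
        raise ValueError(
            f"unknown schedule {name!r}; expected one of {sorted(SCHEDULES)}"
        )
    return canon


class ScheduleEngine:
    """State machine translating lever presses into schedule outcomes.

    Presses must be fed in non-decreasing time order via :meth:`press`.
    The engine never draws randomness; it is shared by the deterministic
    replay path and the stochastic simulator.
    """

    def __init__(self, schedule: str, duration_s: float | None = None,
                 ladder: Sequence[int] = defaults.PR_LADDER,
                 timeout_s: float = defaults.TIMEOUT_S):
        self.schedule = _canonical_schedule(schedule)
        if duration_s is None:
            duration_s = defaults.SESSION_DURATION_S[self.schedule]
        if duration_s <= 0:
            raise ValueError("session duration must be positive")
        self.duration_s = float(duration_s)
        self.timeout_s = float(timeout_s)
        self.ladder = tuple(ladder)

        self.ratio = {"FR1": 1}.get(self.schedule, 5)
        self.counter = 0            # active responses toward current ratio
        self.timeout_until = -math.inf
        self.n_pellets = 0
        self.n_shocks = 0
        self.completed_cycles = 0   # SHOCK: cycles reaching the 5th response
        self.abandoned_cycles = 0   # SHOCK: cycles reset after the 4th
        self._t_fourth = math.inf   # SHOCK: time of the pending 4th response
        self.ladder_idx = 0         # PR: index of requirement in progress
        self.terminated = False
        self.termination_reason: str | None = None

        if self.schedule == "FR5_PELLET_FREE":
            self.pellet_free = (self.duration_s - defaults.PELLET_FREE_LEN_S,
                                self.duration_s)
        else:
            self.pellet_free = None
        self.cue_onset_s = (defaults.CUE_ONSET_FRACTION * self.duration_s
                            if self.schedule == "CUE_PROBE" else None)

    # ------------------------------------------------------------- queries

    @property
    def current_requirement(self) -> int:
        """PR: responses needed for the pellet currently being worked for."""
        if self.ladder_idx >= len(self.ladder):
            return self.ladder[-1]
        return self.ladder[self.ladder_idx]

    def period_at(self, t: float) -> str:
        if self.pellet_free and self.pellet_free[0] <= t < self.pellet_free[1]:
            return "pellet_free"
        if t < self.timeout_until:
            return "timeout"
        return "reinforced"

    def next_rate_boundary(self, t: float) -> float:
        """Next instant at which the response-rate context may change."""
        candidates = [self.duration_s]
        if self.timeout_until > t:
            candidates.append(self.timeout_until)
        if self.pellet_free:
            for edge in self.pellet_free:
                if edge > t:
                    candidates.append(edge)
        if self.cue_onset_s is not None and self.cue_onset_s > t:
            candidates.append(self.cue_onset_s)
        return min(candidates)

    # --------------------------------------------------------------- press

    def press(self, t: float, lever: str) -> dict:
        """Register one lever press; returns the event row."""
        if self.terminated:
            raise RuntimeError("session already terminated")
        period = self.period_at(t)
        outcome = "none"
        cue = self.cue_onset_s is not None and t >= self.cue_onset_s

        if lever == "active" and period == "reinforced":
            if self.schedule in ("FR1", "FR5", "FR5_PELLET_FREE", "REVERSAL"):
                self.counter += 1
                if self.counter == self.ratio:
                    outcome = "pellet"
                    cue = True
                    self._deliver_pellet(t)
            elif self.schedule == "PR":
                self.counter += 1
                if self.counter == self.current_requirement:
                    outcome = "pellet"
                    cue = True
                    self._deliver_pellet(t)
                    self.ladder_idx += 1
                    if self.ladder_idx == len(self.ladder):
                        self.terminated = True
                        self.termination_reason = "ladder_exhausted"
            elif self.schedule == "SHOCK":
                if (self.counter == 4
                        and t - self._t_fourth > defaults.SHOCK_RESET_S):
                    # 5th response too late: schedule reinitiated; the shock
                    # taken at the 4th response stands.
                    self.abandoned_cycles += 1
                    self.counter = 0
                self.counter += 1
                if self.counter == 4:
                    outcome = "shock"
                    self.n_shocks += 1
                    self._t_fourth = t
                elif self.counter == 5:
                    outcome = "shock_pellet"
                    cue = True
                    self.n_shocks += 1
                    self.completed_cycles += 1
                    self._deliver_pellet(t)
            # CUE_PROBE / GRID_EXTINCTION deliver nothing.

        return {"time_s": t, "lever": lever, "outcome": outcome,
                "cue_light": bool(cue), "period": period}

    def _deliver_pellet(self, t: float) -> None:
        self.n_pellets += 1
        self.counter = 0
        self.timeout_until = t + self.timeout_s

    def finish(self, t_end: float) -> None:
        """Close the session; accounts for a trailing abandoned shock cycle."""
        if self.schedule == "SHOCK" and self.counter == 4:
            self.abandoned_cycles += 1
            self.counter = 0
        if not self.terminated:
            self.terminated = True
            self.termination_reason = self.termination_reason or "duration"


def _finalise_log(engine: ScheduleEngine, rows: list[dict], t_end: float,
                  meta: dict) -> SessionLog:
    engine.finish(t_end)
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    meta = dict(meta)
    meta.update(
        n_pellets=engine.n_pellets,
        n_shocks=engine.n_shocks,
        termination=engine.termination_reason,
    )
    if engine.schedule == "SHOCK":
        meta["shock_intensity"] = defaults.SHOCK_INTENSITY
        meta["completed_cycles"] = engine.completed_cycles
        meta["abandoned_cycles"] = engine.abandoned_cycles
    return SessionLog(schedule=engine.schedule, duration_s=t_end,
                      events=events, meta=meta)


def replay_presses(schedule: str,
                   presses: Iterable[tuple[float, str]],
                   duration_s: float | None = None,
                   **engine_kwargs) -> SessionLog:
    """Deterministically replay an explicit press sequence.

    ``presses`` is an iterable of ``(time_s, lever)`` with non-decreasing
    times; presses beyond the session duration (or past PR termination)
    are ignored.
    """
    engine = ScheduleEngine(schedule, duration_s, **engine_kwargs)
    rows: list[dict] = []
    last_t = 0.0
    prev = -math.inf
    for t, lever in presses:
        if t < prev:
            raise ValueError("presses must be in non-decreasing time order")
        prev = t
        if engine.terminated or t > engine.duration_s:
            break
        if engine.schedule == "PR" and t - last_t > defaults.PR_GAP_S:
            engine.termination_reason = "response_gap"
            break
        rows.append(engine.press(t, lever))
        last_t = t
    if engine.schedule == "PR":
        if engine.termination_reason is None:
            engine.termination_reason = (
                "duration" if last_t + defaults.PR_GAP_S > engine.duration_s
                else "response_gap")
        t_end = min(engine.duration_s, last_t + defaults.PR_GAP_S)
    else:
        t_end = engine.duration_s
    return _finalise_log(engine, rows, t_end, {"replayed": True})


def _rates_per_s(agent: AgentParams, engine: ScheduleEngine,
                 t: float) -> tuple[float, float]:
    """Instantaneous active/inactive press rates (per second) at time t."""
    ra = agent.active_rate / 60.0
    ri = agent.inactive_rate / 60.0
    sched = engine.schedule
    period = engine.period_at(t)
    if sched in ("FR1", "FR5", "FR5_PELLET_FREE", "REVERSAL"):
        if period in ("pellet_free", "timeout"):
            ra *= agent.persistence_bias
        if sched == "REVERSAL":
            # previously-active lever: perseverative pressing
            ri = (agent.active_rate / 60.0) * agent.persistence_bias
    elif sched == "PR":
        if engine.current_requirement > agent.motivation_cap:
            ra = 0.0
        elif period == "timeout":
            ra *= agent.persistence_bias
    elif sched == "SHOCK":
        ra *= agent.punishment_sensitivity ** engine.n_shocks
        if period == "timeout":
            ra *= agent.persistence_bias
    elif sched == "CUE_PROBE":
        if t >= engine.cue_onset_s:
            # cue-primed food seeking
            ra *= 1.0 + agent.persistence_bias
    elif sched == "GRID_EXTINCTION":
        ra *= agent.persistence_bias * agent.punishment_sensitivity
    return ra, ri


def simulate_session(agent: AgentParams, schedule: str,
                     duration_s: float | None = None,
                     seed: int | np.random.Generator = 0) -> SessionLog:
    """Simulate one operant session for an agent under a named schedule.

    Responses on each lever form a Poisson process whose rate is piecewise
    constant in the schedule state (periods, shocks received, current PR
    requirement).  Identical ``(agent, schedule, seed)`` yield identical
    logs.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    engine = ScheduleEngine(schedule, duration_s)
    rows: list[dict] = []
    t = 0.0
    last_press = 0.0
    is_pr = engine.schedule == "PR"

    while not engine.terminated:
        ra, ri = _rates_per_s(agent, engine, t)
        total = ra + ri
        if total <= 0.0:
            t_next = math.inf
        else:
            t_next = t + rng.exponential(1.0 / total)
        boundary = engine.next_rate_boundary(t)

        if is_pr and t_next - last_press > defaults.PR_GAP_S:
            t_end = min(last_press + defaults.PR_GAP_S, engine.duration_s)
            engine.termination_reason = (
                "response_gap" if t_end < engine.duration_s else "duration")
            return _finalise_log(engine, rows, t_end,
                                 _sim_meta(agent, engine))
        if t_next >= boundary:
            if boundary >= engine.duration_s:
                break
            t = boundary  # rate context changes; redraw (memoryless)
            continue
        lever = "active" if (total > 0 and rng.random() < ra / total) else "inactive"
        rows.append(engine.press(t_next, lever))
        t = t_next
        last_press = t_next

    t_end = engine.duration_s if not is_pr else min(
        engine.duration_s,
        last_press + defaults.PR_GAP_S if engine.termination_reason == "response_gap"
        else (last_press if engine.termination_reason == "ladder_exhausted"
              else engine.duration_s))
    return _finalise_log(engine, rows, t_end, _sim_meta(agent, engine))


def _sim_meta(agent: AgentParams, engine: ScheduleEngine) -> dict:
    return {"phenotype": agent.phenotype_label, "schedule": engine.schedule}
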