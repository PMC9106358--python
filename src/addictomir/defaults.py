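"""Frozen defaults for schedules, cohort effect sizes, and analysis thresholds.

Effect sizes separating the vulnerable and resilient phenotypes were fixed
once by forward simulation so that a default 51-mouse cohort classifies
roughly a quarter of animals as addicted under the 75th-percentile / 2-of-3
rule; they are not meant to be tuned per run.
"""

# ---------------------------------------------------------------- schedules

#: Progressive-ratio response-requirement ladder (responses per pellet).
PR_LADDER: tuple[int, ...] = (
    1, 5, 12, 21, 33, 51, 75, 90, 120, 155, 180, 225, 260, 300, 350,
    410, 465, 540, 630, 730, 850, 1000, 1200, 1500, 1800, 2100, 2400,
    2700, 3000, 3400, 3800, 4200, 4600, 5000, 5500,
)

#: Default session durations, seconds.  PR carries its hard cap instead.
SESSION_DURATION_S: dict[str, float] = {
    "FR1": 3600.0,
    "FR5": 3600.0,
    "FR5_PELLET_FREE": 3600.0,
    "PR": 18000.0,          # 5-hour cap; stopping rules may end it earlier
    "SHOCK": 3000.0,        # 50-minute shock test
    "CUE_PROBE": 1200.0,
    "GRID_EXTINCTION": 900.0,
    "REVERSAL": 3600.0,
}

TIMEOUT_S = 10.0            # post-pellet time-out, no reinforcement
PELLET_FREE_LEN_S = 600.0   # signalled 10-min pellet-free window (end of session)
PR_GAP_S = 3600.0           # PR ends after 1 h without any lever response
SHOCK_RESET_S = 60.0        # cycle resets if the 5th response lags the 4th by >1 min
SHOCK_INTENSITY = "0.18 mA, 2 s"  # recorded as metadata only; no physical model
CUE_ONSET_FRACTION = 0.5    # non-contingent cue light at mid-session

# -------------------------------------------------- cohort (mouse) phenotypes

#: Per-phenotype agent parameter distributions: (mean, sd) of truncated
#: normals.  Rates are responses/min.
PHENOTYPE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "resilient": {
        "active_rate": (8.0, 1.5),
        "inactive_rate": (1.0, 0.3),
        "persistence_bias": (0.35, 0.10),
        "motivation_cap": (140.0, 60.0),
        "punishment_sensitivity": (0.70, 0.08),
    },
    "vulnerable": {
        "active_rate": (10.0, 1.5),
        "inactive_rate": (1.2, 0.3),
        "persistence_bias": (0.95, 0.20),
        "motivation_cap": (700.0, 250.0),
        "punishment_sensitivity": (0.93, 0.04),
    },
}

#: Default session plan: three FR5 sessions with the pellet-free window
#: (persistence), a PR session (motivation), the shock test (compulsion),
#: and one probe per phenotypic trait.
DEFAULT_SESSION_PLAN: tuple[str, ...] = (
    "FR5_PELLET_FREE", "FR5_PELLET_FREE", "FR5_PELLET_FREE",
    "PR", "SHOCK", "CUE_PROBE", "GRID_EXTINCTION", "REVERSAL",
)

DEFAULT_N_MICE = 51
DEFAULT_VULNERABLE_FRACTION = 0.25

# ------------------------------------------------------------ classification

CRITERION_QUANTILE = 0.75   # positivity threshold: above the 75th percentile
ADDICTED_MIN_CRITERIA = 2   # 2-of-3 rule
N_CRITERIA = 3
EXTREMES_PER_SIDE = 6       # discovery and replica subgroup size, per side
DSM5_SEVERE_MIN = 6         # DSM-5 severe: >= 6 of 11 criteria
DSM5_N_CRITERIA = 11

# ------------------------------------------------------------------ DE stage

DE_MIN_TOTAL = 10           # drop features with total count below this
DE_DISPERSION_FLOOR = 1e-4
DE_Q_CUTOFF = 0.05
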