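"""Synthetic human cohort: YFAS 2.0 item responses, BMI, sex, and circulating
miRNA levels with planted per-sex correlations.

Item responses are generated so that scoring them with the same
:class:`~addictomir.yfas.ItemMap` reproduces the assigned symptom count,
impairment flag and diagnosis exactly (a round-trip guarantee used by the
tests).  miRNA levels are built within each sex stratum as
``r * z(score) + sqrt(1 - r^2) * noise`` on the z-scored target score, so the
sample Pearson correlation converges to the planted value as n grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .yfas import IMPAIRMENT_CRITERION, ItemMap

#: Default planted (mirna, score column, sex) -> correlation, echoing a
#: male-specific negative signature and one female-specific positive one.
DEFAULT_PLANTED_CORRELATIONS: dict[tuple[str, str, str], float] = {
    ("mir_29c_3p", "persistence_sum", "male"): -0.6,
    ("mir_665_3p", "motivation_sum", "male"): -0.5,
    ("mir_192_5p", "reward_sensitivity", "female"): 0.5,
}


@dataclass
class HumanCohortSpec:
    """Human cohort design (defaults: 51 subjects, 12 with food addiction)."""

    n_subjects: int = 51
    n_addicted: int = 12
    male_fraction: float = 0.5
    planted_correlations: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_CORRELATIONS))
    bmi_addicted: tuple[float, float] = (31.0, 4.5)
    bmi_nonaddicted: tuple[float, float] = (25.0, 3.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_addicted > self.n_subjects:
            raise ValueError("requested addicted count exceeds n_subjects")
        for key, r in self.planted_correlations.items():
            if not (-1.0 <= r <= 1.0):
                raise ValueError(f"planted correlation {key} outside [-1, 1]")

    @property
    def mirna_columns(self) -> list[str]:
        return sorted({m for m, _, _ in self.planted_correlations})


def _assign_items(rng: np.random.Generator, item_map: ItemMap,
                  met_criteria: set[str], impairment: bool) -> dict[str, int]:
    """Item codes reproducing exactly the assigned criterion flags."""
    codes: dict[str, int] = {}
    for crit in item_map.criteria + [IMPAIRMENT_CRITERION]:
        items = item_map.items_for(crit)
        is_met = crit in met_criteria or (crit == IMPAIRMENT_CRITERION
                                          and impairment)
        for item in items:
            thr = item_map.items[item][1]
            codes[item] = int(rng.integers(0, thr))  # below threshold
        if is_met:
            hit = items[int(rng.integers(len(items)))]
            thr = item_map.items[hit][1]
            codes[hit] = int(rng.integers(thr, 8))
    return codes


def simulate_human(spec: HumanCohortSpec,
                   item_map: ItemMap | None = None) -> pd.DataFrame:
    """Generate the per-subject questionnaire / biomarker table.

    Columns: ``subject_id, sex, bmi, y1..y35, reward_sensitivity``, one
    column per simulated circulating miRNA, and the generator's latent
    assignment (``assigned_addicted``, ``assigned_symptom_count``).
    """
    item_map = item_map or ItemMap()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    addicted = np.zeros(n, bool)
    addicted[rng.choice(n, size=spec.n_addicted, replace=False)] = True
    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female")

    rows = []
    for i in range(n):
        if addicted[i]:
            count = int(rng.integers(2, 10))    # mild to severe
            impair = True
        else:
            count = int(rng.integers(0, 2))     # 0 or 1 symptom
            impair = bool(rng.random() < 0.3)
        met = set(rng.choice(item_map.criteria, size=count, replace=False))
        codes = _assign_items(rng, item_map, met, impair)
        mu_bmi, sd_bmi = (spec.bmi_addicted if addicted[i]
                          else spec.bmi_nonaddicted)
        rows.append({
            "subject_id": f"s{i + 1:04d}",
            "sex": sex[i],
            "bmi": float(np.clip(rng.normal(mu_bmi, sd_bmi), 16.0, None)),
            "assigned_addicted": bool(addicted[i]),
            "assigned_symptom_count": count,
            **codes,
        })
    table = pd.DataFrame(rows)

    # reward-sensitivity score: tracks addiction load plus noise
    load = table["assigned_symptom_count"].to_numpy(float)
    z_load = (load - load.mean()) / (load.std() or 1.0)
    table["reward_sensitivity"] = 8.0 + 2.5 * (
        0.6 * z_load + np.sqrt(1 - 0.6 ** 2) * rng.normal(size=n))

    # circulating miRNA levels with planted per-sex correlations
    from .yfas import score_table
    scored = score_table(table, item_map)
    for mirna in spec.mirna_columns:
        level = np.empty(n)
        for stratum in ("male", "female"):
            mask = (table["sex"] == stratum).to_numpy()
            eps = rng.normal(size=int(mask.sum()))
            planted = [(score, r) for (m, score, sx), r
                       in spec.planted_correlations.items()
                       if m == mirna and sx == stratum]
            total_r2 = sum(r * r for _, r in planted)
            if total_r2 > 1.0:
                raise ValueError(
                    f"planted correlations for {mirna}/{stratum} exceed unit variance")
            val = np.sqrt(1.0 - total_r2) * eps
            for score, r in planted:
                y = scored.loc[mask, score].to_numpy(float)
                sd = y.std()
                zy = (y - y.mean()) / sd if sd > 0 else np.zeros(mask.sum())
                val = val + r * zy
            level[mask] = val
        table[mirna] = level
    return table
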