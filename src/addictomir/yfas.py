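"""YFAS 2.0 scoring: symptom flags, diagnosis, severity, hallmark composites,
group comparisons, and correlations with circulating miRNA levels.

The 35-item instrument maps onto 11 DSM-5-style food-addiction criteria plus
a clinical-impairment indicator.  A criterion is met when any of its items
reaches that item's frequency-code threshold; diagnosis requires >= 2
criteria met together with impairment, and the severity bands are 2-3
criteria mild, 4-5 moderate, 6-11 severe.

The item -> criterion mapping and the grouping of criteria into the three
behavioural hallmarks (persistence of response, motivation, compulsion-like
behaviour) ship as an editable configuration.  The default mapping is a
synthetic reconstruction — a plausible assignment of 3 items per criterion
and of criteria to hallmarks — not the published scoring key; replace it via
:func:`ItemMap.from_yaml` to score real questionnaires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

ITEM_CODE_MAX = 7          # ordinal frequency codes 0..7
N_ITEMS = 35
N_SYMPTOM_CRITERIA = 11
MILD_RANGE = (2, 3)
MODERATE_RANGE = (4, 5)
SEVERE_RANGE = (6, 11)

HALLMARKS = ("persistence", "motivation", "compulsion", "other")

#: Default hallmark grouping of the 11 symptom criteria (a reconstruction).
DEFAULT_HALLMARK_MAP: dict[str, str] = {
    "C1": "motivation",    # larger amounts / longer than intended
    "C2": "persistence",   # persistent desire, unsuccessful cut-down
    "C3": "motivation",    # great deal of time spent
    "C4": "persistence",   # craving
    "C5": "other",         # failure to fulfil role obligations
    "C6": "compulsion",    # continued use despite social problems
    "C7": "other",         # activities given up
    "C8": "compulsion",    # use in physically hazardous situations
    "C9": "compulsion",    # continued use despite physical/psychological harm
    "C10": "motivation",   # tolerance
    "C11": "other",        # withdrawal
}

IMPAIRMENT_CRITERION = "IMPAIRMENT"


def _default_items() -> dict[str, tuple[str, int]]:
    """3 items per symptom criterion (y1..y33) + 2 impairment items."""
    mapping: dict[str, tuple[str, int]] = {}
    item = 1
    for c in range(1, N_SYMPTOM_CRITERIA + 1):
        for _ in range(3):
            mapping[f"y{item}"] = (f"C{c}", 4)  # met at frequency code >= 4
            item += 1
    mapping["y34"] = (IMPAIRMENT_CRITERION, 4)
    mapping["y35"] = (IMPAIRMENT_CRITERION, 4)
    return mapping


@dataclass
class ItemMap:
    """Item -> (criterion, threshold code) plus criterion -> hallmark maps."""

    items: dict[str, tuple[str, int]] = field(default_factory=_default_items)
    hallmarks: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_HALLMARK_MAP))

    def __post_init__(self) -> None:
        crits = {c for c, _ in self.items.values() if c != IMPAIRMENT_CRITERION}
        unassigned = crits - set(self.hallmarks)
        if unassigned:
            raise ValueError(f"criteria without hallmark: {sorted(unassigned)}")
        bad = set(self.hallmarks.values()) - set(HALLMARKS)
        if bad:
            raise ValueError(f"unknown hallmarks: {sorted(bad)}")

    @property
    def criteria(self) -> list[str]:
        seen: list[str] = []
        for c, _ in self.items.values():
            if c != IMPAIRMENT_CRITERION and c not in seen:
                seen.append(c)
        return seen

    def items_for(self, criterion: str) -> list[str]:
        return [i for i, (c, _) in self.items.items() if c == criterion]

    def hallmark_items(self, hallmark: str) -> list[str]:
        return [i for i, (c, _) in self.items.items()
                if c != IMPAIRMENT_CRITERION and self.hallmarks[c] == hallmark]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ItemMap":
        import yaml
        cfg = yaml.safe_load(Path(path).read_text())
        items = {k: (v["criterion"], int(v["threshold"]))
                 for k, v in cfg["items"].items()}
        return cls(items=items, hallmarks=dict(cfg["hallmarks"]))

    def to_yaml(self, path: str | Path) -> None:
        import yaml
        cfg = {
            "items": {k: {"criterion": c, "threshold": t}
                      for k, (c, t) in self.items.items()},
            "hallmarks": dict(self.hallmarks),
        }
        Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


@dataclass
class YFASScore:
    symptom_flags: dict[str, bool]
    symptom_count: int
    impairment: bool
    diagnosis: str                  # none | mild | moderate | severe
    persistence_sum: int
    motivation_sum: int
    compulsion_sum: int


def _diagnosis(symptom_count: int, impairment: bool) -> str:
    if symptom_count < MILD_RANGE[0] or not impairment:
        return "none"
    if symptom_count <= MILD_RANGE[1]:
        return "mild"
    if symptom_count <= MODERATE_RANGE[1]:
        return "moderate"
    return "severe"


def score_yfas(responses: pd.Series | dict, item_map: ItemMap | None = None
               ) -> YFASScore:
    """Score one subject's 35 ordinal item responses.

    A criterion flag is true when any of its items reaches the item's
    threshold code; hallmark composites are sums of the raw codes of the
    items mapped to that hallmark's criteria.  Missing items leave their
    criterion unscoreable (flag false).
    """
    item_map = item_map or ItemMap()
    resp = dict(responses)
    for item, code in resp.items():
        if item in item_map.items and not pd.isna(code):
            if not (0 <= code <= ITEM_CODE_MAX):
                raise ValueError(f"item {item} code {code} outside 0..{ITEM_CODE_MAX}")

    def met(item: str) -> bool:
        code = resp.get(item)
        if code is None or pd.isna(code):
            return False
        return code >= item_map.items[item][1]

    flags = {c: any(met(i) for i in item_map.items_for(c))
             for c in item_map.criteria}
    impairment = any(met(i) for i in item_map.items_for(IMPAIRMENT_CRITERION))
    count = sum(flags.values())

    def hsum(hallmark: str) -> int:
        return int(sum(resp.get(i, 0) or 0
                       for i in item_map.hallmark_items(hallmark)))

    return YFASScore(
        symptom_flags=flags,
        symptom_count=count,
        impairment=impairment,
        diagnosis=_diagnosis(count, impairment),
        persistence_sum=hsum("persistence"),
        motivation_sum=hsum("motivation"),
        compulsion_sum=hsum("compulsion"),
    )


def score_table(subjects: pd.DataFrame, item_map: ItemMap | None = None
                ) -> pd.DataFrame:
    """Score every subject; keeps non-item columns (sex, bmi, miRNAs...)."""
    item_map = item_map or ItemMap()
    item_cols = [c for c in subjects.columns if c in item_map.items]
    rows = []
    for _, row in subjects.iterrows():
        s = score_yfas(row[item_cols], item_map)
        rows.append({
            "symptom_count": s.symptom_count,
            "impairment": s.impairment,
            "diagnosis": s.diagnosis,
            "persistence_sum": s.persistence_sum,
            "motivation_sum": s.motivation_sum,
            "compulsion_sum": s.compulsion_sum,
        })
    scored = pd.DataFrame(rows, index=subjects.index)
    keep = [c for c in subjects.columns if c not in item_cols]
    return pd.concat([subjects[keep], scored], axis=1)


COMPOSITES = ("persistence_sum", "motivation_sum", "compulsion_sum")


def group_compare(scored: pd.DataFrame, sex_stratified: bool = False
                  ) -> pd.DataFrame:
    """Mann-Whitney U (two-sided, normal approximation with tie correction)
    of each hallmark composite between diagnosed and undiagnosed subjects."""
    scored = scored.copy()
    scored["group"] = np.where(scored["diagnosis"] == "none",
                               "nonaddicted", "addicted")
    strata = (sorted(scored["sex"].unique()) if sex_stratified else ["all"])
    rows = []
    for stratum in strata:
        sub = scored if stratum == "all" else scored[scored["sex"] == stratum]
        g1 = sub[sub["group"] == "addicted"]
        g0 = sub[sub["group"] == "nonaddicted"]
        if len(g1) < 2 or len(g0) < 2:
            raise ValueError(f"need >= 2 subjects per group in stratum {stratum!r}")
        for comp in COMPOSITES:
            u, p = stats.mannwhitneyu(g1[comp], g0[comp],
                                      alternative="two-sided",
                                      method="asymptotic")
            rows.append({"stratum": stratum, "composite": comp,
                         "n_addicted": len(g1), "n_nonaddicted": len(g0),
                         "u_stat": float(u), "pvalue": float(p)})
    return pd.DataFrame(rows)


def mirna_correlations(scored: pd.DataFrame, mirna_cols: list[str],
                       score_cols: list[str], sex_stratified: bool = True
                       ) -> pd.DataFrame:
    """Pearson r (t-based two-sided p) per (miRNA, score, stratum).

    Constant columns within a stratum yield an explicit invalid row
    (``valid=False``) rather than propagating NaN.
    """
    from .de import bh_fdr

    strata = sorted(scored["sex"].unique()) if sex_stratified else ["all"]
    rows = []
    for stratum in strata:
        sub = scored if stratum == "all" else scored[scored["sex"] == stratum]
        for mirna in mirna_cols:
            for score in score_cols:
                pair = sub[[mirna, score]].dropna()
                if len(pair) < 3:
                    raise ValueError(
                        f"fewer than 3 paired observations in stratum {stratum!r}")
                x, y = pair[mirna].to_numpy(), pair[score].to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    rows.append({"mirna": mirna, "score": score,
                                 "stratum": stratum, "n": len(pair),
                                 "r": np.nan, "pvalue": np.nan,
                                 "valid": False})
                    continue
                r, p = stats.pearsonr(x, y)
                rows.append({"mirna": mirna, "score": score,
                             "stratum": stratum, "n": len(pair),
                             "r": float(r), "pvalue": float(p),
                             "valid": True})
    out = pd.DataFrame(rows)
    qs = np.full(len(out), np.nan)
    ok = out["valid"].to_numpy()
    if ok.any():
        qs[ok] = bh_fdr(out.loc[ok, "pvalue"].to_numpy())
    out["qvalue"] = qs
    return out
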