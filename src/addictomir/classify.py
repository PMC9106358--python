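"""Percentile-threshold addiction classification, severity scale, extreme
subgroup selection, PCA profile, and group χ² comparison.

A mouse is positive for a criterion when its score lies strictly above the
cohort's 75th percentile of that criterion; animals positive on at least
2 of the 3 criteria are classified addicted (the 2-of-3 ≈ 66% rule, the
analogue of the DSM-5 severe threshold of 6 of 11 ≈ 55%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import defaults

logger = logging.getLogger(__name__)

CRITERIA = ("persistence", "breaking_point", "shocks")
TRAITS = ("impulsivity", "flexibility_errors",
          "appetitive_reactivity", "aversive_reactivity")

#: 2-of-3 addiction rule and its DSM-5 analogue, as fractions of criteria.
ADDICTION_RULE = (defaults.ADDICTED_MIN_CRITERIA, defaults.N_CRITERIA)
DSM5_SEVERE_RULE = (defaults.DSM5_SEVERE_MIN, defaults.DSM5_N_CRITERIA)


@dataclass
class PCAProfile:
    loadings: pd.DataFrame          # variables x components, unit-norm columns
    variance_explained: np.ndarray  # percent, non-increasing
    high_loading: pd.DataFrame      # |loading| > 0.7 flags


def criterion_thresholds(scores: pd.DataFrame,
                         q: float = defaults.CRITERION_QUANTILE) -> pd.Series:
    """Per-criterion cohort quantile (linear interpolation between order stats).

    Thresholds must be computed on the palatable-food-trained reference
    cohort; positivity downstream uses a strict ``>`` comparison.
    """
    if len(scores) < 4:
        raise ValueError("need at least 4 mice to set percentile thresholds")
    cols = [c for c in CRITERIA if c in scores.columns]
    if len(cols) != len(CRITERIA):
        raise ValueError(f"scores table must contain columns {CRITERIA}")
    vals = scores[list(CRITERIA)]
    if not np.issubdtype(vals.values.dtype, np.number) or vals.isna().any().any():
        raise ValueError("criterion scores must be numeric and complete")
    return vals.quantile(q, interpolation="linear")


def classify_cohort(scores: pd.DataFrame,
                    thresholds: pd.Series) -> pd.DataFrame:
    """Apply per-criterion strict thresholds and the 2-of-3 addiction rule.

    Returns the scores table extended with per-criterion positivity,
    ``n_criteria`` and ``label``. Mice with a missing criterion value are
    excluded with a logged reason.
    """
    out = scores.copy()
    missing = out[list(CRITERIA)].isna().any(axis=1)
    if missing.any():
        for mid in out.loc[missing, "mouse_id"]:
            logger.warning("mouse %s excluded: missing criterion value", mid)
        out = out[~missing].copy()
    for c in CRITERIA:
        out[f"{c}_positive"] = out[c] > thresholds[c]
    out["n_criteria"] = sum(out[f"{c}_positive"].astype(int) for c in CRITERIA)
    out["label"] = np.where(out["n_criteria"] >= defaults.ADDICTED_MIN_CRITERIA,
                            "addicted", "nonaddicted")
    return out


def severity_scores(classified: pd.DataFrame) -> pd.Series:
    """Severity in [0, 1]: mean fractional rank of the three criterion scores.

    Monotone non-decreasing in each criterion; a mouse at the cohort median
    of all three criteria scores ~0.5.
    """
    n = len(classified)
    if n < 2:
        return pd.Series(0.5, index=classified.index)
    ranks = [
        (stats.rankdata(classified[c], method="average") - 1) / (n - 1)
        for c in CRITERIA
    ]
    return pd.Series(np.mean(ranks, axis=0), index=classified.index)


def severity_and_extremes(classified: pd.DataFrame,
                          k: int = defaults.EXTREMES_PER_SIDE) -> pd.DataFrame:
    """Attach severity and pick discovery/replica extremes per side.

    The vulnerable side takes the highest-severity addicted mice, the
    resilient side the lowest-severity nonaddicted mice; discovery takes the
    k most extreme animals per side, replica the next k. Ties are broken by
    (persistence, breaking_point, shocks), then mouse id.
    """
    out = classified.copy()
    out["severity"] = severity_scores(out)
    out["extreme_set"] = "none"
    out["extreme_side"] = "none"

    def assign(side_mask: np.ndarray, side: str, ascending: bool) -> None:
        side_df = out[side_mask].sort_values(
            by=["severity", *CRITERIA, "mouse_id"],
            ascending=[ascending] * 4 + [True],
        )
        if len(side_df) < 2 * k:
            logger.warning("only %d %s mice for 2x%d extremes; sets truncated",
                           len(side_df), side, k)
        disc = side_df.index[:k]
        repl = side_df.index[k:2 * k]
        out.loc[disc, "extreme_set"] = "discovery"
        out.loc[repl, "extreme_set"] = "replica"
        out.loc[list(disc) + list(repl), "extreme_side"] = side

    assign((out["label"] == "addicted").to_numpy(), "vulnerable", ascending=False)
    assign((out["label"] == "nonaddicted").to_numpy(), "resilient", ascending=True)
    return out


def pca_profile(features: pd.DataFrame) -> PCAProfile:
    """PCA of the standardized criteria + traits (correlation structure).

    Variables are z-scored (criteria and traits have incommensurate units);
    loading columns are the unit-norm principal axes; variables with
    |loading| > 0.7 are flagged as main contributors.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    cols = [c for c in (*CRITERIA, *TRAITS) if c in features.columns]
    X = features[cols].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 mice")
    if np.isnan(X).any():
        raise ValueError("PCA input must have no missing values")
    keep = [i for i in range(X.shape[1]) if X[:, i].std() > 0]
    if len(keep) < len(cols):
        dropped = [cols[i] for i in range(len(cols)) if i not in keep]
        logger.warning("dropping zero-variance features: %s", dropped)
    cols = [cols[i] for i in keep]
    X = StandardScaler().fit_transform(X[:, keep])
    pca = PCA()
    pca.fit(X)
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    loadings = pd.DataFrame(pca.components_.T, index=cols, columns=comp_names)
    var_pct = pca.explained_variance_ratio_ * 100.0
    return PCAProfile(
        loadings=loadings,
        variance_explained=var_pct,
        high_loading=loadings.abs() > 0.7,
    )


def group_chi2(table: np.ndarray | pd.DataFrame,
               yates: bool = False) -> tuple[float, float]:
    """Pearson χ² (df=1) for a 2x2 addicted/nonaddicted × group table.

    Continuity correction off by default; pass ``yates=True`` to enable it.
    A zero row or column margin makes the statistic undefined.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table entries must be non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("χ² undefined: a table margin is zero")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=yates)
    assert dof == 1
    return float(chi2), float(p)
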