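"""Count normalization, negative-binomial two-group tests, and BH FDR.

This module is self-contained on purpose: the NB Wald test (with a
label-permutation alternative) is the package's own differential-expression
engine rather than a wrapper around an external tool.

Model
-----
Counts are modelled as NB(mu_ij, alpha_i) with Var = mu + alpha * mu^2 and
mu_ij = s_j * q_i * 2^(beta_i * x_j), where s_j are median-of-ratios size
factors and x_j indicates the vulnerable group.  Dispersion is estimated per
feature by a pooled within-group method of moments with a floor; the Wald
statistic on the group log-fold-change is referred to a t distribution with
n1 + n2 - 2 degrees of freedom, which calibrates the test at small group
sizes where dispersion estimates are noisy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import defaults

GROUPS = ("resilient", "vulnerable")  # contrast: vulnerable vs resilient

_PSEUDO = 0.5  # pseudo-count on normalized group means for the log ratio


@dataclass
class CountMatrix:
    """Feature x sample integer counts with per-sample group labels."""

    counts: pd.DataFrame            # features as rows, sample ids as columns
    groups: pd.Series               # sample id -> group label

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("feature ids must be unique")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.counts.columns)]


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample normalization factors.

    ``factor_j = median_i(count_ij / geometric_mean_i)`` over features with
    all-positive counts, rescaled so the factors have geometric mean 1.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a features x samples matrix with >= 2 samples")
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has positive counts in every sample")
    logs = np.log(arr[positive])
    log_gm = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_gm, axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone in p-rank)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def _mom_dispersion(yn: np.ndarray, masks: list[np.ndarray],
                    inv_sf_means: list[float],
                    floor: float) -> np.ndarray:
    """Pooled within-group method-of-moments dispersion on normalized counts.

    For y/s, Var = mu * E[1/s] + alpha * mu^2, so
    alpha_hat = (var - mean * E[1/s]) / mean^2, pooled across groups with
    (n_g - 1) weights and floored.
    """
    num = np.zeros(yn.shape[0])
    den = 0.0
    for mask, xi in zip(masks, inv_sf_means):
        g = yn[:, mask]
        m = g.mean(axis=1)
        v = g.var(axis=1, ddof=1)
        a = (v - m * xi) / np.maximum(m, 1e-12) ** 2
        w = mask.sum() - 1
        num += a * w
        den += w
    return np.maximum(num / den, floor)


def _wald_table(yn: np.ndarray, masks: list[np.ndarray],
                inv_sf_means: list[float],
                dispersion_floor: float) -> tuple[np.ndarray, ...]:
    m_res = yn[:, masks[0]].mean(axis=1)
    m_vul = yn[:, masks[1]].mean(axis=1)
    alpha = _mom_dispersion(yn, masks, inv_sf_means, dispersion_floor)
    n0, n1 = masks[0].sum(), masks[1].sum()
    lfc_ln = np.log(m_vul + _PSEUDO) - np.log(m_res + _PSEUDO)
    var = ((inv_sf_means[0] / (m_res + _PSEUDO) + alpha) / n0
           + (inv_sf_means[1] / (m_vul + _PSEUDO) + alpha) / n1)
    z = lfc_ln / np.sqrt(var)
    return m_res, m_vul, alpha, lfc_ln / np.log(2.0), z


def nb_test(counts: CountMatrix,
            min_total: int = defaults.DE_MIN_TOTAL,
            mode: str = "wald",
            n_perm: int = 500,
            seed: int = 0,
            dispersion_floor: float = defaults.DE_DISPERSION_FLOOR) -> pd.DataFrame:
    """Two-group NB differential expression (vulnerable vs resilient).

    Features with total count below ``min_total`` are removed before
    testing.  ``mode='wald'`` refers the Wald statistic to t(n1+n2-2);
    ``mode='perm'`` derives the p-value from ``n_perm`` random label
    permutations of the same statistic.

    Returns a DataFrame with columns ``feature, base_mean, log2fc,
    dispersion, stat, pvalue, qvalue, direction``.
    """
    groups = counts.groups
    masks = [np.asarray(groups == g) for g in GROUPS]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("both groups need at least 2 samples")
    if mode not in ("wald", "perm"):
        raise ValueError("mode must be 'wald' or 'perm'")

    mat = counts.counts
    keep = mat.sum(axis=1) >= min_total
    mat = mat.loc[keep]
    arr = mat.to_numpy(dtype=float)
    sf = size_factors(arr)
    yn = arr / sf
    xis = [float(np.mean(1.0 / sf[m])) for m in masks]

    m_res, m_vul, alpha, log2fc, z = _wald_table(yn, masks, xis,
                                                 dispersion_floor)
    df_t = int(masks[0].sum() + masks[1].sum() - 2)
    if mode == "wald":
        pvals = 2.0 * stats.t.sf(np.abs(z), df_t)
    else:
        rng = np.random.default_rng(seed)
        n_samples = yn.shape[1]
        exceed = np.ones(yn.shape[0])
        for _ in range(n_perm):
            perm = rng.permutation(n_samples)
            pmasks = [np.zeros(n_samples, bool), np.zeros(n_samples, bool)]
            pmasks[0][perm[:masks[0].sum()]] = True
            pmasks[1][~pmasks[0]] = True
            _, _, _, _, zp = _wald_table(yn, pmasks, [
                float(np.mean(1.0 / sf[m])) for m in pmasks], dispersion_floor)
            exceed += np.abs(zp) >= np.abs(z)
        pvals = exceed / (n_perm + 1)
    pvals = np.clip(pvals, 0.0, 1.0)

    out = pd.DataFrame({
        "feature": mat.index,
        "base_mean": yn.mean(axis=1),
        "log2fc": log2fc,
        "dispersion": alpha,
        "stat": z,
        "pvalue": pvals,
        "qvalue": bh_fdr(pvals),
        "direction": np.where(log2fc >= 0, "up", "down"),
    }).set_index("feature", drop=False)
    out.index.name = None
    return out


def significant_features(de: pd.DataFrame,
                         q_cutoff: float = defaults.DE_Q_CUTOFF,
                         direction: str | None = None,
                         use_nominal_p: bool = False) -> set[str]:
    """Feature ids significant at the q (or nominal p) cutoff, by direction."""
    col = "pvalue" if use_nominal_p else "qvalue"
    mask = de[col] < q_cutoff
    if direction is not None:
        mask &= de["direction"] == direction
    return set(de.loc[mask, "feature"])
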