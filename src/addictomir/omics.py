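"""Synthetic miRNA / mRNA count matrices with planted group effects.

Counts are drawn directly as negative-binomial integers with
``mean = baseline * library_factor * 2^(lfc * group)`` and a common
dispersion; each planted miRNA's target genes receive an opposite-sign mean
shift scaled by the coupling coefficient (miRNA down => targets up), which
is the sign convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import CountMatrix
from .setstats import TargetSetDB

#: Default planted miRNA effects: 9 down- and 2 up-regulated in the
#: vulnerable group, log2 fold change magnitude 1.
DEFAULT_PLANTED: tuple[tuple[str, float], ...] = tuple(
    [(f"mir-d{i + 1:02d}", -1.0) for i in range(9)]
    + [(f"mir-u{i + 1:02d}", 1.0) for i in range(2)]
)


@dataclass
class OmicsSpec:
    """Design of the synthetic omics experiment (defaults: 6 vs 6 groups)."""

    n_features_mirna: int = 400
    n_features_mrna: int = 2000
    group_size: int = 6
    planted: tuple[tuple[str, float], ...] = DEFAULT_PLANTED
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.7, 1.3)
    #: Fraction of the regulating miRNA's |lfc| transferred (opposite sign)
    #: to each of its target genes.
    coupling: float = 0.7
    targets_per_mirna: int = 40
    #: Decoy miRNAs (unplanted) that also get target sets, for enrichment nulls.
    n_decoy_target_sets: int = 20
    baseline_log_mean: float = 4.5
    baseline_log_sd: float = 1.2
    planted_log_mean: float = 5.5
    planted_log_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.group_size < 2:
            raise ValueError("group sizes must be >= 2")
        names = [n for n, _ in self.planted]
        if len(names) != len(set(names)):
            raise ValueError("planted feature ids must be unique")
        if self.targets_per_mirna > self.n_features_mrna:
            raise ValueError("targets_per_mirna exceeds the mRNA pool")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             alpha: float) -> np.ndarray:
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def _sample_frame(rng: np.random.Generator, baselines: np.ndarray,
                  lfc: np.ndarray, features: list[str],
                  sample_ids: list[str], groups: np.ndarray,
                  spec: OmicsSpec) -> pd.DataFrame:
    lib = rng.uniform(*spec.library_size_range, size=len(sample_ids))
    mu = baselines[:, None] * lib[None, :]
    mu = mu * np.power(2.0, lfc[:, None] * groups[None, :])
    counts = _nb_draw(rng, mu, spec.dispersion)
    return pd.DataFrame(counts, index=features, columns=sample_ids)


def simulate_counts(spec: OmicsSpec, labels: pd.DataFrame
                    ) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, TargetSetDB]:
    """Generate miRNA and mRNA count matrices for labelled samples.

    ``labels`` needs columns ``sample_id`` and ``group`` with groups
    'vulnerable' / 'resilient' (>= 2 samples each, typically the extreme
    subgroups).  Returns ``(mirna, mrna, truth, target_db)`` where ``truth``
    lists every feature's true log2 fold change and planted flag.
    """
    for g in ("vulnerable", "resilient"):
        if (labels["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
    rng = np.random.default_rng(spec.seed)
    sample_ids = list(labels["sample_id"])
    grp = (labels["group"] == "vulnerable").to_numpy().astype(float)

    # ---- miRNA panel
    n_planted = len(spec.planted)
    mirna_ids = [n for n, _ in spec.planted] + [
        f"mir-bg{i + 1:04d}" for i in range(spec.n_features_mirna - n_planted)]
    mirna_base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd,
                               spec.n_features_mirna)
    mirna_base[:n_planted] = rng.lognormal(spec.planted_log_mean,
                                           spec.planted_log_sd, n_planted)
    mirna_lfc = np.zeros(spec.n_features_mirna)
    mirna_lfc[:n_planted] = [lfc for _, lfc in spec.planted]

    # ---- mRNA pool and target coupling
    gene_ids = [f"gene{i + 1:05d}" for i in range(spec.n_features_mrna)]
    mrna_base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd,
                              spec.n_features_mrna)
    mrna_lfc = np.zeros(spec.n_features_mrna)
    sets: dict[str, set[str]] = {}
    set_owners = mirna_ids[:n_planted] + [
        f"mir-bg{i + 1:04d}" for i in range(spec.n_decoy_target_sets)]
    for mirna in set_owners:
        idx = rng.choice(spec.n_features_mrna, size=spec.targets_per_mirna,
                         replace=False)
        sets[mirna] = {gene_ids[i] for i in idx}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for (mirna, lfc) in spec.planted:
        for gene in sets[mirna]:
            mrna_lfc[gene_index[gene]] += -spec.coupling * lfc  # opposite sign
    target_db = TargetSetDB(sets=sets, universe=set(gene_ids))

    mirna_counts = _sample_frame(rng, mirna_base, mirna_lfc, mirna_ids,
                                 sample_ids, grp, spec)
    mrna_counts = _sample_frame(rng, mrna_base, mrna_lfc, gene_ids,
                                sample_ids, grp, spec)
    groups = pd.Series(labels["group"].to_numpy(), index=sample_ids)

    truth = pd.DataFrame({
        "feature": mirna_ids + gene_ids,
        "kind": ["mirna"] * len(mirna_ids) + ["mrna"] * len(gene_ids),
        "log2fc": np.concatenate([mirna_lfc, mrna_lfc]),
    })
    truth["planted"] = truth["log2fc"] != 0.0
    return (CountMatrix(mirna_counts, groups.copy()),
            CountMatrix(mrna_counts, groups.copy()),
            truth, target_db)
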