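"""End-to-end orchestration: simulate -> score -> classify -> DE -> enrichment
(mouse arm) and simulate -> YFAS scoring -> correlations (human arm).

One global seed derives per-stage seeds by stable hashing of stage names, so
adding a stage never shifts the randomness of earlier stages; re-running a
config reproduces byte-identical outputs and manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, classify, defaults
from .cohort import CohortSpec, simulate_cohort
from .de import nb_test, significant_features
from .humans import HumanCohortSpec, simulate_human
from .io import (sha256_file, write_cohort, write_counts, write_json)
from .omics import OmicsSpec, simulate_counts
from .setstats import export_network, replication_overlap, target_enrichment, write_gmt
from .yfas import ItemMap, group_compare, mirna_correlations, score_table

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/run0"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    omics: OmicsSpec = field(default_factory=OmicsSpec)
    human: HumanCohortSpec = field(default_factory=HumanCohortSpec)
    q_quantile: float = defaults.CRITERION_QUANTILE
    extremes_k: int = defaults.EXTREMES_PER_SIDE
    de_q_cutoff: float = defaults.DE_Q_CUTOFF

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("seed", "out_dir", "q_quantile", "extremes_k",
                    "de_q_cutoff"):
            if key in raw:
                kwargs[key] = raw[key]
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "session_plan" in c:
                c["session_plan"] = tuple(c["session_plan"])
            kwargs["cohort"] = CohortSpec(**c)
        if "omics" in raw:
            o = dict(raw["omics"])
            if "planted" in o:
                o["planted"] = tuple((str(n), float(l)) for n, l in o["planted"])
            kwargs["omics"] = OmicsSpec(**o)
        if "human" in raw:
            h = dict(raw["human"])
            if "planted_correlations" in h:
                h["planted_correlations"] = {
                    (d["mirna"], d["score"], d["sex"]): float(d["r"])
                    for d in h["planted_correlations"]}
            kwargs["human"] = HumanCohortSpec(**h)
        return cls(**kwargs)


class _Manifest:
    def __init__(self, cfg: RunConfig, arm: str):
        import addictomir
        self.data = {
            "arm": arm,
            "seed": cfg.seed,
            "config": _config_dict(cfg),
            "versions": {
                "addictomir": addictomir.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "stage_seeds": {},
            "files": {},
            "warnings": [],
        }
        self.timings: list[str] = []
        self._t0 = time.time()

    def stage(self, name: str) -> None:
        self.timings.append(f"{name}\t{time.time() - self._t0:.3f}s")
        self._t0 = time.time()

    def add_files(self, outdir: Path, *paths: Path) -> None:
        for p in paths:
            self.data["files"][str(p.relative_to(outdir))] = sha256_file(p)

    def write(self, outdir: Path) -> Path:
        path = outdir / "manifest.json"
        write_json(self.data, path)
        (outdir / "run.log").write_text("\n".join(self.timings) + "\n")
        return path


def _config_dict(cfg: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj
    return clean(cfg)


def run_mouse_pipeline(cfg: RunConfig) -> dict:
    """Cohort logs -> scores -> classification -> DE (discovery + replica)
    -> replication overlap -> target enrichment -> network export."""
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    man = _Manifest(cfg, "mouse")

    # 1. behavioural cohort
    cohort_spec = dataclasses.replace(cfg.cohort,
                                      seed=stage_seed(cfg.seed, "cohort"))
    man.data["stage_seeds"]["cohort"] = cohort_spec.seed
    logs, labels = simulate_cohort(cohort_spec)
    write_cohort(logs, labels, outdir)
    man.stage("simulate_cohort")

    # 2. scores
    scores = behavior.score_cohort(logs)
    scores.to_csv(outdir / "scores.csv", index=False)
    man.stage("score")

    # 3. classification, severity, extremes, PCA
    thresholds = classify.criterion_thresholds(scores, cfg.q_quantile)
    classified = classify.classify_cohort(scores, thresholds)
    classified = classify.severity_and_extremes(classified, cfg.extremes_k)
    classified.to_csv(outdir / "classification.csv", index=False)
    pca = classify.pca_profile(classified)
    pca.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
    pd.DataFrame({"component": pca.loadings.columns,
                  "variance_pct": pca.variance_explained}
                 ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
    man.stage("classify")

    # 4. extreme-set sample tables
    report: dict = {"n_mice": len(scores),
                    "n_addicted": int((classified["label"] == "addicted").sum())}
    de_outputs: dict[str, dict] = {}
    for sample in ("discovery", "replica"):
        sub = classified[classified["extreme_set"] == sample]
        lab = pd.DataFrame({
            "sample_id": sub["mouse_id"],
            "group": np.where(sub["extreme_side"] == "vulnerable",
                              "vulnerable", "resilient"),
        })
        if ((lab["group"] == "vulnerable").sum() < 2
                or (lab["group"] == "resilient").sum() < 2):
            msg = (f"{sample} extreme set incomplete "
                   f"({len(lab)} mice); omics stages skipped")
            logger.warning(msg)
            man.data["warnings"].append(msg)
            continue
        omics_spec = dataclasses.replace(
            cfg.omics, seed=stage_seed(cfg.seed, f"counts_{sample}"))
        man.data["stage_seeds"][f"counts_{sample}"] = omics_spec.seed
        mirna, mrna, truth, target_db = simulate_counts(omics_spec, lab)
        write_counts(mirna, outdir / f"mirna_counts_{sample}.tsv",
                     outdir / f"samples_{sample}.csv")
        write_counts(mrna, outdir / f"mrna_counts_{sample}.tsv",
                     outdir / f"samples_{sample}_mrna.csv")
        if sample == "discovery":
            truth.to_csv(outdir / "omics_truth.csv", index=False)
            write_gmt(target_db, outdir / "targets.gmt")
        de_mirna = nb_test(mirna, defaults.DE_MIN_TOTAL)
        de_mirna.to_csv(outdir / f"de_mirna_{sample}.tsv", sep="\t",
                        index=False)
        de_outputs[sample] = {"de_mirna": de_mirna, "mrna": mrna,
                              "target_db": target_db}
    man.stage("omics")

    # 5. replication overlap + target enrichment + network
    if set(de_outputs) == {"discovery", "replica"}:
        tests, replicated = replication_overlap(
            de_outputs["discovery"]["de_mirna"],
            de_outputs["replica"]["de_mirna"], cfg.de_q_cutoff)
        rep_rows = [{"direction": d, "overlap": t.overlap,
                     "n_discovery": t.set_size, "n_replica": t.selected_size,
                     "universe": t.universe_size, "pvalue": t.pvalue,
                     "odds_ratio": t.odds_ratio} for d, t in tests.items()]
        pd.DataFrame(rep_rows).to_csv(outdir / "replication.tsv", sep="\t",
                                      index=False)
        report["replicated_down"] = sorted(replicated["down"])
        report["replicated_up"] = sorted(replicated["up"])

        de_mrna = nb_test(de_outputs["discovery"]["mrna"], defaults.DE_MIN_TOTAL)
        de_mrna.to_csv(outdir / "de_mrna_discovery.tsv", sep="\t", index=False)
        universe = set(de_mrna["feature"])
        de_genes = significant_features(de_mrna, cfg.de_q_cutoff)
        target_db = de_outputs["discovery"]["target_db"]
        enr = target_enrichment(de_genes, _restrict_db(target_db, universe),
                                universe)
        enr.to_csv(outdir / "target_enrichment.tsv", sep="\t", index=False)
        edges, degrees = export_network(set(replicated["down"]),
                                        _restrict_db(target_db, universe),
                                        de_genes)
        edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        degrees.to_csv(outdir / "network_degrees.tsv", sep="\t", index=False)
    man.stage("setstats")

    man.add_files(outdir, *sorted(p for p in outdir.rglob("*")
                                  if p.is_file() and p.name not in
                                  ("manifest.json", "run.log")))
    man.data["report"] = report
    man.write(outdir)
    report["manifest"] = str(outdir / "manifest.json")
    return report


def _restrict_db(db, universe: set[str]):
    from .setstats import TargetSetDB
    return TargetSetDB(sets={m: s & universe for m, s in db.sets.items()},
                       universe=set(universe))


def run_human_pipeline(cfg: RunConfig) -> dict:
    """Synthetic subjects -> YFAS scores -> group tests -> correlations."""
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    man = _Manifest(cfg, "human")
    item_map = ItemMap()

    human_spec = dataclasses.replace(cfg.human,
                                     seed=stage_seed(cfg.seed, "human"))
    man.data["stage_seeds"]["human"] = human_spec.seed
    subjects = simulate_human(human_spec, item_map)
    subjects.to_csv(outdir / "subjects.csv", index=False)
    item_map.to_yaml(outdir / "yfas_map.yaml")
    man.stage("simulate_human")

    scored = score_table(subjects, item_map)
    scored.to_csv(outdir / "yfas_scores.csv", index=False)
    report: dict = {
        "n_subjects": len(scored),
        "n_diagnosed": int((scored["diagnosis"] != "none").sum()),
    }
    man.stage("score")

    try:
        comp = group_compare(scored, sex_stratified=False)
        comp.to_csv(outdir / "group_comparison.tsv", sep="\t", index=False)
    except ValueError as exc:
        msg = f"group comparison skipped: {exc}"
        logger.warning(msg)
        man.data["warnings"].append(msg)
    score_cols = ["persistence_sum", "motivation_sum", "compulsion_sum",
                  "reward_sensitivity", "symptom_count", "bmi"]
    try:
        corr = mirna_correlations(scored, human_spec.mirna_columns,
                                  score_cols, sex_stratified=True)
        corr.to_csv(outdir / "mirna_correlations.tsv", sep="\t", index=False)
        report["correlations"] = "mirna_correlations.tsv"
    except ValueError as exc:
        msg = f"stratified correlations skipped: insufficient n ({exc})"
        logger.warning(msg)
        man.data["warnings"].append(msg)
        report["correlations"] = None
    man.stage("associations")

    man.add_files(outdir, *sorted(p for p in outdir.rglob("*")
                                  if p.is_file() and p.name not in
                                  ("manifest.json", "run.log")))
    man.data["report"] = report
    man.write(outdir)
    report["manifest"] = str(outdir / "manifest.json")
    return report
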