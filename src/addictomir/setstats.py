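"""Discovery/replica replication overlap and miRNA-target enrichment.

All tests are one-sided upper-tail hypergeometric probabilities of observing
at least the seen overlap given the set sizes and a finite universe; the
universe is always the set of features actually testable (tested in both
samples for replication, the expressed background for target enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import defaults
from .de import bh_fdr, significant_features


@dataclass
class TargetSetDB:
    """miRNA id -> set of target gene ids, within a gene universe."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(not name for name in self.sets):
            raise ValueError("empty set ids are not allowed")
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, genes in self.sets.items():
            if not genes <= self.universe:
                raise ValueError(f"target set {name!r} not within the universe")


@dataclass
class EnrichmentResult:
    name: str
    overlap: int          # k
    set_size: int         # m
    selected_size: int    # s
    universe_size: int    # N
    pvalue: float
    odds_ratio: float
    qvalue: float = float("nan")


def read_gmt(path: str | Path) -> TargetSetDB:
    """Read a GMT-dialect file: ``id<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return TargetSetDB(sets=sets)


def write_gmt(db: TargetSetDB, path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name in sorted(db.sets):
        desc = (descriptions or {}).get(name, "targets")
        lines.append("\t".join([name, desc, *sorted(db.sets[name])]))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_overlap(set_a: set, set_b: set, universe: set,
                      name: str = "overlap") -> EnrichmentResult:
    """Upper-tail hypergeometric p for observing >= |A ∩ B| elements.

    Draws of size |B| from a universe of size N containing |A| marked
    elements; p = P(X >= k).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("both sets must be subsets of the universe")
    N, m, s = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, N, m, s))
    # odds ratio of the 2x2 partition (Haldane 0.5 correction on zeros)
    a, b = k, m - k
    c, d = s - k, N - m - s + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return EnrichmentResult(name=name, overlap=k, set_size=m,
                            selected_size=s, universe_size=N,
                            pvalue=min(p, 1.0), odds_ratio=float(odds))


def replication_overlap(de_discovery: pd.DataFrame,
                        de_replica: pd.DataFrame,
                        q_cutoff: float = defaults.DE_Q_CUTOFF,
                        direction_consistent: bool = True,
                        use_nominal_p: bool = False,
                        ) -> tuple[dict[str, EnrichmentResult], dict[str, set[str]]]:
    """Per-direction overlap test between discovery and replica signatures.

    Significant sets (q < cutoff by default) are split by fold-change
    direction and their overlap is tested against the universe of features
    tested in both samples.  Returns ``(tests, replicated)`` where
    ``replicated`` maps direction -> features significant in both samples
    with a consistent direction (the replicated signature).
    """
    universe = set(de_discovery["feature"]) & set(de_replica["feature"])
    if not universe:
        raise ValueError("no features tested in both samples")
    tests: dict[str, EnrichmentResult] = {}
    replicated: dict[str, set[str]] = {}
    for direction in ("down", "up"):
        d_dir = direction if direction_consistent else None
        sig_d = significant_features(de_discovery, q_cutoff, d_dir,
                                     use_nominal_p) & universe
        sig_r = significant_features(de_replica, q_cutoff, d_dir,
                                     use_nominal_p) & universe
        tests[direction] = hypergeom_overlap(sig_d, sig_r, universe,
                                             name=f"replication_{direction}")
        replicated[direction] = sig_d & sig_r
    return tests, replicated


def target_enrichment(de_genes: set[str], targets: TargetSetDB,
                      expressed_universe: set[str]) -> pd.DataFrame:
    """Per-miRNA hypergeometric enrichment of its targets among DE genes.

    Target sets are intersected with the expressed universe before testing;
    a miRNA whose intersected set is empty is reported with overlap 0, not
    dropped.  BH correction is applied across miRNAs.
    """
    expressed_universe = set(expressed_universe)
    if not de_genes <= expressed_universe:
        raise ValueError("de_genes must be a subset of the expressed universe")
    rows = []
    for mirna in sorted(targets.sets):
        tset = targets.sets[mirna] & expressed_universe
        res = hypergeom_overlap(tset, de_genes, expressed_universe, name=mirna)
        rows.append({"mirna": mirna, "overlap": res.overlap,
                     "set_size": res.set_size,
                     "selected_size": res.selected_size,
                     "universe_size": res.universe_size,
                     "pvalue": res.pvalue, "odds_ratio": res.odds_ratio})
    out = pd.DataFrame(rows)
    out["qvalue"] = bh_fdr(out["pvalue"].to_numpy()) if len(out) else []
    return out


def export_network(replicated_mirnas: set[str], targets: TargetSetDB,
                   de_genes: set[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list linking replicated miRNAs to their target genes.

    Returns ``(edges, degrees)``: edges with columns
    ``mirna, gene, gene_is_de`` in deterministic order, and a node degree
    table over the union of miRNAs and genes.
    """
    edges = []
    for mirna in sorted(replicated_mirnas):
        for gene in sorted(targets.sets.get(mirna, set())):
            edges.append({"mirna": mirna, "gene": gene,
                          "gene_is_de": gene in de_genes})
    edge_df = pd.DataFrame(edges, columns=["mirna", "gene", "gene_is_de"])
    deg = {}
    for _, row in edge_df.iterrows():
        deg[row["mirna"]] = deg.get(row["mirna"], 0) + 1
        deg[row["gene"]] = deg.get(row["gene"], 0) + 1
    degree_df = pd.DataFrame(
        [{"node": n, "degree": d} for n, d in sorted(deg.items())],
        columns=["node", "degree"])
    return edge_df, degree_df
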