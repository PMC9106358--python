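"""Test whether each miRNA's target genes are enriched among differentially
expressed mRNAs, and export the miRNA-target network edge list.

The generator couples each planted miRNA to its target genes with an
opposite-sign expression shift, so the planted miRNAs' target sets should be
enriched (small q) while decoy target sets stay at chance.
"""

import pandas as pd

from addictomir import (OmicsSpec, TargetSetDB, export_network, nb_test,
                        significant_features, simulate_counts,
                        target_enrichment)

labels = pd.DataFrame({
    "sample_id": [f"s{i}" for i in range(12)],
    "group": ["vulnerable"] * 6 + ["resilient"] * 6,
})
spec = OmicsSpec(seed=5, coupling=1.0, dispersion=0.05)
_, mrna, _, targets = simulate_counts(spec, labels)

de_mrna = nb_test(mrna)
universe = set(de_mrna["feature"])
de_genes = significant_features(de_mrna, q_cutoff=0.05)
print(f"{len(de_genes)} of {len(universe)} genes differentially expressed")

trimmed = TargetSetDB(sets={m: s & universe for m, s in targets.sets.items()},
                      universe=universe)
enr = target_enrichment(de_genes, trimmed, universe)
enr["planted"] = enr["mirna"].str.startswith(("mir-d", "mir-u"))
print("\nenrichment (top 12 by q):")
print(enr.sort_values("qvalue").head(12)
      [["mirna", "overlap", "set_size", "odds_ratio", "qvalue", "planted"]]
      .to_string(index=False))

replicated_down = {m for m, lfc in spec.planted if lfc < 0}
edges, degrees = export_network(replicated_down, trimmed, de_genes)
print(f"\nnetwork: {len(edges)} edges, "
      f"{edges['gene_is_de'].sum()} to DE genes; "
      f"max gene degree = {degrees['degree'].max()}")
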