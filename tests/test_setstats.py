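"""Hypergeometric overlap, replication, target enrichment, network export."""

import itertools

import numpy as np
import pandas as pd
import pytest

from addictomir import (OmicsSpec, TargetSetDB, export_network,
                        hypergeom_overlap, nb_test, read_gmt,
                        replication_overlap, simulate_counts,
                        target_enrichment, write_gmt)


def enumerate_overlap_p(N, m, s, k):
    """Exhaustive enumeration oracle: fraction of s-subsets of an N-universe
    meeting a fixed m-set in >= k elements."""
    marked = set(range(m))
    hits = total = 0
    for subset in itertools.combinations(range(N), s):
        total += 1
        if len(marked & set(subset)) >= k:
            hits += 1
    return hits / total


class TestHypergeomOverlap:
    def test_worked_example_matches_enumeration(self):
        # |U|=10, |A|=4, |B|=5, overlap 4 -> 5/210
        universe = set(range(10))
        res = hypergeom_overlap(set(range(4)), {0, 1, 2, 3, 9}, universe)
        assert res.pvalue == pytest.approx(5 / 210)
        assert res.pvalue == pytest.approx(enumerate_overlap_p(10, 4, 5, 4))

    def test_full_overlap_of_everything_is_certain(self):
        u = set(range(8))
        assert hypergeom_overlap(u, u, u).pvalue == pytest.approx(1.0)

    def test_zero_overlap_tail_is_one(self):
        res = hypergeom_overlap({0, 1}, {2, 3}, set(range(6)))
        assert res.pvalue == pytest.approx(1.0)

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError, match="subsets"):
            hypergeom_overlap({99}, {0}, {0, 1})

    def test_matches_enumeration_on_small_universes(self):
        for N in (5, 8):
            universe = set(range(N))
            for m in range(N + 1):
                for s in range(N + 1):
                    a = set(range(m))
                    b = set(range(N - s, N))
                    res = hypergeom_overlap(a, b, universe)
                    assert res.pvalue == pytest.approx(
                        enumerate_overlap_p(N, m, s, res.overlap)), (N, m, s)


class TestReplicationOverlap:
    @staticmethod
    def de_table(features, qvals, lfcs):
        return pd.DataFrame({
            "feature": features,
            "log2fc": lfcs,
            "pvalue": qvals,
            "qvalue": qvals,
            "direction": ["down" if l < 0 else "up" for l in lfcs],
        })

    def test_identical_tables_replicate_fully(self):
        feats = [f"f{i}" for i in range(40)]
        q = [0.001] * 5 + [0.5] * 35
        lfc = [-2.0] * 5 + [0.1] * 35
        t = self.de_table(feats, q, lfc)
        tests, rep = replication_overlap(t, t.copy())
        assert rep["down"] == set(feats[:5])
        # minimal attainable p for this configuration: 1 / C(40, 5)
        from math import comb
        assert tests["down"].pvalue == pytest.approx(1 / comb(40, 5))
        assert rep["up"] == set()

    def test_permuted_replica_gives_chance_level_overlap(self, rng):
        feats = [f"f{i}" for i in range(200)]
        sizes = []
        for _ in range(100):
            qd = np.where(np.arange(200) < 10, 0.001, 0.5)
            ld = np.where(np.arange(200) < 10, -1.0, 0.0)
            perm = rng.permutation(200)
            t1 = self.de_table(feats, qd, ld)
            t2 = self.de_table(feats, qd[perm], ld[perm])
            _, rep = replication_overlap(t1, t2)
            sizes.append(len(rep["down"]))
        # E[overlap] = 10*10/200 = 0.5 under the null
        assert np.mean(sizes) < 1.5

    def test_empty_common_universe_rejected(self):
        t1 = self.de_table(["a"], [0.5], [1.0])
        t2 = self.de_table(["b"], [0.5], [1.0])
        with pytest.raises(ValueError, match="both samples"):
            replication_overlap(t1, t2)

    def test_planted_down_effects_replicate_down_not_up(self):
        """Strong planted down-regulation replicates in the down direction
        while the up direction stays at chance (generator + DE + overlap)."""
        labels = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(12)],
            "group": ["vulnerable"] * 6 + ["resilient"] * 6,
        })
        spec = dict(n_features_mirna=100, n_features_mrna=50,
                    planted=tuple((f"mir-d{i:02d}", -3.0) for i in range(9)),
                    dispersion=0.02)
        de = {}
        for name, seed in (("disc", 11), ("repl", 12)):
            mirna, _, _, _ = simulate_counts(OmicsSpec(seed=seed, **spec),
                                             labels)
            de[name] = nb_test(mirna)
        tests, rep = replication_overlap(de["disc"], de["repl"])
        planted = {f"mir-d{i:02d}" for i in range(9)}
        assert rep["down"] <= planted | {f for f in rep["down"]}
        assert len(rep["down"] & planted) >= 5
        assert tests["down"].pvalue < 0.01
        assert tests["up"].pvalue > 0.05


class TestTargetEnrichment:
    def test_de_set_equal_to_target_set_is_extreme(self):
        universe = {f"g{i}" for i in range(200)}
        targets = TargetSetDB(sets={"mirX": {f"g{i}" for i in range(20)}},
                              universe=universe)
        res = target_enrichment({f"g{i}" for i in range(20)}, targets,
                                universe)
        assert res.loc[0, "pvalue"] < 1e-6

    def test_random_de_genes_rarely_enriched(self, rng):
        universe = {f"g{i}" for i in range(400)}
        genes = sorted(universe)
        sets = {f"mir{j}": set(rng.choice(genes, size=30, replace=False))
                for j in range(40)}
        targets = TargetSetDB(sets=sets, universe=universe)
        hits = 0
        reps = 25
        for _ in range(reps):
            de_genes = set(rng.choice(genes, size=40, replace=False))
            res = target_enrichment(de_genes, targets, universe)
            hits += int((res["qvalue"] < 0.05).sum())
        assert hits / (reps * 40) <= 0.05

    def test_empty_target_set_reported_not_dropped(self):
        universe = {"g1", "g2", "g3"}
        targets = TargetSetDB(sets={"mirA": {"g1"}, "mirB": set()},
                              universe=universe)
        res = target_enrichment({"g1"}, targets, universe)
        assert set(res["mirna"]) == {"mirA", "mirB"}
        assert res.set_index("mirna").loc["mirB", "overlap"] == 0

    def test_coupling_switches_enrichment_on_and_off(self):
        """Positive/negative control: planted miRNAs' targets are enriched
        among DE genes only when the generator couples them."""
        labels = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(12)],
            "group": ["vulnerable"] * 6 + ["resilient"] * 6,
        })
        base = dict(n_features_mirna=50, n_features_mrna=600,
                    planted=tuple((f"mir-d{i:02d}", -2.5) for i in range(5)),
                    dispersion=0.05, targets_per_mirna=30,
                    n_decoy_target_sets=5, seed=21)
        results = {}
        for coupling in (1.2, 0.0):
            _, mrna, _, db = simulate_counts(
                OmicsSpec(**base, coupling=coupling), labels)
            de_mrna = nb_test(mrna)
            genes = set(de_mrna.loc[de_mrna["qvalue"] < 0.05, "feature"])
            universe = set(de_mrna["feature"])
            trimmed = TargetSetDB(
                sets={m: s & universe for m, s in db.sets.items()},
                universe=universe)
            res = target_enrichment(genes, trimmed, universe).set_index("mirna")
            results[coupling] = res.loc[[f"mir-d{i:02d}" for i in range(5)]]
        assert (results[1.2]["qvalue"] < 0.05).sum() >= 4
        assert (results[0.0]["qvalue"] < 0.05).sum() == 0


class TestNetworkExport:
    def test_shared_target_has_degree_two(self):
        db = TargetSetDB(sets={"mirA": {"g1", "g2"}, "mirB": {"g1"}})
        edges, degrees = export_network({"mirA", "mirB"}, db, {"g2"})
        deg = degrees.set_index("node")["degree"]
        assert deg["g1"] == 2
        assert edges["gene_is_de"].sum() == 1

    def test_empty_de_genes_flags_nothing(self):
        db = TargetSetDB(sets={"mirA": {"g1", "g2"}})
        edges, _ = export_network({"mirA"}, db, set())
        assert not edges["gene_is_de"].any()

    def test_edge_count_conservation(self, rng):
        genes = [f"g{i}" for i in range(50)]
        sets = {f"mir{j}": set(rng.choice(genes, size=int(rng.integers(1, 20)),
                                          replace=False))
                for j in range(6)}
        db = TargetSetDB(sets=sets)
        edges, _ = export_network(set(sets), db, set(genes[:10]))
        assert len(edges) == sum(len(s) for s in sets.values())


class TestGMTRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        db = TargetSetDB(sets={"mirA": {"g1", "g2"}, "mirB": {"g3"}})
        path = tmp_path / "t.gmt"
        write_gmt(db, path)
        back = read_gmt(path)
        assert back.sets == db.sets

    def test_venn_partition_sums_to_union(self, rng):
        genes = [f"g{i}" for i in range(60)]
        sets = {m: set(rng.choice(genes, size=20, replace=False))
                for m in ("a", "b", "c")}
        union = sets["a"] | sets["b"] | sets["c"]
        total = 0
        for mask in itertools.product([0, 1], repeat=3):
            if mask == (0, 0, 0):
                continue
            region = set(genes)
            for inside, m in zip(mask, ("a", "b", "c")):
                region &= sets[m] if inside else (set(genes) - sets[m])
            total += len(region)
        assert total == len(union)
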