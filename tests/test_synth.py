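"""Synthetic-bundle generators: determinism, planted structure, feasibility."""

import filecmp
import json

import numpy as np
import pytest

from netpharm import (
    filter_by_median,
    generate_bundle,
    generate_disease_sets,
    generate_docking_scores,
    generate_pathways,
    generate_ppi,
    run_ora,
    venn_partition,
    write_bundle,
)
from netpharm import io as npio
from netpharm.topology import feature_median


class TestPpiGenerator:
    def test_minimal_tree(self):
        edges = generate_ppi(3, attachment=1, seed=0)
        assert len(edges) == 2

    def test_deterministic_per_seed(self):
        assert generate_ppi(50, 2, seed=9) == generate_ppi(50, 2, seed=9)
        assert generate_ppi(50, 2, seed=9) != generate_ppi(50, 2, seed=10)

    def test_heavy_tailed_degrees(self):
        edges = generate_ppi(10_000, attachment=2, seed=1)
        degree: dict[str, int] = {}
        for a, b in edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        values = list(degree.values())
        assert max(values) >= 20 * feature_median(values)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_ppi(1, 1)
        with pytest.raises(ValueError):
            generate_ppi(5, 0)


class TestDiseaseSets:
    SIZES = {"PT": 97, "T2D": 59, "HT": 279, "HL": 20}
    SPEC = {("PT", "HT"): 8, ("PT", "HL"): 1, ("PT", "T2D", "HT", "HL"): 1}

    def universe(self):
        return [f"g{i}" for i in range(800)]

    def test_partition_recovers_spec_exactly(self):
        sets, regions = generate_disease_sets(self.universe(), self.SIZES,
                                              self.SPEC, seed=2)
        assert {len(sets[l]) for l in self.SIZES} == {97, 59, 279, 20} == \
            {self.SIZES[l] for l in self.SIZES}
        part = venn_partition(sets)
        for combo, count in self.SPEC.items():
            assert len(part.region(*combo)) == count
            assert part.region(*combo) == regions[frozenset(combo)]

    def test_all_disjoint_spec(self):
        sets, _ = generate_disease_sets(self.universe(),
                                        {"A": 5, "B": 7, "C": 3}, {}, seed=0)
        assert not (sets["A"] & sets["B"] or sets["A"] & sets["C"]
                    or sets["B"] & sets["C"])

    def test_same_seed_reproduces(self):
        a, _ = generate_disease_sets(self.universe(), self.SIZES, self.SPEC, seed=5)
        b, _ = generate_disease_sets(self.universe(), self.SIZES, self.SPEC, seed=5)
        assert a == b

    def test_infeasible_specs_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            generate_disease_sets(self.universe(), {"A": 2, "B": 9},
                                  {("A", "B"): 5}, seed=0)
        with pytest.raises(ValueError, match="universe too small"):
            generate_disease_sets(["g1", "g2"], {"A": 2, "B": 2}, {}, seed=0)


class TestPathways:
    def test_fully_planted_set_is_overwhelming(self):
        universe = [f"g{i}" for i in range(1000)]
        query = universe[:10]
        coll, planted = generate_pathways(universe, n_sets=20,
                                          planted_query=query,
                                          planted_set_fraction=1.0, seed=4)
        results = run_ora(query, coll, universe=universe)
        assert results[0].set_id == planted and results[0].q_value < 1e-6

    def test_background_fraction_rarely_significant(self):
        """A 'planted' set sharing only a background-level overlap with the
        query should almost never clear the 0.05 cutoff."""
        universe = [f"g{i}" for i in range(1000)]
        insignificant = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            query = list(rng.choice(universe, size=10, replace=False))
            coll, planted = generate_pathways(universe, n_sets=10,
                                              size_range=(10, 40),
                                              planted_query=query,
                                              planted_set_fraction=0.1,
                                              seed=seed)
            results = run_ora(query, coll, universe=universe, alpha=0.05)
            if not any(r.set_id == planted for r in results):
                insignificant += 1
        assert insignificant >= 0.95 * n_seeds

    def test_single_set_collection_is_the_planted_set(self):
        universe = [f"g{i}" for i in range(100)]
        coll, planted = generate_pathways(universe, n_sets=1,
                                          planted_query=universe[:5],
                                          planted_set_fraction=1.0, seed=0)
        assert len(coll) == 1 and planted in coll

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_pathways(["a", "b"], planted_query=["a"],
                              planted_set_fraction=0.0)


class TestDockingScores:
    def test_order_statistics_identity(self):
        """2n+1 continuous scores -> the median filter keeps exactly n."""
        pairs = [("c", f"T{i}") for i in range(41)]
        records = generate_docking_scores(pairs, seed=6)
        retained, _ = filter_by_median(records)
        assert len(retained) == 20

    def test_deterministic(self):
        pairs = [("c1", "T1"), ("c2", "T2")]
        assert generate_docking_scores(pairs, seed=3) == generate_docking_scores(pairs, seed=3)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            generate_docking_scores([])

    def test_bad_sd_rejected(self):
        with pytest.raises(ValueError):
            generate_docking_scores([("c", "T")], sd=0.0)


class TestBundle:
    def test_ground_truth_symbols_exist_in_tables(self, default_bundle):
        b = default_bundle
        proteins = set().union(*(d.target_symbols for d in b.disease_lists.values()))
        proteins |= b.putative_targets
        assert set(b.ground_truth["planted_hubs"]) <= proteins
        for members in b.ground_truth["venn_regions"].values():
            assert set(members) <= proteins | b.putative_targets
        assert b.ground_truth["enriched_set_id"] in b.pathways

    def test_bundle_files_pass_all_readers(self, tmp_path, default_bundle):
        paths = write_bundle(default_bundle, tmp_path)
        assert len(npio.read_compounds(paths["compounds"])) == 20
        assoc = npio.read_target_associations(paths["putative_targets"])
        assert {a.target_symbol for a in assoc} == default_bundle.putative_targets
        for label in ("T2D", "HT", "HL"):
            rows = npio.read_disease_target_rows(paths[f"targets_{label}"])
            dlist = npio.dedupe_disease_targets(rows)
            assert dlist.target_symbols == default_bundle.disease_lists[label].target_symbols
        assert len(npio.read_ppi_edges(paths["ppi"])) == len(default_bundle.ppi_edges)
        assert npio.read_gmt(paths["pathways"]).sets == default_bundle.pathways.sets
        assert len(npio.read_docking_scores(paths["docking"])) == len(default_bundle.docking)

    def test_same_seed_writes_byte_identical_files(self, tmp_path):
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        paths_a = write_bundle(generate_bundle(seed=11), dir_a)
        paths_b = write_bundle(generate_bundle(seed=11), dir_b)
        for key in paths_a:
            assert filecmp.cmp(paths_a[key], paths_b[key], shallow=False), key

    def test_every_compound_has_a_target(self, default_bundle):
        hit = {c.compound_id for c in default_bundle.compounds}
        assert hit == {a.compound_id for a in default_bundle.associations}

    def test_venn_ground_truth_matches_partition(self, default_bundle):
        labeled = {"PT": default_bundle.putative_targets}
        labeled.update({l: d.target_symbols
                        for l, d in default_bundle.disease_lists.items()})
        part = venn_partition(labeled)
        truth = default_bundle.ground_truth["venn_regions"]
        for key, members in part.regions.items():
            label = "&".join(sorted(key))
            assert sorted(members) == truth.get(label, [])
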