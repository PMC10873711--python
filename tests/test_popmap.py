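import collections

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hapsoma.popmap import (PopulationMap, binomial_window_filter,
                            export_distance_nexus, group_specific_screen,
                            merge_population, pairwise_distances,
                            polarize_and_spectrum, read_distance_nexus)
from hapsoma.simgen import CloneTree, generate_diploid, spike_somatic

from conftest import TruthCall, small_config, truth_callsets


@pytest.fixture(scope="module")
def clonal_map():
    g = generate_diploid(small_config(contigs={"chr1": 40_000}, seed=19))
    tree = CloneTree.with_outgroup_clade(n_outgroup=8, n_ingroup=8)
    truth = spike_somatic(g, tree, 300, seed=20)
    calls = truth_callsets(g, tree, truth)
    return g, tree, truth, merge_population(calls)


def _matrix(rows, accs):
    idx = pd.Index([tuple(r) for r in rows], tupleize_cols=False)
    return PopulationMap(pd.DataFrame(
        np.zeros((len(rows), len(accs))), index=idx, columns=accs))


class TestMerge:
    def test_single_accession_equals_callset(self):
        from hapsoma.simgen import SomaticMutation

        m = SomaticMutation("s0", "A", "c_A", 10, "A", "T", "SNP", "b")
        pmap = merge_population({"acc0": [TruthCall(m)]})
        assert list(pmap.genotypes.columns) == ["acc0"]
        assert pmap.genotypes.iloc[0, 0] == 1.0

    def test_occupancy_equals_tree_leaf_counts(self, clonal_map):
        """Per-variant occupancy equals the number of leaves below the
        carrying branch (brute-force path enumeration)."""
        g, tree, truth, pmap = clonal_map
        occ = pmap.occupancy()
        leaves = sorted(tree.leaves)
        below = {b: sum(b in set(tree.path_branches(l)) for l in leaves)
                 for b in tree.branches}
        by_key = {(m.haplotype_id, m.contig, m.pos0, m.ref, m.alt): m for m in truth}
        for key, n in occ.items():
            assert n == below[by_key[key].branch_id]

    def test_block_diagonal_for_disjoint_accessions(self):
        from hapsoma.simgen import SomaticMutation

        m1 = SomaticMutation("s0", "A", "c_A", 10, "A", "T", "SNP", "b1")
        m2 = SomaticMutation("s1", "A", "c_A", 99, "G", "C", "SNP", "b2")
        pmap = merge_population({"x": [TruthCall(m1)], "y": [TruthCall(m2)]})
        mat = pmap.genotypes
        assert mat.loc[[("A", "c_A", 10, "A", "T")], "y"].iloc[0] == 0
        assert mat.loc[[("A", "c_A", 99, "G", "C")], "x"].iloc[0] == 0

    def test_conflicting_ref_raises(self):
        from hapsoma.simgen import SomaticMutation

        m1 = SomaticMutation("s0", "A", "c_A", 10, "A", "T", "SNP", "b")
        m2 = SomaticMutation("s1", "A", "c_A", 10, "G", "T", "SNP", "b")
        with pytest.raises(ValueError, match="build mismatch"):
            merge_population({"x": [TruthCall(m1)], "y": [TruthCall(m2)]})

    def test_low_depth_becomes_na(self):
        from hapsoma.simgen import SomaticMutation

        m = SomaticMutation("s0", "A", "c_A", 10, "A", "T", "SNP", "b")
        pmap = merge_population(
            {"x": [TruthCall(m)], "y": []},
            depth_of={"y": lambda c, p: 0, "x": lambda c, p: 30},
        )
        assert np.isnan(pmap.genotypes.loc[[("A", "c_A", 10, "A", "T")], "y"].iloc[0])


class TestWindowFilter:
    def test_uniform_null_removal_rate_below_alpha(self):
        """Uniformly spiked variants: removed-window fraction <= alpha."""
        g = generate_diploid(small_config(contigs={"chr1": 50_000}, seed=23))
        removed = total = 0
        for seed in range(20):
            truth = spike_somatic(g, CloneTree.linear(1), 100, seed=seed)
            pmap = merge_population({"a": [TruthCall(m) for m in truth]})
            _, stats_out = binomial_window_filter(
                pmap, {n: len(s) for n, s in g.contigs.items()},
                window=5_000, alpha=0.001)
            removed += sum(w.removed for w in stats_out)
            total += len(stats_out)
        assert removed / total <= 0.001 + 3 * np.sqrt(0.001 / total)

    def test_hotspot_window_removed(self):
        """A window given ~10x the uniform expectation is always removed."""
        rows = []
        # 200 uniform variants over 1 Mb + 100 extra inside one 50-kb window
        rng = np.random.default_rng(3)
        for p in rng.integers(0, 1_000_000, 200):
            rows.append(("A", "c_A", int(p), "A", "T"))
        for p in rng.integers(600_000, 650_000, 100):
            rows.append(("A", "c_A", int(p), "G", "C"))
        rows = list(dict.fromkeys(rows))
        pmap = _matrix(rows, ["x"])
        pmap.genotypes.loc[:, "x"] = 1.0
        filtered, stats_out = binomial_window_filter(pmap, {"c_A": 1_000_000})
        hot = [w for w in stats_out if w.start == 600_000]
        assert hot[0].removed
        # the filtered map lost exactly the hotspot window's variants
        assert all(not (600_000 <= k[2] < 650_000) for k in filtered.genotypes.index)

    def test_default_window_is_50kb(self):
        pmap = _matrix([("A", "c_A", 10, "A", "T")], ["x"])
        pmap.genotypes.loc[:, "x"] = 1.0
        _, stats_out = binomial_window_filter(pmap, {"c_A": 200_000})
        assert stats_out[0].end - stats_out[0].start == 50_000


class TestSpectrum:
    def test_outgroup_absent_variant_polarized_to_alt(self):
        rows = [("A", "c_A", 10, "A", "T")]
        pmap = _matrix(rows, ["in1", "in2", "out1"])
        pmap.genotypes.loc[:, "in1"] = 1.0
        res = polarize_and_spectrum(pmap, ["out1"])
        assert res.derived_labels.iloc[0] == "alt"
        assert res.counts == {1: 1}

    def test_missing_outgroup_raises(self):
        pmap = _matrix([("A", "c_A", 10, "A", "T")], ["a"])
        with pytest.raises(ValueError):
            polarize_and_spectrum(pmap, ["nope"])

    def test_spectrum_matches_tree_oracle(self, clonal_map):
        """8-leaf-outgroup clone tree: occupancy spectrum equals the
        brute-force tally from truth branches."""
        g, tree, truth, pmap = clonal_map
        res = polarize_and_spectrum(pmap, sorted(tree.outgroup))
        ingroup = sorted(tree.leaves - tree.outgroup)
        expected = collections.Counter()
        unresolved = 0
        for m in truth:
            out_carriers = sum(m.branch_id in set(tree.path_branches(l))
                               for l in tree.outgroup)
            in_carriers = sum(m.branch_id in set(tree.path_branches(l))
                              for l in ingroup)
            if out_carriers == 0:
                expected[in_carriers] += 1
            elif out_carriers == len(tree.outgroup):
                expected[len(ingroup) - in_carriers] += 1
            else:
                unresolved += 1
        assert dict(res.counts) == dict(expected)
        assert res.unresolved == unresolved
        # conservation
        assert res.total == len(truth)

    def test_low_frequency_fraction_definition(self):
        rows = [("A", "c", i, "A", "T") for i in range(4)]
        pmap = _matrix(rows, ["i1", "i2", "i3", "o"])
        gm = pmap.genotypes
        gm.iloc[0, 0] = 1.0                      # occupancy 1 (low)
        gm.iloc[1, 0] = gm.iloc[1, 1] = 1.0      # occupancy 2 (low)
        gm.iloc[2, :3] = 1.0                     # occupancy 3
        gm.iloc[3, :3] = 1.0                     # occupancy 3
        res = polarize_and_spectrum(pmap, ["o"])
        assert res.low_frequency_fraction(below=3) == pytest.approx(0.5)


class TestGroupScreen:
    def test_group_private_variant_retained_and_partial_excluded(self):
        rows = [("A", "c", 1, "A", "T"), ("A", "c", 2, "G", "C")]
        pmap = _matrix(rows, ["g1", "g2", "g3", "x1"])
        gm = pmap.genotypes
        gm.iloc[0, :3] = 1.0        # all three group members
        gm.iloc[1, :2] = 1.0        # only two of three
        hits = group_specific_screen(pmap, ["g1", "g2", "g3"])
        assert list(hits["pos0"]) == [1]

    def test_group_must_be_strict_subset(self):
        pmap = _matrix([("A", "c", 1, "A", "T")], ["a", "b"])
        with pytest.raises(ValueError):
            group_specific_screen(pmap, ["a", "b"])

    def test_private_branch_recovered_exactly(self, clonal_map):
        """A clade-private branch's mutations are exactly the screen output."""
        g, tree, truth, pmap = clonal_map
        group = sorted(tree.leaves - tree.outgroup)  # the ingroup clade
        hits = group_specific_screen(pmap, group)
        expected = {(m.haplotype_id, m.contig, m.pos0) for m in truth
                    if m.branch_id == "inclade"}
        got = {(r.haplotype, r.contig, r.pos0) for r in hits.itertuples()}
        assert got == expected

    def test_gene_proximity_annotation(self):
        genes = pd.DataFrame([("g1", "c_A", 5_000, 6_000, "+")],
                             columns=["gene_id", "contig", "start", "end", "strand"])
        rows = [("A", "c_A", 4_000, "A", "T"), ("A", "c_A", 500, "G", "C")]
        pmap = _matrix(rows, ["g1acc", "x"])
        pmap.genotypes.iloc[:, 0] = 1.0
        hits = group_specific_screen(pmap, ["g1acc"], genes=genes, proximity=3_000)
        ann = dict(zip(hits["pos0"], hits["genes"]))
        assert ann[4_000] == "g1"   # within 3 kb upstream
        assert ann[500] == ""       # 4.5 kb away: outside


class TestDistances:
    def test_identical_accessions_zero_distance(self):
        rows = [("A", "c", i, "A", "T") for i in range(5)]
        pmap = _matrix(rows, ["a", "b", "c"])
        pmap.genotypes.loc[:, "a"] = [1, 1, 0, 0, 1.0]
        pmap.genotypes.loc[:, "b"] = [1, 1, 0, 0, 1.0]
        pmap.genotypes.loc[:, "c"] = [0, 1, 1, 0, 0.0]
        d = pairwise_distances(pmap)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == pytest.approx(3 / 5)

    def test_hand_computed_3x4(self):
        rows = [("A", "c", i, "A", "T") for i in range(4)]
        pmap = _matrix(rows, ["x", "y", "z"])
        pmap.genotypes.loc[:, "x"] = [1, 0, 1, 0.0]
        pmap.genotypes.loc[:, "y"] = [1, 1, 0, 0.0]
        pmap.genotypes.loc[:, "z"] = [0, 0, 0, 1.0]
        d = pairwise_distances(pmap)
        assert d.loc["x", "y"] == pytest.approx(2 / 4)
        assert d.loc["x", "z"] == pytest.approx(3 / 4)
        assert d.loc["y", "z"] == pytest.approx(3 / 4)
        # metric properties
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        for a in d.index:
            for b in d.index:
                for c in d.index:
                    assert d.loc[a, c] <= d.loc[a, b] + d.loc[b, c] + 1e-12

    def test_nexus_roundtrip(self, tmp_path):
        rows = [("A", "c", i, "A", "T") for i in range(4)]
        pmap = _matrix(rows, ["x", "y", "z"])
        pmap.genotypes.loc[:, "x"] = [1, 0, 1, 0.0]
        pmap.genotypes.loc[:, "y"] = [1, 1, 0, 0.0]
        pmap.genotypes.loc[:, "z"] = [0, 0, 0, 1.0]
        path = tmp_path / "dist.nex"
        d = export_distance_nexus(pmap, path)
        back = read_distance_nexus(path)
        assert np.allclose(back.to_numpy(), d.to_numpy(), atol=1e-6)
        assert list(back.index) == list(d.index)
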