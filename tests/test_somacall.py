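import math

import numpy as np
import pytest

from hapsoma.homology import build_homology_map
from hapsoma.mapping import ReadMapper
from hapsoma.pileup import PileupColumn, build_pileup
from hapsoma.seqs import random_seq
from hapsoma.simgen import (CloneTree, build_accession_genome, generate_diploid,
                            simulate_reads, spike_somatic)
from hapsoma.somacall import (Blacklist, build_blacklist, call_somatic,
                              dedup_homologous, genotype_site, germline_genotypes,
                              retained)

from conftest import small_config


def _col(counts, contig="c", pos=10, mapq0=0.0):
    return PileupColumn(contig, pos, sum(counts.values()), counts, mapq0)


class TestGenotypeSite:
    def test_pure_alt_dual_high_qual(self):
        gc = genotype_site(_col({"T": 30}), "dual", 0.002, ref="A")
        assert gc.genotype == ("T",)
        assert gc.qual > 50

    def test_dual_balanced_without_mapq0_is_not_collapsed(self):
        gc = genotype_site(_col({"A": 15, "T": 15}), "dual", 0.002, ref="A")
        assert not gc.collapsed

    def test_dual_balanced_with_mapq0_collapsed_het(self):
        gc = genotype_site(_col({"A": 15, "T": 15}, mapq0=0.9), "dual", 0.002, ref="A")
        assert gc.collapsed
        assert gc.genotype == ("A", "T")
        assert gc.qual > 50

    def test_single_het_posterior_matches_bruteforce(self):
        """15 REF / 15 ALT: posterior equals direct binomial-likelihood
        enumeration over the candidate genotypes (flat prior)."""
        e = 0.002
        counts = {"A": 15, "T": 15}
        gc = genotype_site(_col(counts), "single", e, ref="A")
        assert gc.genotype == ("A", "T")

        def loglik(gt):
            ll = 0.0
            for obs, n in counts.items():
                p = sum((1 - e) if obs == a else e / 3 for a in gt) / 2
                ll += n * math.log(p)
            return ll

        gts = [("A", "A"), ("A", "T"), ("T", "T")]
        lls = np.array([loglik(g) for g in gts])
        post = np.exp(lls - lls.max())
        post /= post.sum()
        expected_qual = min(-10 * math.log10(max(1 - post[1], 1e-100)), 1000.0)
        assert gc.qual == pytest.approx(expected_qual, rel=1e-6)

    def test_depth_requirement(self):
        with pytest.raises(ValueError):
            genotype_site(_col({}), "dual", ref="A")


class TestCallFilters:
    def test_depth1_flagged_lowdepth(self, rng):
        ref = {"cA": random_seq(rng, 400), "cB": random_seq(rng, 400)}
        from hapsoma.mapping import AlignmentRecord

        alt = "G" if ref["cA"][200] != "G" else "C"
        seq = ref["cA"][150:200] + alt + ref["cA"][201:300]
        rec = AlignmentRecord("r", "cA", 150, "+", "50=1X99=", 1, 60, seq)
        pp = build_pileup([rec], ref)
        calls = call_somatic(pp, ref, "dual", min_alt=1)
        assert len(calls) == 1
        assert "LOWDEPTH" in calls[0].filters

    def test_blacklist_removes_exactly_members(self, rng):
        ref = {"cA": random_seq(rng, 400), "cB": random_seq(rng, 400)}
        from hapsoma.mapping import AlignmentRecord

        alt = "G" if ref["cA"][200] != "G" else "C"
        seq = ref["cA"][150:200] + alt + ref["cA"][201:300]
        recs = [AlignmentRecord(f"r{i}", "cA", 150, "+", "50=1X99=", 1, 60, seq)
                for i in range(30)]
        pp = build_pileup(recs, ref)
        bl = Blacklist({("cA", 200)})
        calls = call_somatic(pp, ref, "dual", blacklist=bl)
        assert len(calls) == 1 and "BLACKLIST" in calls[0].filters
        calls2 = call_somatic(pp, ref, "dual", blacklist=Blacklist({("cA", 42)}))
        assert calls2[0].retained


class TestDedup:
    def _setup(self, rng, identical=True):
        shared = random_seq(rng, 2_000)
        if identical:
            a, b = shared, shared
        else:
            a = shared
            b = list(shared)
            b[900] = "A" if shared[900] != "A" else "C"
            b = "".join(b)
        ref = {"h_A": a, "h_B": b}
        hm = build_homology_map({"h_A": a}, {"h_B": b}, k_anchor=21)
        return ref, hm

    def _call(self, contig, pos, alt="T"):
        from hapsoma.somacall import SomaticCall

        return SomaticCall(id="x", mode="dual", contig=contig, pos0=pos, ref="A",
                           alt=alt, kind="SNP", support=10, depth=20, qual=99,
                           genotype=(alt,), haplotype=contig[-1], collapsed=False)

    def test_identical_flanks_merge_keep_hapA(self, rng):
        ref, hm = self._setup(rng, identical=True)
        ca, cb = self._call("h_A", 1000), self._call("h_B", 1000)
        out = dedup_homologous([ca, cb], ref, hm, flank=150)
        kept = [c for c in out if c.retained]
        assert len(kept) == 1 and kept[0].contig == "h_A"
        assert "DUP" in cb.filters
        assert ca.dup_group == cb.dup_group is not None

    def test_different_flanks_keep_both(self, rng):
        ref, hm = self._setup(rng, identical=False)
        ca, cb = self._call("h_A", 1000), self._call("h_B", 1000)
        out = dedup_homologous([ca, cb], ref, hm, flank=150)
        assert all(c.retained for c in out)

    def test_idempotence(self, rng):
        ref, hm = self._setup(rng, identical=True)
        calls = [self._call("h_A", 1000), self._call("h_B", 1000),
                 self._call("h_A", 300, alt="G")]
        once = dedup_homologous(calls, ref, hm, flank=150)
        snap = [(c.contig, c.pos0, sorted(c.filters), c.dup_group) for c in once]
        twice = dedup_homologous(once, ref, hm, flank=150)
        assert [(c.contig, c.pos0, sorted(c.filters), c.dup_group) for c in twice] == snap

    def test_contig_end_truncated_symmetrically(self, rng):
        ref, hm = self._setup(rng, identical=True)
        ca, cb = self._call("h_A", 30), self._call("h_B", 30)  # flank hits the start
        out = dedup_homologous([ca, cb], ref, hm, flank=150)
        assert sum(c.retained for c in out) == 1


class TestBlacklistBuild:
    def test_unique_genome_error_free_empty(self, rng):
        g = generate_diploid(small_config(contigs={"chr1": 20_000},
                                          repeat_fraction=0.0,
                                          n_hap_specific_segments=0, seed=31))
        bl = build_blacklist(g, "dual", coverage=20, error_rate=0.0, seed=1)
        assert len(bl) == 0

    def test_engineered_duplication_concentrates_blacklist(self, rng):
        """A 5-kb segment duplicated on haplotype B only: in single-reference
        mode the extra copy's reads collapse onto the lone haplotype-A copy,
        so null-simulation false calls concentrate inside that segment."""
        from hapsoma.simgen import DiploidGenome
        from hapsoma.homology import HomologyMap
        from hapsoma.seqs import mutate_seq

        base = random_seq(rng, 30_000)
        seg = base[5_000:10_000]
        extra = mutate_seq(np.random.default_rng(5), seg, 0.01)
        hapA = {"c_A": base}
        hapB = {"c_B": base[:20_000] + extra + base[20_000:]}
        hm = HomologyMap()
        hm.add_block("c_A", 0, 20_000, "c_B", 0)
        hm.add_block("c_A", 20_000, 30_000, "c_B", 25_000)
        g = DiploidGenome(hapA, hapB, hm, [], [], seed=0)
        bl = build_blacklist(g, "single", coverage=25, seed=2)
        assert len(bl) > 10
        inside = sum(1 for c, p in bl.positions
                     if 5_000 - 400 <= p < 10_000 + 400 or abs(p - 20_000) < 400)
        assert inside / len(bl) > 0.9

    def test_application_is_set_difference(self):
        bl = Blacklist({("c", 1), ("c", 2)})
        assert ("c", 1) in bl and ("c", 3) not in bl


def test_mutation_free_dual_mode_is_clean(small_genome):
    """Dual-mode calling on a mutation-free simulation, after blacklisting,
    retains no calls (the het background vanishes in the dual reference)."""
    g = small_genome
    mapper = ReadMapper(g.contigs)
    bl = build_blacklist(g, "dual", coverage=35, seed=41, mapper=mapper)
    batch = simulate_reads(g, 35, seed=42)
    recs = mapper.map_pairs(batch)
    pp = build_pileup(recs, g.contigs)
    calls = call_somatic(pp, g.contigs, "dual", blacklist=bl, homology=g.homology)
    assert len(retained(calls)) == 0


def test_single_mode_sees_het_background(small_genome):
    """Single-reference calling without germline subtraction reproduces the
    heterozygous background at roughly the configured density."""
    g = small_genome
    ref = dict(g.hapA)
    mapper = ReadMapper(ref)
    batch = simulate_reads(g, 35, seed=43)
    recs = mapper.map_pairs(batch)
    pp = build_pileup(recs, ref)
    calls = call_somatic(pp, ref, "single", germline=None, min_qual=20)
    n_het = sum(1 for c in calls if c.genotype[0] != c.genotype[1])
    n_expected = sum(v.kind == "SNP" for v in g.germline)
    assert 0.75 * n_expected < n_het < 1.25 * n_expected


def test_spiked_snp_called_on_true_haplotype(small_genome, small_truth):
    """A spiked SNP in a divergent region yields one retained call at the
    true haplotype position with near-fixed alt fraction."""
    g = small_genome
    tree = CloneTree.linear(1)
    acc = build_accession_genome(g, small_truth, tree, "acc0")
    batch = simulate_reads(acc, 35, seed=44)
    mapper = ReadMapper(g.contigs)
    recs = mapper.map_pairs(batch)
    pp = build_pileup(recs, g.contigs)
    bl = build_blacklist(g, "dual", 35, seed=45, mapper=mapper)
    calls = retained(call_somatic(pp, g.contigs, "dual", blacklist=bl,
                                  homology=g.homology))
    by_pos = {(c.contig, c.pos0): c for c in calls}
    germ_snps = np.asarray(sorted(v.posA for v in g.germline if v.kind == "SNP"))
    checked = 0
    for m in small_truth:
        if m.kind != "SNP":
            continue
        # require a germline SNP within the read span (divergent window)
        if m.contig.endswith("_A"):
            aPos = m.pos0
        else:
            hom = g.homology.lookup(m.contig, m.pos0)
            if hom is None:
                continue
            aPos = hom[1]
        lo, hi = np.searchsorted(germ_snps, [aPos - 120, aPos + 120])
        if hi - lo < 2:
            continue
        c = by_pos.get((m.contig, m.pos0))
        if c is None:
            continue
        if c.collapsed or pp.column(m.contig, m.pos0).mapq0_fraction > 0.1:
            continue  # repeat-stacked context; alt fraction is diluted there
        checked += 1
        assert c.alt == m.alt
        assert c.support / c.depth > 0.8
    assert checked >= 10
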