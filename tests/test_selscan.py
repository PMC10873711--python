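import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hapsoma.seqs import random_seq, revcomp
from hapsoma.selscan import (CodingAnnotation, MutationMatrix, Transcript,
                             annotate_effects, count_ns, estimate_mutation_matrix,
                             jc_distance, jc_inverse, normalized_dnds,
                             simulate_neutral)

_CODON = {}


def _codon_table():
    if not _CODON:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON.update(standard_dna_table.forward_table)
        for c in standard_dna_table.stop_codons:
            _CODON[c] = "*"
    return _CODON


class _V:
    def __init__(self, contig, pos0, ref, alt):
        self.contig, self.pos0, self.ref, self.alt = contig, pos0, ref, alt


class TestMutationMatrix:
    def test_jukes_cantor_rows(self):
        m = MutationMatrix.jukes_cantor()
        assert np.allclose(m.probs.sum(axis=1), 1)
        assert np.allclose(np.diag(m.probs), 0)
        assert np.allclose(m.probs[m.probs > 0], 1 / 3)

    def test_single_event_type(self):
        m = estimate_mutation_matrix([("A", "G")] * 10)
        assert m.probs[0, 2] == 1.0
        assert m.counts[0, 2] == 10

    def test_zero_row_warns_uniform(self):
        with pytest.warns(UserWarning):
            m = estimate_mutation_matrix([("A", "G")])
        assert np.allclose(m.probs[3], [1 / 3, 1 / 3, 1 / 3, 0])

    @pytest.mark.parametrize("n", [500, 5000])
    def test_parameter_recovery(self, n, rng):
        """Estimates from samples of a known matrix converge (3 sigma)."""
        true = np.array([
            [0.0, 0.5, 0.3, 0.2],
            [0.1, 0.0, 0.2, 0.7],
            [0.25, 0.25, 0.0, 0.5],
            [0.4, 0.4, 0.2, 0.0],
        ])
        m_true = MutationMatrix(true)
        bases = "ACGT"
        events = []
        for _ in range(n):
            ref = bases[int(rng.integers(4))]
            events.append((ref, m_true.sample_alt(ref, rng)))
        est = estimate_mutation_matrix(events)
        for i in range(4):
            row_n = est.counts[i].sum()
            for j in range(4):
                if i == j:
                    continue
                sd = math.sqrt(true[i, j] * (1 - true[i, j]) / max(row_n, 1))
                assert abs(est.probs[i, j] - true[i, j]) < 3 * sd + 1e-9


class TestJukesCantor:
    def test_examples(self):
        assert jc_distance(0.0) == 0.0
        assert jc_distance(0.1) == pytest.approx(0.107326, abs=1e-6)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError):
            jc_distance(0.75)
        with pytest.raises(ValueError):
            jc_distance(-0.01)

    @given(st.floats(0.0, 0.7))
    @settings(deadline=None)
    def test_inverse_roundtrip_and_expansion(self, p):
        d = jc_distance(p)
        assert abs(jc_inverse(d) - p) < 1e-12
        assert d >= p - 1e-15  # correction only expands distances


def _toy_annotation(rng, n_genes=3, gene_len=300, spacer=200, strand_cycle=("+", "-")):
    """Random genome with clean single-exon CDSs (ATG ... stop-free interior)."""
    parts = []
    txs = []
    pos = 0
    table = _codon_table()
    stops = {c for c, a in table.items() if a == "*"}
    for i in range(n_genes):
        parts.append(random_seq(rng, spacer))
        pos += spacer
        n_codons = gene_len // 3
        body = ["ATG"]
        while len(body) < n_codons - 1:
            c = random_seq(rng, 3)
            if c not in stops:
                body.append(c)
        body.append("TGA")
        cds = "".join(body)
        strand = strand_cycle[i % len(strand_cycle)]
        if strand == "-":
            parts.append(revcomp(cds))
        else:
            parts.append(cds)
        txs.append(Transcript(f"tx{i}", "chr", strand, [(pos, pos + len(cds))]))
        pos += len(cds)
    parts.append(random_seq(rng, spacer))
    genome = {"chr": "".join(parts)}
    return genome, CodingAnnotation(txs, genome)


class TestEffects:
    def test_synonymous_third_position(self):
        genome = {"c": "ATGGGATGA"}  # M G *
        ann = CodingAnnotation([Transcript("t", "c", "+", [(0, 9)])], genome)
        assert ann.classify_snp("c", 5, "G") == "synonymous"  # GGA->GGG
        assert ann.classify_snp("c", 4, "T") == "missense"    # GGA->GTA

    def test_stop_gain_tgg_to_tga(self):
        genome = {"c": "ATGTGGTGA"}  # M W *
        ann = CodingAnnotation([Transcript("t", "c", "+", [(0, 9)])], genome)
        assert ann.classify_snp("c", 5, "A") == "stop_gain"
        assert ann.is_lof("stop_gain")

    def test_start_loss_and_stop_loss(self):
        genome = {"c": "ATGTGGTGA"}
        ann = CodingAnnotation([Transcript("t", "c", "+", [(0, 9)])], genome)
        assert ann.classify_snp("c", 0, "C") == "start_loss"
        assert ann.classify_snp("c", 8, "C") == "stop_loss"  # TGA->TGC

    def test_minus_strand_gene(self):
        cds = "ATGGGATGA"
        genome = {"c": "TT" + revcomp(cds) + "AA"}
        ann = CodingAnnotation([Transcript("t", "c", "-", [(2, 11)])], genome)
        # genomic base pairing with the wobble G of codon GGA is a C
        # third codon position of GGA lies at genomic pos 2 + (9-1-5) = 5
        assert ann.classify_snp("c", 5, "C") == "synonymous"

    def test_frameshift_and_inframe(self, rng):
        genome, ann = _toy_annotation(rng, n_genes=1)
        tx = ann.transcripts[0]
        inside = tx.cds[0][0] + 10
        assert ann.classify("chr", inside, "AA", "A") == "frameshift"
        assert ann.classify("chr", inside, "AAAA", "A") == "inframe_indel"  # 3-bp del
        assert ann.classify("chr", inside, "A", "AGGG") == "inframe_indel"
        assert ann.classify("chr", inside, "A", "AGG") == "frameshift"
        assert ann.classify("chr", 5, "A", "AG") == "noncoding"  # spacer

    def test_annotate_effects_frame(self, rng):
        genome, ann = _toy_annotation(rng, n_genes=2)
        s = ann.transcripts[0].cds[0][0]
        variants = [_V("chr", s + 5, genome["chr"][s + 5], "A"),
                    _V("chr", 10, genome["chr"][10], "T")]
        if variants[0].alt == variants[0].ref:
            variants[0].alt = "C"
        if variants[1].alt == variants[1].ref:
            variants[1].alt = "G"
        df = annotate_effects(variants, ann)
        assert df.loc[1, "effect"] == "noncoding"
        assert df.loc[0, "effect"] in ("synonymous", "missense", "stop_gain", "stop_loss")


class TestExhaustiveOracle:
    def test_classification_and_opportunities_match_bruteforce(self, rng):
        """Toy genes <= 1 kb: every single-base change's class, and the N/S
        opportunity totals, equal literal mutate-and-translate enumeration."""
        genome, ann = _toy_annotation(rng, n_genes=3, gene_len=300)
        table = _codon_table()
        syn = nonsyn = 0
        for tx in ann.transcripts:
            s, e = tx.cds[0]
            cds = genome["chr"][s:e]
            if tx.strand == "-":
                cds = revcomp(cds)
            for ci in range(len(cds) // 3):
                codon = cds[ci * 3 : ci * 3 + 3]
                aa = table[codon]
                for within in range(3):
                    for alt in "ACGT":
                        if alt == codon[within]:
                            continue
                        alt_codon = codon[:within] + alt + codon[within + 1 :]
                        aa2 = table[alt_codon]
                        if ci == 0 and aa == "M" and aa2 != "M":
                            expect = "start_loss"
                        elif aa != "*" and aa2 == "*":
                            expect = "stop_gain"
                        elif aa == "*" and aa2 != "*":
                            expect = "stop_loss"
                        elif aa == aa2:
                            expect = "synonymous"
                        else:
                            expect = "missense"
                        if expect == "synonymous":
                            syn += 1
                        else:
                            nonsyn += 1
                        # genomic coordinates of this change
                        cds_i = ci * 3 + within
                        if tx.strand == "+":
                            gpos = s + cds_i
                            galt = alt
                        else:
                            gpos = e - 1 - cds_i
                            galt = revcomp(alt)
                        assert ann.classify_snp("chr", gpos, galt) == expect, (
                            tx.tx_id, ci, within, alt)
        opp = ann.opportunity_counts()
        assert opp["synonymous_changes"] == syn
        assert opp["nonsynonymous_changes"] == nonsyn
        assert opp["S_sites"] == pytest.approx(syn / 3)


class TestNeutralDnds:
    def test_r_minimum(self, rng):
        genome, ann = _toy_annotation(rng)
        with pytest.raises(ValueError):
            simulate_neutral(MutationMatrix.jukes_cantor(), ann, genome, 10, R=1)

    def test_determinism(self, rng):
        genome, ann = _toy_annotation(rng)
        m = MutationMatrix.jukes_cantor()
        r1 = simulate_neutral(m, ann, genome, 200, R=5, seed=3)
        r2 = simulate_neutral(m, ann, genome, 200, R=5, seed=3)
        assert r1 == r2

    def test_neutral_replicates_cluster_at_opportunity_ratio(self, rng):
        """Under the equal-rate matrix, replicate N/S counts track the
        enumeration-oracle opportunity ratio."""
        genome, ann = _toy_annotation(rng, n_genes=4, spacer=50)
        m = MutationMatrix.jukes_cantor()
        reps = simulate_neutral(m, ann, genome, 2_000, R=30, seed=1)
        opp = ann.opportunity_counts()
        expected = opp["nonsynonymous_changes"] / opp["synonymous_changes"]
        ratio_ns = np.mean([r["n"] / max(r["s"], 1) for r in reps])
        assert ratio_ns == pytest.approx(expected, rel=0.15)

    def test_self_normalization_near_one(self, rng):
        """An observed set drawn neutrally has normalized dN/dS ~ 1."""
        genome, ann = _toy_annotation(rng, n_genes=4, spacer=50)
        m = MutationMatrix.jukes_cantor()
        reps = simulate_neutral(m, ann, genome, 1_000, R=100, seed=5)
        obs = _draw_neutral_variants(genome, ann, m, 1_000, seed=99)
        res = normalized_dnds(obs, ann, reps)
        assert res.ci95[0] <= 1.0 <= res.ci95[1] or abs(res.normalized - 1) < 0.2

    def test_nonsynonymous_only_exceeds_one(self, rng):
        genome, ann = _toy_annotation(rng, n_genes=4, spacer=50)
        m = MutationMatrix.jukes_cantor()
        reps = simulate_neutral(m, ann, genome, 500, R=50, seed=6)
        obs = _draw_neutral_variants(genome, ann, m, 2_000, seed=7)
        non = [v for v in obs
               if ann.classify_snp(v.contig, v.pos0, v.alt) not in ("synonymous", "noncoding")]
        res = normalized_dnds(non, ann, reps)
        assert res.normalized > 1.0
        # ratio-of-ratios cross-check against direct recomputation
        n_obs, s_obs = count_ns(non, ann)
        assert s_obs == 0 and res.pseudo_used


def _draw_neutral_variants(genome, ann, matrix, n, seed):
    from hapsoma._rng import stage_rng
    rng = stage_rng(seed, "neutral-sim")
    names = sorted(genome)
    lens = np.array([len(genome[k]) for k in names])
    cum = np.concatenate([[0], np.cumsum(lens)])
    g = rng.integers(0, cum[-1], size=n)
    out = []
    from hapsoma.seqs import encode
    codes = {k: encode(genome[k]) for k in names}
    ci = np.searchsorted(cum, g, side="right") - 1
    for name_i in np.unique(ci):
        name = names[name_i]
        pos = (g[ci == name_i] - cum[name_i]).astype(np.int64)
        refc = codes[name][pos]
        altc = matrix.sample_alts(refc, rng)
        for p, rc, ac in zip(pos, refc, altc):
            out.append(_V(name, int(p), "ACGT"[rc], "ACGT"[ac]))
    return out
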