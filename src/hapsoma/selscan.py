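"""Base-mutation matrix, Jukes-Cantor correction and neutral-normalized dN/dS.

The clonal population is too young for a classical codon-model dN/dS, so
selection is assessed by the normalization route: count observed
nonsynonymous (N) and synonymous (S) somatic SNPs, convert the proportions
per opportunity site to distances with the Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p), and divide the observed dN/dS by the mean
dN/dS of R neutral simulations that drop the same number of mutations
uniformly over the genome with alternate alleles drawn from the empirical
base-mutation matrix. A normalized value near 1 is neutral; > 1 indicates
an excess of protein-changing mutations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rng import stage_rng
from .seqs import encode, revcomp

_BASES = "ACGT"

# standard genetic code, '*' = stop
_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for c in standard_dna_table.stop_codons:
            _CODON_TABLE[c] = "*"
    return _CODON_TABLE


# --------------------------------------------------------------------------
# mutation matrix
# --------------------------------------------------------------------------

@dataclass
class MutationMatrix:
    """4x4 relative substitution probabilities, rows = reference base.

    Off-diagonal rows sum to 1; the diagonal is 0. The raw counts matrix is
    retained when the matrix was estimated from calls.
    """

    probs: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4, 4) or (p < 0).any():
            raise ValueError("probs must be a nonnegative 4x4 matrix")
        if not np.allclose(np.diag(p), 0):
            raise ValueError("diagonal must be 0")
        if not np.allclose(p.sum(axis=1), 1):
            raise ValueError("off-diagonal rows must sum to 1")
        self.probs = p

    @classmethod
    def jukes_cantor(cls) -> "MutationMatrix":
        """Equal-rate matrix: every alternate base with probability 1/3."""
        p = np.full((4, 4), 1 / 3)
        np.fill_diagonal(p, 0.0)
        return cls(p)

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "MutationMatrix":
        c = np.asarray(counts, dtype=float)
        p = c.copy()
        np.fill_diagonal(p, 0.0)
        rows = p.sum(axis=1)
        for i in range(4):
            if rows[i] == 0:
                warnings.warn(f"no observations for reference base {_BASES[i]}; uniform row")
                p[i] = 1 / 3
                p[i, i] = 0.0
            else:
                p[i] /= rows[i]
        return cls(p, counts=c)

    def sample_alt(self, ref_base: str, rng: np.random.Generator) -> str:
        i = _BASES.index(ref_base)
        return _BASES[int(rng.choice(4, p=self.probs[i]))]

    def sample_alts(self, ref_codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Vectorized alternate-base codes for an array of reference codes."""
        u = rng.random(len(ref_codes))
        cum = np.cumsum(self.probs, axis=1)
        out = (u[:, None] < cum[ref_codes]).argmax(axis=1)
        return out.astype(np.uint8)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ref\\alt\t" + "\t".join(_BASES) + "\n")
            for i, b in enumerate(_BASES):
                fh.write(b + "\t" + "\t".join(f"{x:.6f}" for x in self.probs[i]) + "\n")


def estimate_mutation_matrix(variants, reference: dict[str, str] | None = None) -> MutationMatrix:
    """Tally SNP ref->alt counts into a base-mutation matrix.

    `variants` is any iterable with .ref/.alt (single-base) attributes, or
    (ref, alt) tuples. Counts stay on the reference strand as printed — no
    pyrimidine collapsing.
    """
    counts = np.zeros((4, 4))
    n = 0
    for v in variants:
        ref, alt = (v if isinstance(v, tuple) else (v.ref, v.alt))
        if len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES and ref != alt:
            counts[_BASES.index(ref), _BASES.index(alt)] += 1
            n += 1
    if n == 0:
        raise ValueError("need at least one SNP to estimate the matrix")
    return MutationMatrix.from_counts(counts)


# --------------------------------------------------------------------------
# Jukes-Cantor correction
# --------------------------------------------------------------------------

def jc_distance(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); valid for 0 <= p < 0.75."""
    if not 0 <= p < 0.75:
        raise ValueError(f"mismatch proportion {p} outside [0, 0.75) (saturated)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def jc_inverse(d: float) -> float:
    """Mismatch proportion recovering a given JC distance."""
    return 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * d))


# --------------------------------------------------------------------------
# coding annotation
# --------------------------------------------------------------------------

EFFECTS = ("synonymous", "missense", "stop_gain", "stop_loss", "start_loss",
           "frameshift", "inframe_indel", "noncoding")
LOF_EFFECTS = {"stop_gain", "frameshift", "start_loss"}
_SEVERITY = {e: i for i, e in enumerate(
    ("noncoding", "synonymous", "inframe_indel", "missense", "stop_loss",
     "start_loss", "frameshift", "stop_gain"))}


@dataclass
class Transcript:
    tx_id: str
    contig: str
    strand: str
    cds: list[tuple[int, int]]  # 0-based half-open genomic CDS segments, sorted

    def __post_init__(self):
        self.cds = sorted(self.cds)
        self.length = sum(e - s for s, e in self.cds)
        self._gpos: np.ndarray | None = None

    def genomic_positions(self) -> np.ndarray:
        """CDS genomic positions in translation order (5'->3' of the mRNA)."""
        if self._gpos is None:
            parts = [np.arange(s, e) for s, e in self.cds]
            g = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
            self._gpos = g[::-1] if self.strand == "-" else g
        return self._gpos


class CodingAnnotation:
    """Per-transcript CDS models with codon-resolved effect classification."""

    def __init__(self, transcripts: list[Transcript], genome: dict[str, str]):
        self.transcripts = transcripts
        self.genome = genome
        self._by_contig: dict[str, list[Transcript]] = {}
        self._cds_pos: dict[str, dict[int, list[tuple[Transcript, int]]]] = {}
        for tx in transcripts:
            if tx.length % 3 != 0:
                warnings.warn(f"CDS length of {tx.tx_id} not divisible by 3; flagged")
            self._by_contig.setdefault(tx.contig, []).append(tx)
            posmap = self._cds_pos.setdefault(tx.contig, {})
            for i, g in enumerate(tx.genomic_positions()):
                posmap.setdefault(int(g), []).append((tx, i))
        self._lookup_cache: dict[str, np.ndarray] | None = None

    @classmethod
    def from_gff3(cls, path, genome: dict[str, str]) -> "CodingAnnotation":
        from .io import read_gff3_cds

        return cls(read_gff3_cds(path), genome)

    # ---------------------------------------------------------------- SNPs
    def classify_snp(self, contig: str, pos0: int, alt: str) -> str:
        """Most severe effect of a single-base substitution across transcripts."""
        hits = self._cds_pos.get(contig, {}).get(pos0)
        if not hits:
            return "noncoding"
        effects = [self._classify_in_tx(tx, i, alt) for tx, i in hits]
        return max(effects, key=lambda e: _SEVERITY[e])

    def classify_snp_per_transcript(self, contig: str, pos0: int, alt: str) -> dict[str, str]:
        hits = self._cds_pos.get(contig, {}).get(pos0, [])
        return {tx.tx_id: self._classify_in_tx(tx, i, alt) for tx, i in hits}

    def _classify_in_tx(self, tx: Transcript, cds_i: int, alt: str) -> str:
        table = _codon_table()
        gpos = tx.genomic_positions()
        codon_i = cds_i // 3
        within = cds_i % 3
        codon_pos = gpos[codon_i * 3 : codon_i * 3 + 3]
        seq = self.genome[tx.contig]
        bases = [seq[p] for p in codon_pos]
        if tx.strand == "-":
            bases = [revcomp(b) for b in bases]
            alt_b = revcomp(alt)
        else:
            alt_b = alt
        ref_codon = "".join(bases)
        alt_codon = ref_codon[:within] + alt_b + ref_codon[within + 1 :]
        aa_ref = table.get(ref_codon, "X")
        aa_alt = table.get(alt_codon, "X")
        if codon_i == 0 and aa_ref == "M" and aa_alt != "M":
            return "start_loss"
        if aa_ref != "*" and aa_alt == "*":
            return "stop_gain"
        if aa_ref == "*" and aa_alt != "*":
            return "stop_loss"
        return "synonymous" if aa_ref == aa_alt else "missense"

    # --------------------------------------------------------------- InDels
    def classify_indel(self, contig: str, pos0: int, ref: str, alt: str) -> str:
        span = range(pos0, pos0 + max(len(ref), 1))
        posmap = self._cds_pos.get(contig, {})
        if not any(p in posmap for p in span):
            return "noncoding"
        return "frameshift" if abs(len(ref) - len(alt)) % 3 else "inframe_indel"

    def classify(self, contig: str, pos0: int, ref: str, alt: str) -> str:
        if len(ref) == 1 and len(alt) == 1:
            return self.classify_snp(contig, pos0, alt)
        return self.classify_indel(contig, pos0, ref, alt)

    def is_lof(self, effect: str) -> bool:
        return effect in LOF_EFFECTS

    # -------------------------------------------------- opportunity counting
    def opportunity_counts(self) -> dict[str, float]:
        """Counts of synonymous / nonsynonymous single-base changes over all
        CDS positions (3 changes per site; stop-affecting changes count as
        nonsynonymous), plus the conventional fractional site totals."""
        tab = self._effect_table()
        syn = nonsyn = 0
        for contig, eff in tab.items():
            syn += int((eff == _SEVERITY["synonymous"]).sum())
            coding = eff >= 0
            nonsyn += int((coding & (eff != _SEVERITY["synonymous"])).sum())
        return {
            "synonymous_changes": syn,
            "nonsynonymous_changes": nonsyn,
            "S_sites": syn / 3.0,
            "N_sites": nonsyn / 3.0,
        }

    def _effect_table(self) -> dict[str, np.ndarray]:
        """(L, 4) int8 per contig: severity code of substituting each alt
        base at each position; -1 = noncoding or the reference base itself."""
        if self._lookup_cache is not None:
            return self._lookup_cache
        out: dict[str, np.ndarray] = {}
        for contig, posmap in self._cds_pos.items():
            seq = self.genome[contig]
            eff = np.full((len(seq), 4), -1, dtype=np.int8)
            for pos in posmap:
                ref_b = seq[pos]
                if ref_b not in _BASES:
                    continue
                for alt_b in _BASES:
                    if alt_b == ref_b:
                        continue
                    e = self.classify_snp(contig, pos, alt_b)
                    eff[pos, _BASES.index(alt_b)] = _SEVERITY[e]
            out[contig] = eff
        # contigs without CDS stay absent; callers treat missing as noncoding
        self._lookup_cache = out
        return out


def annotate_effects(variants, annotation: CodingAnnotation):
    """Effect + LoF flag per variant; returns a pandas DataFrame."""
    import pandas as pd

    rows = []
    for v in variants:
        contig, pos, ref, alt = v.contig, v.pos0, v.ref, v.alt
        if alt.startswith("+"):
            ref_s, alt_s = ref, ref + alt[1:]
        elif alt.startswith("-"):
            n = int(alt[1:])
            ref_s = annotation.genome[contig][pos : pos + 1 + n]
            alt_s = ref_s[0]
        else:
            ref_s, alt_s = ref, alt
        eff = annotation.classify(contig, pos, ref_s, alt_s)
        rows.append((contig, pos, ref_s, alt_s, eff, eff in LOF_EFFECTS))
    return pd.DataFrame(rows, columns=["contig", "pos0", "ref", "alt", "effect", "lof"])


# --------------------------------------------------------------------------
# neutral simulation and normalized dN/dS
# --------------------------------------------------------------------------

@dataclass
class DnDsResult:
    n_obs: int
    s_obs: int
    pn: float
    ps: float
    dn: float
    ds: float
    raw_ratio: float
    neutral_ratios: np.ndarray
    normalized: float
    normalized_sd: float
    ci95: tuple[float, float]
    pseudo_used: bool = False

    @property
    def neutral_mean(self) -> float:
        return float(np.mean(self.neutral_ratios))

    @property
    def neutral_sd(self) -> float:
        return float(np.std(self.neutral_ratios, ddof=1))

    def to_json(self, path) -> None:
        import json

        doc = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in self.__dict__.items()}
        doc["neutral_mean"] = self.neutral_mean
        doc["neutral_sd"] = self.neutral_sd
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def _raw_dnds(n_obs: int, s_obs: int, n_sites: float, s_sites: float,
              pseudo: float = 0.5) -> tuple[float, float, float, float, float, bool]:
    pseudo_used = False
    if s_obs == 0:
        s_obs_eff = pseudo
        pseudo_used = True
    else:
        s_obs_eff = s_obs
    pn = n_obs / n_sites if n_sites else 0.0
    ps = s_obs_eff / s_sites if s_sites else 0.0
    dn = jc_distance(min(pn, 0.7499999))
    ds = jc_distance(min(ps, 0.7499999))
    if ds <= 0:
        return pn, ps, dn, ds, float("nan"), pseudo_used
    return pn, ps, dn, ds, dn / ds, pseudo_used


def count_ns(variants, annotation: CodingAnnotation) -> tuple[int, int]:
    """Observed nonsynonymous and synonymous SNP counts in CDS."""
    n_obs = s_obs = 0
    for v in variants:
        if len(getattr(v, "ref", "N")) != 1 or len(getattr(v, "alt", "NN")) != 1:
            continue
        eff = annotation.classify_snp(v.contig, v.pos0, v.alt)
        if eff == "synonymous":
            s_obs += 1
        elif eff != "noncoding":
            n_obs += 1
    return n_obs, s_obs


def simulate_neutral(
    matrix: MutationMatrix,
    annotation: CodingAnnotation,
    genome: dict[str, str],
    n_mutations: int,
    R: int = 100,
    seed: int = 0,
) -> list[dict]:
    """R neutral replicate mutation sets with their raw dN/dS.

    Positions are uniform over the genome; alternate alleles are drawn from
    the base-mutation matrix row of the reference base. Effects come from a
    precomputed per-position lookup so replicates are cheap.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    rng = stage_rng(seed, "neutral-sim")
    names = sorted(genome)
    lens = np.array([len(genome[n]) for n in names], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lens)])
    codes = {n: encode(genome[n]) for n in names}
    table = annotation._effect_table()
    opp = annotation.opportunity_counts()
    syn_code = _SEVERITY["synonymous"]
    out = []
    for r in range(R):
        g = rng.integers(0, cum[-1], size=n_mutations)
        ci = np.searchsorted(cum, g, side="right") - 1
        n_obs = s_obs = 0
        for name_i in np.unique(ci):
            name = names[name_i]
            pos = (g[ci == name_i] - cum[name_i]).astype(np.int64)
            refc = codes[name][pos]
            valid = refc < 4
            pos, refc = pos[valid], refc[valid]
            altc = matrix.sample_alts(refc, rng)
            eff_tab = table.get(name)
            if eff_tab is None:
                continue
            eff = eff_tab[pos, altc]
            s_obs += int((eff == syn_code).sum())
            n_obs += int(((eff >= 0) & (eff != syn_code)).sum())
        pn, ps, dn, ds, ratio, pseudo = _raw_dnds(n_obs, s_obs, opp["N_sites"], opp["S_sites"])
        out.append({"replicate": r, "n": n_obs, "s": s_obs, "ratio": ratio})
    return out


def normalized_dnds(
    observed_variants,
    annotation: CodingAnnotation,
    neutral_replicates: list[dict],
) -> DnDsResult:
    """Observed dN/dS divided by the mean neutral dN/dS, with replicate
    spread (sd and 2.5-97.5 percentile interval of obs/neutral)."""
    opp = annotation.opportunity_counts()
    n_obs, s_obs = count_ns(observed_variants, annotation)
    pn, ps, dn, ds, raw, pseudo = _raw_dnds(n_obs, s_obs, opp["N_sites"], opp["S_sites"])
    ratios = np.array([rep["ratio"] for rep in neutral_replicates], dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if len(ratios) < 2 or not math.isfinite(raw):
        return DnDsResult(n_obs, s_obs, pn, ps, dn, ds, raw, ratios,
                          float("nan"), float("nan"), (float("nan"), float("nan")), pseudo)
    norm_dist = raw / ratios
    normalized = raw / float(np.mean(ratios))
    lo, hi = np.percentile(norm_dist, [2.5, 97.5])
    return DnDsResult(n_obs, s_obs, pn, ps, dn, ds, raw, ratios,
                      float(normalized), float(np.std(norm_dist, ddof=1)),
                      (float(lo), float(hi)), pseudo)
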