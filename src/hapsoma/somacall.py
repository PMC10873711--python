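"""Somatic variant calling in single-reference and dual-haplotype modes.

"Somatic" here means: a difference from the reference individual's diploid
genome. In single mode, reads are mapped to haplotype A alone and the
expected genotype at each site is the individual's germline genotype (het
at the ~18 SNPs/kb heterozygous background); a somatic mutation shows up as
a departure from that expectation, including tri-allelic sites. In dual
mode both haplotypes are in the reference, the germline heterozygosity
vanishes, and a somatic heterozygous mutation manifests as a near-fixed
allele on one haplotype's pileup — except inside regions identical between
haplotypes, where tie-broken reads from both copies stack on one position
and the mutation appears as a balanced ("collapsed het") column; those are
modelled explicitly and merged by the 150-bp flanking-homology dedup.

Alleles are symbolic: 'A'/'C'/'G'/'T' for SNPs, '+SEQ' for insertions after
the anchor base, '-N' for deletions of the next N reference bases.

Filters follow the quality >= 50 / depth >= 2 rule; positions called on a
mutation-free simulation form the false-positive blacklist.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .homology import HomologyMap
from .pileup import Pileup, PileupColumn
from .seqs import left_normalize

PHRED_CAP = 1000.0


# --------------------------------------------------------------------------
# genotype models
# --------------------------------------------------------------------------

def _log_allele_prob(obs: str, true: str, e: float) -> float:
    return math.log1p(-e) if obs == true else math.log(e / 3.0)


@dataclass
class GenotypeCall:
    contig: str
    pos0: int
    mode: str  # 'single' | 'dual'
    counts: dict[str, int]
    genotype: tuple[str, ...]  # one allele in dual-haploid, two otherwise
    qual: float
    depth: int
    collapsed: bool = False  # dual mode: balanced column in a collapsed region


def genotype_site(column: PileupColumn, mode: str, error_rate: float = 0.002,
                  ref: str = "N", collapsed_gate: float = 0.7) -> GenotypeCall:
    """Maximum-posterior genotype under binomial allele sampling.

    single mode: diploid — hypotheses are all unordered allele pairs from the
    observed alleles plus the reference. dual mode: haploid per chromosome
    copy; when at least `collapsed_gate` of the column's reads are
    ambiguously placed (MAPQ 0), an explicit 50:50 "collapsed het"
    hypothesis joins the model — in a region truly identical between
    haplotypes essentially every read ties between the two copies and
    stacks on one position, so the gate sits high; partial MAPQ0 fractions
    come from interspersed-repeat ambiguity, where the column still
    represents one chromosome copy and must be genotyped haploid. Flat
    prior; qual is the Phred-scaled 1 - posterior of the winning genotype.
    """
    counts = dict(column.base_counts)
    if column.depth < 1 and not counts:
        raise ValueError("genotype_site requires depth >= 1")
    alleles = sorted(set(counts) | {ref})
    e = error_rate
    hyps: list[tuple[tuple[str, ...], bool]] = []
    if mode == "dual":
        hyps += [((a,), False) for a in alleles]
        if column.mapq0_fraction >= collapsed_gate:
            hyps += [(tuple(sorted((ref, a))), True) for a in alleles if a != ref]
    elif mode == "single":
        hyps += [(tuple(sorted(p)), False) for p in itertools.combinations_with_replacement(alleles, 2)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    logls = []
    for gt, _ in hyps:
        ll = 0.0
        for obs, n in counts.items():
            p = sum(math.exp(_log_allele_prob(obs, a, e)) for a in gt) / len(gt)
            ll += n * math.log(p)
        logls.append(ll)
    logls = np.asarray(logls)
    m = logls.max()
    post = np.exp(logls - m)
    post /= post.sum()
    best = int(np.argmax(post))
    gt, collapsed = hyps[best]
    one_minus = max(1.0 - float(post[best]), 10 ** (-PHRED_CAP / 10))
    qual = min(-10.0 * math.log10(one_minus), PHRED_CAP)
    depth = column.depth if column.depth else sum(counts.values())
    return GenotypeCall(column.contig, column.pos0, mode, counts, gt, qual, depth, collapsed)


# --------------------------------------------------------------------------
# calls
# --------------------------------------------------------------------------

def _kind_of(alt: str) -> str:
    if alt.startswith("+"):
        return "INS"
    if alt.startswith("-"):
        return "DEL"
    return "SNP"


@dataclass
class SomaticCall:
    id: str
    mode: str
    contig: str
    pos0: int
    ref: str
    alt: str  # symbolic allele
    kind: str
    support: int
    depth: int
    qual: float
    genotype: tuple[str, ...]
    haplotype: str | None = None  # 'A'/'B' in dual mode; None if collapsed/single
    collapsed: bool = False
    dup_group: int | None = None
    hom_pos: tuple[str, int] | None = None
    filters: set[str] = field(default_factory=set)
    norm_key: tuple | None = None  # left-normalized (contig,pos,ref,alt) for InDels

    @property
    def retained(self) -> bool:
        return not self.filters


@dataclass
class Blacklist:
    positions: set[tuple[str, int]] = field(default_factory=set)
    reason: str = "null-sim artifact"

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for contig, pos in sorted(self.positions):
                fh.write(f"{contig}\t{pos}\t{pos + 1}\t{self.reason}\n")

    @classmethod
    def from_bed(cls, path) -> "Blacklist":
        bl = cls()
        with open(path) as fh:
            for line in fh:
                f = line.split("\t")
                bl.positions.add((f[0], int(f[1])))
        return bl


def germline_genotypes(genome) -> dict[tuple[str, int], tuple[str, str]]:
    """Expected diploid genotype (on haplotype-A coordinates) at every
    germline heterozygous site of the reference individual."""
    out: dict[tuple[str, int], tuple[str, str]] = {}
    for v in genome.germline:
        if v.kind == "SNP":
            out[(v.contig, v.posA)] = tuple(sorted((v.refA, v.altB)))
        elif v.kind == "INS":
            out[(v.contig, v.posA)] = tuple(sorted((v.refA[0], "+" + v.altB[1:])))
        elif v.kind == "DEL":
            out[(v.contig, v.posA)] = tuple(sorted((v.refA[0], f"-{len(v.refA) - 1}")))
        # HAP_SPECIFIC_SEGMENT: hemizygous; single-mode columns look hom-ref
    return out


def _normalize_call(reference: dict[str, str], contig: str, pos0: int, ref: str, alt: str):
    """Left-normalized key for InDel call matching."""
    if _kind_of(alt) == "SNP":
        return (contig, pos0, ref, alt)
    seq = reference[contig]
    anchor = seq[pos0]
    if alt.startswith("+"):
        r, a = anchor, anchor + alt[1:]
    else:
        n = int(alt[1:])
        r, a = seq[pos0 : pos0 + 1 + n], anchor
    p, r, a = left_normalize(seq, pos0, r, a)
    return (contig, p, r, a)


def call_somatic(
    pileup: Pileup,
    reference: dict[str, str],
    mode: str,
    germline: dict[tuple[str, int], tuple[str, str]] | None = None,
    blacklist: Blacklist | None = None,
    min_qual: float = 50.0,
    min_depth: int = 2,
    min_alt: int = 2,
    error_rate: float = 0.002,
    homology: HomologyMap | None = None,
    dedup_flank: int = 150,
) -> list[SomaticCall]:
    """Call somatic variants from a pileup.

    Emits every site whose maximum-posterior genotype differs from the
    expected one (the reference base in dual mode; the individual's germline
    genotype in single mode), then applies BLACKLIST / LOWQUAL / LOWDEPTH
    filters; dual mode finishes with flanking-homology deduplication when a
    homology map is supplied. All calls are returned, filtered ones carry a
    non-empty `filters` set.
    """
    if mode not in ("single", "dual"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "dual" and len(reference) < 2:
        raise ValueError("dual mode requires both haplotypes in the reference")
    germline = germline or {}
    calls: list[SomaticCall] = []
    counter = 0
    for contig, pos in pileup.candidate_sites(min_alt):
        ref_base = reference[contig][pos]
        if ref_base not in "ACGT":
            continue
        col = pileup.column(contig, pos)
        gc = genotype_site(col, mode, error_rate, ref=ref_base)
        if mode == "dual":
            expected: tuple[str, ...] = (ref_base,)
        else:
            expected = germline.get((contig, pos), tuple(sorted((ref_base, ref_base))))
        if gc.genotype == expected:
            continue
        # the somatic allele: prefer a non-reference, non-expected allele
        new_alleles = [a for a in gc.genotype if a != ref_base and a not in expected]
        if not new_alleles:
            # genotype changed but no novel allele (e.g. loss of het) — emit
            # against the highest-count non-ref allele for bookkeeping
            new_alleles = [a for a in gc.genotype if a != ref_base] or [gc.genotype[-1]]
        alt = new_alleles[0]
        support = col.base_counts.get(alt, 0)
        call = SomaticCall(
            id=f"{mode[0]}{counter}",
            mode=mode,
            contig=contig,
            pos0=pos,
            ref=ref_base,
            alt=alt,
            kind=_kind_of(alt),
            support=support,
            depth=col.depth,
            qual=gc.qual,
            genotype=gc.genotype,
            haplotype=(None if gc.collapsed else _haplotype_of_contig(contig)) if mode == "dual" else None,
            collapsed=gc.collapsed,
            norm_key=_normalize_call(reference, contig, pos, ref_base, alt),
        )
        counter += 1
        if blacklist is not None and (contig, pos) in blacklist:
            call.filters.add("BLACKLIST")
        if col.depth < min_depth:
            call.filters.add("LOWDEPTH")
        if gc.qual < min_qual:
            call.filters.add("LOWQUAL")
        calls.append(call)
    if mode == "dual" and homology is not None:
        calls = dedup_homologous(calls, reference, homology, flank=dedup_flank)
    return calls


def _haplotype_of_contig(contig: str) -> str | None:
    if contig.endswith("_A"):
        return "A"
    if contig.endswith("_B"):
        return "B"
    return None


def retained(calls: list[SomaticCall]) -> list[SomaticCall]:
    return [c for c in calls if c.retained]


# --------------------------------------------------------------------------
# flanking-homology deduplication
# --------------------------------------------------------------------------

def dedup_homologous(
    calls: list[SomaticCall],
    reference: dict[str, str],
    homology: HomologyMap,
    flank: int = 150,
) -> list[SomaticCall]:
    """Merge duplicate calls at homologous positions with identical flanks.

    For each dual-mode call, the `flank` bp on both sides of the site and of
    its homologous position on the other haplotype are compared (truncated
    symmetrically at contig ends). If the flank pairs are exactly identical
    the two homologous calls are one mutation seen twice: the call at the
    lexicographically first (haplotype-A) coordinate is kept, the partner is
    flagged DUP, and both share a dup_group. Calls in homology gaps are
    untouched. Idempotent.
    """
    by_pos: dict[tuple[str, int], list[SomaticCall]] = {}
    for c in calls:
        by_pos.setdefault((c.contig, c.pos0), []).append(c)
    group = itertools.count(
        1 + max((c.dup_group or 0 for c in calls), default=0)
    )
    for c in sorted(calls, key=lambda c: (c.contig, c.pos0)):
        if "DUP" in c.filters:
            continue
        hom = homology.lookup(c.contig, c.pos0)
        if hom is None:
            continue
        hc, hp = hom
        if not _flanks_identical(reference, c.contig, c.pos0, hc, hp, flank):
            continue
        c.hom_pos = (hc, hp)
        for partner in by_pos.get((hc, hp), []):
            if partner is c or partner.alt != c.alt:
                continue
            if "DUP" in c.filters:
                break
            # keep the call that passes the other filters; tie-break on the
            # lexicographically first (haplotype-A) coordinate
            c_bad = bool(c.filters - {"DUP"})
            p_bad = bool(partner.filters - {"DUP"})
            if c_bad != p_bad:
                keep, drop = (partner, c) if c_bad else (c, partner)
            else:
                keep, drop = ((c, partner) if (c.contig, c.pos0) <= (partner.contig, partner.pos0)
                              else (partner, c))
            if drop.dup_group is None or "DUP" not in drop.filters:
                gid = keep.dup_group or drop.dup_group or next(group)
                keep.dup_group = gid
                drop.dup_group = gid
                drop.filters.add("DUP")
                keep.hom_pos = (drop.contig, drop.pos0)
                drop.hom_pos = (keep.contig, keep.pos0)
    return calls


def _flanks_identical(reference, contigA, posA, contigB, posB, flank: int) -> bool:
    sa, sb = reference[contigA], reference[contigB]
    left = min(flank, posA, posB)
    right = min(flank, len(sa) - posA - 1, len(sb) - posB - 1)
    return (sa[posA - left : posA] == sb[posB - left : posB]
            and sa[posA + 1 : posA + 1 + right] == sb[posB + 1 : posB + 1 + right])


# --------------------------------------------------------------------------
# blacklist from mutation-free simulation
# --------------------------------------------------------------------------

def build_blacklist(
    genome,
    mode: str,
    coverage: float = 35.0,
    read_len: int = 150,
    insert: tuple[float, float] = (400.0, 60.0),
    error_rate: float = 0.002,
    seed: int = 0,
    mapper=None,
) -> Blacklist:
    """Positions called variant on a mutation-free simulation of the genome.

    Reads are simulated from the untouched diploid genome, mapped in the
    requested mode, and every candidate site whose genotype departs from the
    expectation enters the blacklist (no quality floor: a systematically
    artifact-prone position is blacklisted even when its call quality is
    marginal).
    """
    from .mapping import ReadMapper
    from .pileup import build_pileup
    from .simgen import simulate_reads

    batch = simulate_reads(genome, coverage, read_len, insert, error_rate,
                           seed=seed)
    reference = genome.contigs if mode == "dual" else dict(genome.hapA)
    if mapper is None:
        mapper = ReadMapper(reference)
    recs = mapper.map_pairs(batch, insert_mean=insert[0])
    pp = build_pileup(recs, reference)
    germ = germline_genotypes(genome) if mode == "single" else None
    calls = call_somatic(pp, reference, mode, germline=germ, blacklist=None,
                         min_qual=0.0, min_depth=0, min_alt=2,
                         error_rate=error_rate, homology=None)
    bl = Blacklist({(c.contig, c.pos0) for c in calls})
    return bl
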