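"""Pileup engine: per-column allele counts from alignment records.

SNP alleles are dense numpy count arrays (one row per reference position,
columns A/C/G/T); InDel alleles are sparse, keyed by their anchor column
(the reference base immediately left of the event) with symbolic alleles
'+SEQ' (insertion of SEQ after the anchor) and '-N' (deletion of the next
N reference bases). Depth at a column is the sum of its allele counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .mapping import AlignmentRecord, cigar_ops
from .seqs import encode


@dataclass
class PileupColumn:
    contig: str
    pos0: int
    depth: int
    base_counts: dict[str, int]  # allele -> count (bases and indel symbols)
    mapq0_fraction: float

    @property
    def alleles(self) -> list[tuple[str, int]]:
        return sorted(self.base_counts.items(), key=lambda kv: (-kv[1], kv[0]))


class Pileup:
    """Accumulated allele counts over a reference."""

    def __init__(self, reference: dict[str, str], min_mapq: int = 0, count_mapq0: bool = True):
        self.reference = reference
        self.min_mapq = min_mapq
        self.count_mapq0 = count_mapq0
        self.counts = {n: np.zeros((len(s), 4), dtype=np.int32) for n, s in reference.items()}
        self.mapq0_depth = {n: np.zeros(len(s), dtype=np.int32) for n, s in reference.items()}
        self.indels: dict[tuple[str, int], Counter] = {}
        self.n_rejected = 0
        self.n_aligned_bases = 0

    # ------------------------------------------------------------------
    def add(self, rec: AlignmentRecord) -> None:
        if rec.is_unmapped:
            return
        if rec.mapq < self.min_mapq and not (rec.mapq == 0 and self.count_mapq0):
            return
        contig = rec.contig
        cnt = self.counts.get(contig)
        if cnt is None:
            self.n_rejected += 1
            return
        codes = encode(rec.seq)
        rpos = rec.pos0
        qpos = 0
        is_q0 = rec.mapq == 0
        clen = len(self.reference[contig])
        try:
            for n, op in cigar_ops(rec.cigar):
                if op in "=XM":
                    if rpos + n > clen:
                        raise IndexError
                    seg = codes[qpos : qpos + n]
                    ok = seg < 4
                    idx = np.arange(rpos, rpos + n)[ok]
                    np.add.at(cnt, (idx, seg[ok]), 1)
                    if is_q0:
                        self.mapq0_depth[contig][rpos : rpos + n] += 1
                    self.n_aligned_bases += int(ok.sum())
                    rpos += n
                    qpos += n
                elif op == "I":
                    anchor = rpos - 1
                    if anchor >= 0 and qpos >= 1:
                        # the read's anchor-base observation belongs to the
                        # indel allele, not the reference base
                        if cnt[anchor, codes[qpos - 1]] > 0:
                            cnt[anchor, codes[qpos - 1]] -= 1
                            self.n_aligned_bases -= 1
                        key = (contig, anchor)
                        self.indels.setdefault(key, Counter())["+" + rec.seq[qpos : qpos + n]] += 1
                        self.n_aligned_bases += 1
                    qpos += n
                elif op == "D":
                    anchor = rpos - 1
                    if anchor >= 0 and qpos >= 1:
                        if cnt[anchor, codes[qpos - 1]] > 0:
                            cnt[anchor, codes[qpos - 1]] -= 1
                            self.n_aligned_bases -= 1
                        key = (contig, anchor)
                        self.indels.setdefault(key, Counter())[f"-{n}"] += 1
                        self.n_aligned_bases += 1
                    rpos += n
                elif op in "SH":
                    qpos += n if op == "S" else 0
        except IndexError:
            self.n_rejected += 1

    def add_batch(self, records) -> None:
        for rec in records:
            self.add(rec)

    # ------------------------------------------------------------------
    def column(self, contig: str, pos0: int) -> PileupColumn:
        row = self.counts[contig][pos0]
        bc = {b: int(row[i]) for i, b in enumerate("ACGT") if row[i] > 0}
        for allele, n in self.indels.get((contig, pos0), {}).items():
            bc[allele] = bc.get(allele, 0) + n
        depth = sum(bc.values())
        q0 = int(self.mapq0_depth[contig][pos0])
        return PileupColumn(contig, pos0, depth, bc, min(q0 / depth, 1.0) if depth else 0.0)

    def candidate_sites(self, min_alt: int = 2) -> list[tuple[str, int]]:
        """Columns with >= min_alt reads supporting a non-reference allele."""
        out = set()
        for name, cnt in self.counts.items():
            ref_codes = encode(self.reference[name])
            valid = ref_codes < 4
            depth = cnt.sum(axis=1)
            refn = np.zeros(len(ref_codes), dtype=np.int32)
            refn[valid] = cnt[np.arange(len(ref_codes))[valid], ref_codes[valid]]
            alt = depth - refn
            for p in np.flatnonzero(alt >= min_alt):
                out.add((name, int(p)))
        for (contig, pos), ctr in self.indels.items():
            if sum(ctr.values()) >= min_alt:
                out.add((contig, pos))
        return sorted(out)

    def total_depth(self) -> int:
        """Sum of all column allele counts (base + indel observations)."""
        base = int(sum(c.sum() for c in self.counts.values()))
        ind = sum(sum(ctr.values()) for ctr in self.indels.values())
        return base + ind


def build_pileup(records, reference: dict[str, str], min_mapq: int = 0,
                 count_mapq0: bool = True) -> Pileup:
    pp = Pileup(reference, min_mapq, count_mapq0)
    pp.add_batch(records)
    return pp
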