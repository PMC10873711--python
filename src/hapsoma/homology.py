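"""Homology map between the two haplotypes of a diploid genome.

A map is a set of collinear blocks (contigA, a0, a1) <-> (contigB, b0, b1)
with a constant offset inside each block, plus the unanchored spans that are
haplotype-specific ("gaps"). Lookup is an involution on block interiors.

Two constructors exist: the exact truth map the simulator derives from its
germline variant list, and an anchor-based estimate built from mutually
unique shared k-mers chained collinearly (the route available for real
genomes).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .kmers import unique_kmer_positions
from .seqs import CoordMap


@dataclass
class HomologyMap:
    """Bidirectional piecewise-constant-offset map between haplotypes."""

    # per contig: sorted arrays of block starts/ends and partner info
    _blocks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]] = field(default_factory=dict)
    gap_min: int = 50

    @property
    def blocks(self) -> list[tuple[str, int, int, str, int, int, str]]:
        """(contigA, a0, a1, contigB, b0, b1, strand) for A-side contigs."""
        out = []
        seen = set()
        for ca, (st, en, tg, partners) in sorted(self._blocks.items()):
            for i in range(len(st)):
                cb = partners[i]
                key = tuple(sorted([(ca, int(st[i])), (cb, int(tg[i]))]))
                if key in seen:
                    continue
                seen.add(key)
                out.append((ca, int(st[i]), int(en[i]), cb, int(tg[i]), int(tg[i]) + int(en[i] - st[i]), "+"))
        return out

    def add_block(self, contigA: str, a0: int, a1: int, contigB: str, b0: int) -> None:
        if a1 <= a0:
            raise ValueError("empty block")
        for (c_from, s, cb, t) in ((contigA, a0, contigB, b0), (contigB, b0, contigA, a0)):
            st, en, tg, partners = self._blocks.setdefault(
                c_from, (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64), [])
            )
            i = int(np.searchsorted(st, s))
            self._blocks[c_from] = (
                np.insert(st, i, s),
                np.insert(en, i, s + (a1 - a0)),
                np.insert(tg, i, t),
                partners[:i] + [cb] + partners[i:],
            )

    def lookup(self, contig: str, pos: int):
        """Homologous (contig, pos) on the other haplotype, or None in a gap."""
        entry = self._blocks.get(contig)
        if entry is None:
            return None
        st, en, tg, partners = entry
        i = int(np.searchsorted(st, pos, side="right")) - 1
        if i < 0 or pos >= en[i]:
            return None
        return partners[i], int(tg[i]) + (pos - int(st[i]))

    def lookup_many(self, contig: str, pos: np.ndarray) -> np.ndarray:
        """Vectorized homologous positions (-1 where unmapped). Assumes one
        partner contig per source contig (true for the simulator's genomes)."""
        entry = self._blocks.get(contig)
        out = np.full(len(pos), -1, dtype=np.int64)
        if entry is None:
            return out
        st, en, tg, _ = entry
        i = np.searchsorted(st, pos, side="right") - 1
        ok = (i >= 0) & (pos < en[np.maximum(i, 0)])
        out[ok] = tg[i[ok]] + (pos[ok] - st[i[ok]])
        return out

    def gaps(self, contig_lengths: dict[str, int]) -> list[tuple[str, int, int]]:
        """Unmapped spans >= gap_min bp (haplotype-specific sequence)."""
        out = []
        for contig, length in contig_lengths.items():
            entry = self._blocks.get(contig)
            if entry is None:
                if length >= self.gap_min:
                    out.append((contig, 0, length))
                continue
            st, en, _, _ = entry
            cursor = 0
            for s, e in zip(st, en):
                if s - cursor >= self.gap_min:
                    out.append((contig, int(cursor), int(s)))
                cursor = max(cursor, int(e))
            if length - cursor >= self.gap_min:
                out.append((contig, cursor, length))
        return out

    # ---------------------------------------------------------------- I/O
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#contigA\tstartA\tendA\tcontigB\tstartB\tendB\tstrand\n")
            for b in self.blocks:
                fh.write("\t".join(map(str, b)) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "HomologyMap":
        hm = cls()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                ca, a0, a1, cb, b0, b1, strand = line.rstrip("\n").split("\t")
                hm.add_block(ca, int(a0), int(a1), cb, int(b0))
        return hm

    # ------------------------------------------------------- constructors
    @classmethod
    def from_coord_map(cls, contigA: str, contigB: str, cmap: CoordMap) -> "HomologyMap":
        """Exact truth map from a source->derived coordinate map."""
        hm = cls()
        for s, e, off in zip(cmap.src_starts, cmap.src_ends, cmap.offsets):
            if e > s:
                hm.add_block(contigA, int(s), int(e), contigB, int(s + off))
        return hm


def _longest_increasing_chain(b: np.ndarray) -> np.ndarray:
    """Indices of a longest strictly increasing subsequence of b (patience)."""
    tails: list[int] = []  # value of smallest tail of chains of each length
    tails_idx: list[int] = []
    prev = np.full(len(b), -1, dtype=np.int64)
    for i, v in enumerate(b):
        j = bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        out.append(i)
        i = prev[i]
    return np.asarray(out[::-1], dtype=np.int64)


def build_homology_map(
    hapA: dict[str, str],
    hapB: dict[str, str],
    k_anchor: int = 31,
    gap_min: int = 50,
    max_interp: int = 2000,
) -> "HomologyMap":
    """Anchor-based homology map between two haplotypes.

    Mutually unique shared canonical k-mers are chained collinearly (longest
    increasing chain per contig pair); runs of constant offset become blocks;
    short inter-run intervals are interpolated by extending the flanking
    blocks to the midpoint; unanchored spans >= gap_min bp are left as gaps.
    """
    if k_anchor > 63:
        raise ValueError("k_anchor must be <= 63")
    kmA, posA, fwdA, idxA = unique_kmer_positions(hapA, k_anchor)
    kmB, posB, fwdB, idxB = unique_kmer_positions(hapB, k_anchor)
    hm = HomologyMap(gap_min=gap_min)
    if len(kmA) == 0 or len(kmB) == 0:
        import warnings

        warnings.warn("no anchors found; empty homology map")
        return hm
    shared, ia, ib = np.intersect1d(kmA, kmB, assume_unique=True, return_indices=True)
    if len(shared) == 0:
        import warnings

        warnings.warn("no anchors found; empty homology map")
        return hm
    # keep same-orientation anchors only (collinear '+' chains)
    same = fwdA[ia] == fwdB[ib]
    ga, gb = posA[ia[same]], posB[ib[same]]
    # contig id per anchor
    cA = np.searchsorted(idxA.offsets, ga, side="right") - 1
    cB = np.searchsorted(idxB.offsets, gb, side="right") - 1
    import collections

    pairs = collections.defaultdict(list)
    la = ga - idxA.offsets[cA]
    lb = gb - idxB.offsets[cB]
    for i in range(len(ga)):
        pairs[(int(cA[i]), int(cB[i]))].append(i)
    for (ci, cj), idxs in pairs.items():
        nameA, nameB = idxA.names[ci], idxB.names[cj]
        a = la[idxs]
        b = lb[idxs]
        order = np.argsort(a)
        a, b = a[order], b[order]
        keep = _longest_increasing_chain(b)
        a, b = a[keep], b[keep]
        if len(a) == 0:
            continue
        off = b - a
        # split into runs of constant offset
        run_starts = np.concatenate([[0], np.flatnonzero(np.diff(off) != 0) + 1])
        run_ends = np.concatenate([run_starts[1:], [len(a)]])
        blocks = []  # (a0, a1, b0) anchored spans, end includes k
        for rs, re in zip(run_starts, run_ends):
            blocks.append([int(a[rs]), int(a[re - 1]) + k_anchor, int(b[rs])])
        # stitch runs: interpolate small inter-run spans (same span length on
        # both haplotypes, up to small indel slack); leave divergent spans
        # (haplotype-specific segments) unanchored
        merged = [blocks[0]]
        for blk in blocks[1:]:
            prev = merged[-1]
            gapA = blk[0] - prev[1]
            gapB = blk[2] - (prev[2] + prev[1] - prev[0])
            if gapA < 0 or gapB < 0:  # anchored spans overlap across an offset change
                trim = max(-gapA, -gapB)
                prev[1] -= trim
                if prev[1] <= prev[0]:
                    merged.pop()
                merged.append(blk)
                continue
            if abs(gapA - gapB) < gap_min and max(gapA, gapB) <= max_interp:
                # split the span both haplotypes share; any length imbalance
                # (an InDel between the runs) stays a small unmapped sliver
                ext = min(gapA, gapB) // 2
                prev[1] += ext
                rem = min(gapA, gapB) - ext
                blk[0] -= rem
                blk[2] -= rem
            merged.append(blk)
        # extend chain ends to the contig boundaries
        head = merged[0]
        ext = min(head[0], head[2])
        head[0] -= ext
        head[2] -= ext
        endA = len(hapA[nameA])
        endB = len(hapB[nameB])
        tail = merged[-1]
        ext = min(endA - tail[1], endB - (tail[2] + tail[1] - tail[0]))
        tail[1] += max(0, ext)
        for a0, a1, b0 in merged:
            if a1 > a0 and b0 >= 0:
                hm.add_block(nameA, a0, a1, nameB, b0)
    return hm
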