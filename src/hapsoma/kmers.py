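"""Canonical k-mer indexing, haplotype divergence ratios and ancestry painting.

Canonical form is min(forward, reverse complement) of the 2-bit packed k-mer,
so set membership never depends on strand. k is restricted to odd values
(no palindromic k-mers) up to 31 so a k-mer packs into one uint64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqs import encode

MAX_K = 31  # 2 bits/base in a uint64; k=61 comparisons use the sparse path below


def _check_k(k: int, allow_large: bool = False) -> None:
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if not 11 <= k <= 63:
        raise ValueError(f"k must be in [11, 63], got {k}")
    if k > MAX_K and not allow_large:
        raise ValueError(f"packed index supports k <= {MAX_K}")


def packed_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All forward and reverse-complement packed k-mers of `seq`.

    Returns (fwd, rc) uint64 arrays of length len(seq)-k+1 (empty when the
    sequence is shorter than k).
    """
    codes = encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, e
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    comp = np.uint64(3) - c64
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c64[j : n + j]
        # rc of window [i, i+k): complemented bases in reverse order
        rc |= comp[j : n + j] << np.uint64(2 * j)
    return fwd, rc


def canonical_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical packed k-mers and a flag (True where forward == canonical)."""
    fwd, rc = packed_kmers(seq, k)
    is_fwd = fwd <= rc
    return np.where(is_fwd, fwd, rc), is_fwd


def _string_kmers(seq: str, k: int) -> set[str]:
    """Canonical k-mers as strings; fallback path for k > 31 (e.g. k=61)."""
    from .seqs import revcomp

    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        out.add(min(km, revcomp(km)))
    return out


def kmer_set(seqs: dict[str, str] | str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mers of one sequence or a genome dict."""
    _check_k(k)
    if isinstance(seqs, str):
        seqs = {"_": seqs}
    parts = [canonical_kmers(s, k)[0] for s in seqs.values() if len(s) >= k]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


@dataclass
class KmerIndex:
    """Positional index of every canonical k-mer of a reference.

    Positions are global (concatenated contigs); `contig_of` converts back.
    """

    k: int
    names: list[str]
    offsets: np.ndarray  # contig start offsets in global coords, + total at end
    kmers_sorted: np.ndarray
    pos_sorted: np.ndarray  # global position of each k-mer occurrence
    fwd_sorted: np.ndarray  # canonical == forward at that position

    @classmethod
    def build(cls, seqs: dict[str, str], k: int) -> "KmerIndex":
        _check_k(k)
        names, kms, poss, fwds, offs = [], [], [], [], [0]
        warn_short = []
        for name, seq in seqs.items():
            if len(seq) < k:
                warn_short.append(name)
                continue
            can, is_fwd = canonical_kmers(seq, k)
            names.append(name)
            kms.append(can)
            poss.append(np.arange(len(can), dtype=np.int64) + offs[-1])
            fwds.append(is_fwd)
            offs.append(offs[-1] + len(seq))
        if warn_short:
            import warnings

            warnings.warn(f"contigs shorter than k={k} skipped: {warn_short}")
        if not kms:
            return cls(k, [], np.array([0]), np.empty(0, np.uint64), np.empty(0, np.int64), np.empty(0, bool))
        kmers = np.concatenate(kms)
        pos = np.concatenate(poss)
        fwd = np.concatenate(fwds)
        order = np.argsort(kmers, kind="stable")
        return cls(k, names, np.asarray(offs, dtype=np.int64), kmers[order], pos[order], fwd[order])

    def __len__(self) -> int:
        return len(self.kmers_sorted)

    def contig_of(self, global_pos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, global_pos, side="right")) - 1
        return self.names[i], global_pos - int(self.offsets[i])

    def lookup(self, kmer: np.uint64) -> tuple[np.ndarray, np.ndarray]:
        """(global positions, forward flags) of one canonical k-mer."""
        lo = int(np.searchsorted(self.kmers_sorted, kmer, side="left"))
        hi = int(np.searchsorted(self.kmers_sorted, kmer, side="right"))
        return self.pos_sorted[lo:hi], self.fwd_sorted[lo:hi]

    def lookup_ranges(self, kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized (lo, hi) slice bounds into pos_sorted for many k-mers."""
        lo = np.searchsorted(self.kmers_sorted, kmers, side="left")
        hi = np.searchsorted(self.kmers_sorted, kmers, side="right")
        return lo, hi

    def unique_mask(self) -> np.ndarray:
        """Per-entry flag: k-mer occurs exactly once in the reference."""
        km = self.kmers_sorted
        if len(km) == 0:
            return np.empty(0, dtype=bool)
        same_prev = np.concatenate([[False], km[1:] == km[:-1]])
        same_next = np.concatenate([km[:-1] == km[1:], [False]])
        return ~(same_prev | same_next)


def unique_kmer_positions(seqs: dict[str, str], k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, KmerIndex]:
    """(kmer, global position, fwd flag) for k-mers occurring exactly once."""
    idx = KmerIndex.build(seqs, k)
    m = idx.unique_mask()
    return idx.kmers_sorted[m], idx.pos_sorted[m], idx.fwd_sorted[m], idx


def kmer_divergence(seqsX: dict[str, str] | str, seqsY: dict[str, str] | str, k: int = 21) -> dict:
    """Fraction of X's single-copy canonical k-mers absent from Y.

    The ratio is computed per contig of X and genome-wide; empty or too-short
    contigs report None. Monotone non-decreasing in k for fixed sequences.
    For k <= 31 the packed path is used; k = 61 falls back to string sets.
    """
    _check_k(k, allow_large=True)
    if isinstance(seqsX, str):
        seqsX = {"X": seqsX}
    if isinstance(seqsY, str):
        seqsY = {"Y": seqsY}
    per_contig: dict[str, float | None] = {}
    if k <= MAX_K:
        ykm = kmer_set(seqsY, k)
        # single-copy k-mers across all of X
        idx = KmerIndex.build(seqsX, k)
        uniq = idx.kmers_sorted[idx.unique_mask()]
        pos = idx.pos_sorted[idx.unique_mask()]
        missing_total = 0
        n_total = 0
        for i, name in enumerate(idx.names):
            sel = (pos >= idx.offsets[i]) & (pos < idx.offsets[i + 1])
            kms = uniq[sel]
            if len(kms) == 0:
                per_contig[name] = None
                continue
            found = np.searchsorted(ykm, kms)
            found = (found < len(ykm)) & (ykm[np.minimum(found, len(ykm) - 1)] == kms)
            miss = int((~found).sum())
            per_contig[name] = miss / len(kms)
            missing_total += miss
            n_total += len(kms)
        for name, seq in seqsX.items():
            if name not in per_contig:
                per_contig[name] = None
    else:
        yset: set[str] = set()
        for s in seqsY.values():
            yset |= _string_kmers(s, k)
        from collections import Counter

        counts: Counter = Counter()
        contig_kmers: dict[str, set[str]] = {}
        for name, s in seqsX.items():
            contig_kmers[name] = _string_kmers(s, k)
            counts.update(contig_kmers[name])
        missing_total = 0
        n_total = 0
        for name, kms in contig_kmers.items():
            single = {km for km in kms if counts[km] == 1}
            if not single:
                per_contig[name] = None
                continue
            miss = sum(1 for km in single if km not in yset)
            per_contig[name] = miss / len(single)
            missing_total += miss
            n_total += len(single)
    genome = missing_total / n_total if n_total else None
    return {"k": k, "per_contig": per_contig, "genome_wide": genome, "n_unique_kmers": n_total}


def donor_specific_kmers(donorP: dict[str, str], donorM: dict[str, str], k: int = 21) -> tuple[np.ndarray, np.ndarray]:
    """Donor-diagnostic k-mer sets: kmers(P) \\ kmers(M) and kmers(M) \\ kmers(P)."""
    kp = kmer_set(donorP, k)
    km = kmer_set(donorM, k)
    return np.setdiff1d(kp, km, assume_unique=True), np.setdiff1d(km, kp, assume_unique=True)


def _isin_sorted(values: np.ndarray, sorted_set: np.ndarray) -> np.ndarray:
    if len(sorted_set) == 0:
        return np.zeros(len(values), dtype=bool)
    i = np.searchsorted(sorted_set, values)
    i = np.minimum(i, len(sorted_set) - 1)
    return sorted_set[i] == values


def paint_ancestry(
    target: dict[str, str],
    donorP: dict[str, str],
    donorM: dict[str, str],
    k: int = 21,
    window: int = 50_000,
) -> pd.DataFrame:
    """Per-window donor-specific k-mer fractions for a mosaic genome.

    Each window of the target contributes fractions (P, M, unassigned) that
    sum to 1; the majority donor per window is also reported.
    """
    if window < k:
        raise ValueError(f"window ({window}) must be >= k ({k})")
    p_spec, m_spec = donor_specific_kmers(donorP, donorM, k)
    rows = []
    for name, seq in target.items():
        can, _ = canonical_kmers(seq, k)
        if len(can) == 0:
            continue
        starts = np.arange(0, len(seq), window)
        for s in starts:
            e = min(s + window, len(seq))
            kms = can[s : max(s, e - k + 1)]
            if len(kms) == 0:
                continue
            in_p = _isin_sorted(kms, p_spec)
            in_m = _isin_sorted(kms, m_spec)
            fp = in_p.mean()
            fm = in_m.mean()
            fu = 1.0 - fp - fm
            maj = "P" if fp > fm else ("M" if fm > fp else "NA")
            rows.append((name, int(s), int(e), fp, fm, fu, maj))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "frac_P", "frac_M", "frac_unassigned", "majority"])
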