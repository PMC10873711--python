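"""Low-level sequence utilities: encoding, reverse complement, variant splicing.

Coordinates are 0-based half-open throughout the library; 1-based only on
VCF/SAM output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def encode(seq: str | bytes) -> np.ndarray:
    """Sequence -> uint8 codes A=0 C=1 G=2 T=3 (non-ACGT -> 255)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate_seq(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases i.i.d. at `rate`; returns the diverged copy."""
    codes = encode(seq).copy()
    hits = np.flatnonzero(rng.random(len(codes)) < rate)
    if hits.size:
        codes[hits] = (codes[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return decode(codes)


@dataclass(frozen=True)
class SeqVariant:
    """A difference applied to a source sequence (VCF-style anchored ref/alt)."""

    pos0: int
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNP"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"


@dataclass
class CoordMap:
    """Piecewise-linear coordinate map from a source to a derived sequence.

    Positions deleted in the derived sequence map to None.
    """

    src_starts: np.ndarray  # block starts in source coords
    src_ends: np.ndarray
    offsets: np.ndarray  # derived = source + offset inside block
    src_len: int
    dst_len: int

    def lookup(self, pos: int):
        i = int(np.searchsorted(self.src_ends, pos, side="right"))
        if i >= len(self.src_starts) or pos < self.src_starts[i]:
            return None
        return pos + int(self.offsets[i])

    def lookup_many(self, pos: np.ndarray) -> np.ndarray:
        """Vectorized lookup; unmapped positions become -1."""
        i = np.searchsorted(self.src_ends, pos, side="right")
        ok = (i < len(self.src_starts)) & (pos >= self.src_starts[np.minimum(i, len(self.src_starts) - 1)])
        out = np.full(len(pos), -1, dtype=np.int64)
        out[ok] = pos[ok] + self.offsets[i[ok]]
        return out


def apply_variants(seq: str, variants: list[SeqVariant]) -> tuple[str, CoordMap]:
    """Splice non-overlapping variants (sorted by pos0) into `seq`.

    Returns the derived sequence and the source->derived coordinate map.
    For non-SNP variants the anchor base maps through; ref bases beyond the
    alt length are unmapped (deleted).
    """
    variants = sorted(variants, key=lambda v: v.pos0)
    pieces: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    offsets: list[int] = []
    src = 0  # cursor in source
    dst = 0  # cursor in derived
    block_start = 0
    for v in variants:
        if v.pos0 < src:
            raise ValueError(f"overlapping variants at {v.pos0}")
        if seq[v.pos0 : v.pos0 + len(v.ref)] != v.ref:
            raise ValueError(f"ref mismatch at {v.pos0}: {v.ref!r}")
        # copy invariant stretch + substitute
        pieces.append(seq[src : v.pos0])
        pieces.append(v.alt)
        dst += v.pos0 - src
        src = v.pos0
        if v.kind == "SNP":
            src += 1
            dst += 1
            continue  # offset unchanged; block continues
        # close the identity block through the anchor base (shared prefix)
        shared = 1 if v.ref[0] == v.alt[0] else 0
        starts.append(block_start)
        ends.append(v.pos0 + shared)
        offsets.append(dst - src)
        src += len(v.ref)
        dst += len(v.alt)
        block_start = src
    pieces.append(seq[src:])
    starts.append(block_start)
    ends.append(len(seq))
    offsets.append(dst - src)
    dst += len(seq) - src
    derived = "".join(pieces)
    return derived, CoordMap(
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.asarray(offsets, dtype=np.int64),
        src_len=len(seq),
        dst_len=len(derived),
    )


def left_normalize(seq: str, pos0: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Shift an anchored InDel to its leftmost equivalent position (VCF style)."""
    if len(ref) == len(alt):
        return pos0, ref, alt
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if ref[-1] == alt[-1] and pos0 > 0:
            prev = seq[pos0 - 1]
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos0 -= 1
            continue
        break
    return pos0, ref, alt
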