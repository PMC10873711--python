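"""Synthetic diploid genomes, clonal populations and paired-end reads.

The generator emulates a sweet-orange-like diploid: two haplotypes that
differ by dense heterozygous SNPs (~18/kb in aligned regions), heterozygous
short InDels, and large haplotype-specific segments; each haplotype is a
mosaic of two donor ancestries (pummelo-like "P" and mandarin-like "M");
somatic mutations accumulate along a clonal propagation tree and are
heterozygous by construction (present on exactly one haplotype).

Citrus genomes are heavily repetitive, and mapping artifacts inside repeats
are what the false-positive blacklist and flanking-homology deduplication
exist for, so the default preset also lays down interspersed repeat
families: a mixture of young (near-identical) and older (1-15% diverged)
copies covering roughly 45% of the sequence.

Every product carries full ground truth: the germline variant list, the
exact homology map between haplotypes, ancestry blocks, the somatic truth
list keyed by clone-tree branch, and per-read origin coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._rng import stage_rng
from .homology import HomologyMap
from .seqs import CoordMap, SeqVariant, apply_variants, mutate_seq, random_seq, revcomp


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestryBlock:
    haplotype_id: str  # 'A' or 'B'
    contig: str
    start: int
    end: int
    donor: str  # 'P' or 'M'


@dataclass(frozen=True)
class GermlineHetVariant:
    contig: str  # haplotype-A contig
    posA: int
    kind: str  # SNP | INS | DEL | HAP_SPECIFIC_SEGMENT
    refA: str
    altB: str
    length: int


@dataclass(frozen=True)
class SomaticMutation:
    id: str
    haplotype_id: str
    contig: str  # contig of the carrying haplotype
    pos0: int
    ref: str
    alt: str
    kind: str  # SNP | INS | DEL
    branch_id: str


@dataclass
class CloneTree:
    """Rooted clone-propagation tree; every non-root node owns the branch
    above it, and a leaf carries exactly the mutations on its root path."""

    parent: dict[str, str | None]
    outgroup: set[str] = field(default_factory=set)
    branch_budget: dict[str, int] | None = None

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self.root = roots[0]
        self.children: dict[str, list[str]] = {n: [] for n in self.parent}
        for n, p in self.parent.items():
            if p is not None:
                if p not in self.parent:
                    raise ValueError(f"parent {p} of {n} is not a node")
                self.children[p].append(n)
        # cycle check: every node must reach the root
        for n in self.parent:
            seen = set()
            while n is not None:
                if n in seen:
                    raise ValueError("tree contains a cycle")
                seen.add(n)
                n = self.parent[n]
        unknown = self.outgroup - self.leaves
        if unknown:
            raise ValueError(f"outgroup ids are not leaves: {unknown}")

    @property
    def leaves(self) -> set[str]:
        return {n for n, ch in self.children.items() if not ch}

    @property
    def branches(self) -> list[str]:
        """Branch ids = non-root nodes (the edge above each)."""
        return sorted(n for n, p in self.parent.items() if p is not None)

    def path_branches(self, leaf: str) -> list[str]:
        out = []
        n = leaf
        while self.parent[n] is not None:
            out.append(n)
            n = self.parent[n]
        return out[::-1]

    def shared_branches(self, leaf1: str, leaf2: str) -> list[str]:
        return [b for b in self.path_branches(leaf1) if b in set(self.path_branches(leaf2))]

    # ------------------------------------------------------------- factories
    @classmethod
    def linear(cls, n_leaves: int = 1) -> "CloneTree":
        parent: dict[str, str | None] = {"root": None}
        for i in range(n_leaves):
            parent[f"acc{i}"] = "root"
        return cls(parent)

    @classmethod
    def balanced(cls, depth: int) -> "CloneTree":
        parent: dict[str, str | None] = {"n0": None}
        frontier = ["n0"]
        counter = 1
        for _ in range(depth):
            nxt = []
            for node in frontier:
                for _ in range(2):
                    name = f"n{counter}"
                    counter += 1
                    parent[name] = node
                    nxt.append(name)
            frontier = nxt
        # rename leaves to accession ids
        leaves = frontier
        for i, lf in enumerate(leaves):
            parent[f"acc{i}"] = parent.pop(lf)
        return cls(parent)

    @classmethod
    def with_outgroup_clade(cls, n_outgroup: int = 8, n_ingroup: int = 8) -> "CloneTree":
        """Root splits into an outgroup clade and an ingroup clade, mirroring
        the polarization design (Earlier-Clade-I style outgroup)."""
        parent: dict[str, str | None] = {"root": None, "outclade": "root", "inclade": "root"}
        out = set()
        for i in range(n_outgroup):
            parent[f"out{i}"] = "outclade"
            out.add(f"out{i}")
        for i in range(n_ingroup):
            parent[f"in{i}"] = "inclade"
        return cls(parent, outgroup=out)

    def to_newick(self) -> str:
        def sub(node: str) -> str:
            ch = self.children[node]
            if not ch:
                return node
            return "(" + ",".join(sub(c) for c in sorted(ch)) + ")" + node

        return sub(self.root) + ";"


@dataclass
class DiploidGenome:
    hapA: dict[str, str]
    hapB: dict[str, str]
    homology: HomologyMap
    germline: list[GermlineHetVariant]
    ancestry: list[AncestryBlock]
    seed: int
    donors: dict[str, dict[str, str]] | None = None
    coord_maps: dict[str, CoordMap] = field(default_factory=dict)  # base contig -> A->B map

    @property
    def contigs(self) -> dict[str, str]:
        return {**self.hapA, **self.hapB}

    @property
    def hapA_len(self) -> int:
        return sum(len(s) for s in self.hapA.values())

    def haplotype_of(self, contig: str) -> str:
        if contig in self.hapA:
            return "A"
        if contig in self.hapB:
            return "B"
        raise KeyError(contig)

    def write_fasta(self, path) -> None:
        from .io import write_fasta

        write_fasta(path, self.contigs)


@dataclass
class GenomeConfig:
    """Sweet-orange-like defaults: ~18 het SNPs/kb in aligned regions, het
    InDels at a tenth of the SNP rate, a few multi-kb haplotype-specific
    segments, ~45% interspersed repeats, two-donor mosaic ancestry."""

    contigs: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    snp_rate: float = 0.018
    indel_rate: float = 0.0018
    indel_max_len: int = 20
    indel_geom_p: float = 0.5
    n_hap_specific_segments: int = 4
    hap_specific_len: tuple[int, int] = (5_000, 20_000)
    ancestry_block_mean: int = 100_000
    donor_divergence: float = 0.02
    repeat_fraction: float = 0.45
    n_repeat_families: int = 8
    repeat_len_range: tuple[int, int] = (500, 5_000)
    young_repeat_fraction: float = 0.3
    young_divergence_max: float = 0.005
    old_divergence_range: tuple[float, float] = (0.01, 0.15)
    unique_segment_mean: int = 2_000
    keep_donors: bool = True
    seed: int = 0


# --------------------------------------------------------------------------
# genome generation
# --------------------------------------------------------------------------

def _repeat_structured_seq(rng: np.random.Generator, length: int, cfg: GenomeConfig) -> str:
    """Random sequence interleaving unique segments with repeat-family copies."""
    if cfg.repeat_fraction <= 0:
        return random_seq(rng, length)
    lo, hi = cfg.repeat_len_range
    families = [random_seq(rng, int(rng.integers(lo, hi + 1))) for _ in range(cfg.n_repeat_families)]
    parts: list[str] = []
    total = 0
    while total < length:
        if rng.random() < cfg.repeat_fraction:
            fam = families[int(rng.integers(len(families)))]
            if rng.random() < cfg.young_repeat_fraction:
                div = rng.uniform(0.0, cfg.young_divergence_max)
            else:
                div = rng.uniform(*cfg.old_divergence_range)
            piece = mutate_seq(rng, fam, div)
        else:
            piece = random_seq(rng, int(rng.exponential(cfg.unique_segment_mean)) + 200)
        parts.append(piece)
        total += len(piece)
    return "".join(parts)[:length]


def _sample_ancestry_blocks(rng: np.random.Generator, contig: str, length: int, cfg: GenomeConfig,
                            haplotype_id: str) -> list[AncestryBlock]:
    blocks = []
    pos = 0
    donor = "P" if rng.random() < 0.5 else "M"
    while pos < length:
        blen = max(10_000, int(rng.exponential(cfg.ancestry_block_mean)))
        end = min(pos + blen, length)
        blocks.append(AncestryBlock(haplotype_id, contig, pos, end, donor))
        donor = "M" if donor == "P" else "P"
        pos = end
    return blocks


def _sample_germline_variants(rng: np.random.Generator, seq: str, cfg: GenomeConfig,
                              n_segments: int) -> list[SeqVariant]:
    L = len(seq)
    variants: list[tuple[int, str, str, str]] = []  # (pos, ref, alt, kind)
    snp_pos = np.flatnonzero(rng.random(L) < cfg.snp_rate)
    from .seqs import encode, decode

    codes = encode(seq)
    alt_codes = (codes[snp_pos] + rng.integers(1, 4, size=len(snp_pos))) % 4
    for p, a in zip(snp_pos, alt_codes):
        variants.append((int(p), seq[p], decode(np.array([a], dtype=np.uint8)), "SNP"))
    indel_pos = np.flatnonzero(rng.random(L) < cfg.indel_rate)
    for p in indel_pos:
        p = int(p)
        ln = min(int(rng.geometric(cfg.indel_geom_p)), cfg.indel_max_len)
        if rng.random() < 0.5 and p + ln + 1 < L:  # deletion in B
            ref = seq[p : p + 1 + ln]
            variants.append((p, ref, ref[0], "DEL"))
        else:  # insertion in B
            variants.append((p, seq[p], seq[p] + random_seq(rng, ln), "INS"))
    lo, hi = cfg.hap_specific_len
    for i in range(n_segments):
        ln = int(rng.integers(lo, hi + 1))
        p = int(rng.integers(1, max(2, L - ln - 1)))
        if i % 2 == 0 and p + ln + 1 < L:  # segment present only on A (deleted in B)
            ref = seq[p : p + 1 + ln]
            variants.append((p, ref, ref[0], "HAP_SPECIFIC_SEGMENT"))
        else:  # segment present only on B (inserted)
            variants.append((p, seq[p], seq[p] + random_seq(rng, ln), "HAP_SPECIFIC_SEGMENT"))
    # drop overlaps (keep first by position; stable under the seed)
    variants.sort(key=lambda v: v[0])
    kept: list[tuple[int, str, str, str]] = []
    cursor = -1
    for v in variants:
        if v[0] <= cursor:
            continue
        kept.append(v)
        cursor = v[0] + len(v[1]) - 1
    return [SeqVariant(p, r, a) for p, r, a, _ in kept], kept


def generate_diploid(config: GenomeConfig | None = None, **overrides) -> DiploidGenome:
    """Generate a two-haplotype genome with full ground truth.

    hapB is derived from hapA by sampled heterozygous variants, so reapplying
    the germline list to hapA reconstructs hapB byte-for-byte, and the truth
    homology map is exact by construction. Identical seed => identical genome.
    """
    cfg = config or GenomeConfig()
    if overrides:
        cfg = GenomeConfig(**{**asdict(cfg), **overrides})
    if not 0 <= cfg.snp_rate < 0.75:
        raise ValueError(f"snp_rate must be in [0, 0.75) (Jukes-Cantor saturation), got {cfg.snp_rate}")
    if not 0 <= cfg.indel_rate < 0.75:
        raise ValueError(f"indel_rate must be in [0, 0.75), got {cfg.indel_rate}")
    for name, ln in cfg.contigs.items():
        if ln < 10_000:
            raise ValueError(f"contig {name} shorter than 10 kb")

    rng_seq = stage_rng(cfg.seed, "base-sequence")
    rng_anc = stage_rng(cfg.seed, "ancestry")
    rng_var = stage_rng(cfg.seed, "germline")

    hapA: dict[str, str] = {}
    hapB: dict[str, str] = {}
    germline: list[GermlineHetVariant] = []
    ancestry: list[AncestryBlock] = []
    donors: dict[str, dict[str, str]] = {"P": {}, "M": {}}
    homology = HomologyMap()
    coord_maps: dict[str, CoordMap] = {}

    total_len = sum(cfg.contigs.values())
    seg_alloc = {
        name: round(cfg.n_hap_specific_segments * ln / total_len) for name, ln in cfg.contigs.items()
    }

    for name, length in cfg.contigs.items():
        base = _repeat_structured_seq(rng_seq, length, cfg)
        donorP = mutate_seq(rng_seq, base, cfg.donor_divergence / 2)
        donorM = mutate_seq(rng_seq, base, cfg.donor_divergence / 2)
        donors["P"][name] = donorP
        donors["M"][name] = donorM
        nameA, nameB = f"{name}_A", f"{name}_B"
        blocksA = _sample_ancestry_blocks(rng_anc, nameA, length, cfg, "A")
        seqA = "".join(
            (donorP if b.donor == "P" else donorM)[b.start : b.end] for b in blocksA
        )
        variants, kept = _sample_germline_variants(rng_var, seqA, cfg, seg_alloc.get(name, 0))
        seqB, cmap = apply_variants(seqA, variants)
        hapA[nameA] = seqA
        hapB[nameB] = seqB
        coord_maps[name] = cmap
        ancestry.extend(blocksA)
        for b in blocksA:  # hapB inherits the mosaic through the homology map
            b0 = cmap.lookup(b.start)
            b1 = cmap.lookup(max(b.start, b.end - 1))
            if b0 is not None and b1 is not None and b1 >= b0:
                ancestry.append(AncestryBlock("B", nameB, b0, b1 + 1, b.donor))
        for p, ref, alt, kind in kept:
            germline.append(
                GermlineHetVariant(nameA, int(p), kind, ref, alt, abs(len(alt) - len(ref)) or 1)
            )
        part = HomologyMap.from_coord_map(nameA, nameB, cmap)
        for ca, a0, a1, cb, b0, b1, strand in part.blocks:
            homology.add_block(ca, a0, a1, cb, b0)

    return DiploidGenome(hapA, hapB, homology, germline, ancestry, cfg.seed,
                         donors if cfg.keep_donors else None, coord_maps)


# --------------------------------------------------------------------------
# somatic spiking along a clone tree
# --------------------------------------------------------------------------

def spike_somatic(
    genome: DiploidGenome,
    tree: CloneTree | None = None,
    n_mutations: int = 600,
    matrix=None,
    indel_fraction: float = 0.1,
    seed: int = 0,
    min_margin: int = 200,
) -> list[SomaticMutation]:
    """Sample heterozygous somatic mutations uniformly over both haplotypes.

    Each mutation lands on exactly one haplotype and one clone-tree branch
    (uniformly, unless the tree carries per-branch budgets). Position
    collisions are resampled, never overwritten. Returns the truth list.
    """
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    if n_mutations == 0:
        return []
    tree = tree or CloneTree.linear(1)
    rng = stage_rng(seed, "somatic-spike")
    contigs = genome.contigs
    names = sorted(contigs)
    lens = np.array([len(contigs[n]) for n in names], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lens)])
    total = int(cum[-1])

    branches = tree.branches
    if tree.branch_budget:
        budget = [tree.branch_budget.get(b, 0) for b in branches]
        if sum(budget) != n_mutations:
            raise ValueError("branch budgets must sum to n_mutations")
        branch_of = np.repeat(np.arange(len(branches)), budget)
        rng.shuffle(branch_of)
    else:
        branch_of = rng.integers(0, len(branches), size=n_mutations)

    if matrix is None:
        from .selscan import MutationMatrix

        matrix = MutationMatrix.jukes_cantor()

    used: dict[str, set[int]] = {n: set() for n in names}
    out: list[SomaticMutation] = []
    i = 0
    attempts = 0
    while i < n_mutations:
        attempts += 1
        if attempts > 50 * n_mutations:
            raise RuntimeError("could not place somatic mutations without collisions")
        g = int(rng.integers(min_margin, total - min_margin))
        ci = int(np.searchsorted(cum, g, side="right")) - 1
        name = names[ci]
        pos = g - int(cum[ci])
        seq = contigs[name]
        if pos < min_margin or pos > len(seq) - min_margin:
            continue
        if pos in used[name]:
            continue
        ref_base = seq[pos]
        if rng.random() < indel_fraction:
            ln = min(int(rng.geometric(0.5)), 20)
            if rng.random() < 0.5:
                if any(p in used[name] for p in range(pos, pos + ln + 1)):
                    continue
                ref = seq[pos : pos + 1 + ln]
                alt = ref[0]
                kind = "DEL"
                span = range(pos, pos + ln + 1)
            else:
                ref = ref_base
                alt = ref_base + random_seq(rng, ln)
                kind = "INS"
                span = (pos,)
        else:
            alt = matrix.sample_alt(ref_base, rng)
            ref = ref_base
            kind = "SNP"
            span = (pos,)
        used[name].update(span)
        hap = genome.haplotype_of(name)
        out.append(
            SomaticMutation(f"som{i}", hap, name, pos, ref, alt, kind, branches[int(branch_of[i])])
        )
        i += 1
    return out


@dataclass
class AccessionGenome:
    """One clonal accession: the diploid genome with its root-path somatic
    mutations applied, plus coordinate maps back to the reference contigs."""

    accession: str
    contigs: dict[str, str]
    mutations: list[SomaticMutation]
    ref_to_acc: dict[str, CoordMap]
    hapA_names: set[str]
    hapB_names: set[str]

    @property
    def hapA_len(self) -> int:
        return sum(len(self.contigs[n]) for n in self.hapA_names)


def build_accession_genome(genome: DiploidGenome, truth: list[SomaticMutation],
                           tree: CloneTree, leaf: str) -> AccessionGenome:
    carried_branches = set(tree.path_branches(leaf))
    muts = [m for m in truth if m.branch_id in carried_branches]
    by_contig: dict[str, list[SomaticMutation]] = {}
    for m in muts:
        by_contig.setdefault(m.contig, []).append(m)
    contigs: dict[str, str] = {}
    maps: dict[str, CoordMap] = {}
    for name, seq in genome.contigs.items():
        vs = [SeqVariant(m.pos0, m.ref, m.alt) for m in by_contig.get(name, [])]
        if vs:
            newseq, cmap = apply_variants(seq, vs)
        else:
            newseq, cmap = seq, CoordMap(
                np.array([0]), np.array([len(seq)]), np.array([0]), len(seq), len(seq)
            )
        contigs[name] = newseq
        maps[name] = cmap
    return AccessionGenome(leaf, contigs, muts, maps,
                           set(genome.hapA), set(genome.hapB))


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadPair:
    id: str
    mate1_seq: str
    mate2_seq: str
    qual: str
    truth1: tuple[str, str, int, str]  # (haplotype, contig, pos0, strand)
    truth2: tuple[str, str, int, str]


@dataclass
class ReadBatch:
    """Paired reads with per-mate truth origins, kept column-wise."""

    read_len: int
    seq1: list[str]
    seq2: list[str]
    contig1: list[str]
    pos1: np.ndarray
    strand1: list[str]
    contig2: list[str]
    pos2: np.ndarray
    strand2: list[str]
    hap_of: dict[str, str]

    def __len__(self) -> int:
        return len(self.seq1)

    def __iter__(self):
        q = "?" * self.read_len  # constant Q30 (Phred+33); errors are seeded independently
        for i in range(len(self.seq1)):
            yield ReadPair(
                f"r{i}",
                self.seq1[i],
                self.seq2[i],
                q,
                (self.hap_of[self.contig1[i]], self.contig1[i], int(self.pos1[i]), self.strand1[i]),
                (self.hap_of[self.contig2[i]], self.contig2[i], int(self.pos2[i]), self.strand2[i]),
            )

    def write_fastq(self, path1, path2) -> None:
        q = "?" * self.read_len
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i in range(len(self.seq1)):
                f1.write(f"@r{i}/1\n{self.seq1[i]}\n+\n{q}\n")
                f2.write(f"@r{i}/2\n{self.seq2[i]}\n+\n{q}\n")

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#read\tmate\thaplotype\tcontig\tpos0\tstrand\n")
            for i in range(len(self.seq1)):
                c1, c2 = self.contig1[i], self.contig2[i]
                fh.write(f"r{i}\t1\t{self.hap_of[c1]}\t{c1}\t{self.pos1[i]}\t{self.strand1[i]}\n")
                fh.write(f"r{i}\t2\t{self.hap_of[c2]}\t{c2}\t{self.pos2[i]}\t{self.strand2[i]}\n")


def simulate_reads(
    genome,
    coverage: float,
    read_len: int = 150,
    insert: tuple[float, float] = (400.0, 60.0),
    error_rate: float = 0.002,
    seed: int = 0,
) -> ReadBatch:
    """Paired-end reads at `coverage` fold, normalized to one haplotype.

    Total bases = coverage x len(hapA); both chromosome copies are sampled
    equally, so each copy sees ~coverage/2. Substitution errors are i.i.d.
    per base at `error_rate`; base qualities are constant (errors are not
    quality-dependent). `genome` needs .contigs, .hapA_len and hapA/hapB
    membership (DiploidGenome or AccessionGenome).
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    mean_ins, sd_ins = insert
    if mean_ins < read_len:
        raise ValueError(f"insert mean ({mean_ins}) must be >= read length ({read_len})")
    if isinstance(genome, AccessionGenome):
        a_names, b_names = sorted(genome.hapA_names), sorted(genome.hapB_names)
    else:
        a_names, b_names = sorted(genome.hapA), sorted(genome.hapB)
    contigs = genome.contigs
    hap_of = {n: "A" for n in a_names}
    hap_of.update({n: "B" for n in b_names})

    n_pairs = int(round(coverage * genome.hapA_len / (2 * read_len)))
    rng = stage_rng(seed, "reads")
    batch = ReadBatch(read_len, [], [], [], np.zeros(n_pairs, dtype=np.int64), [],
                      [], np.zeros(n_pairs, dtype=np.int64), [], hap_of)
    if n_pairs == 0:
        return batch

    def weights(names):
        w = np.array([len(contigs[n]) for n in names], dtype=float)
        return w / w.sum()

    wA, wB = weights(a_names), weights(b_names)
    pick_hap = rng.random(n_pairs) < 0.5
    isizes = np.clip(rng.normal(mean_ins, sd_ins, size=n_pairs), read_len, None).astype(np.int64)
    flip = rng.random(n_pairs) < 0.5
    nerr1 = rng.binomial(read_len, error_rate, size=n_pairs)
    nerr2 = rng.binomial(read_len, error_rate, size=n_pairs)
    choiceA = rng.choice(len(a_names), size=n_pairs, p=wA)
    choiceB = rng.choice(len(b_names), size=n_pairs, p=wB)

    for i in range(n_pairs):
        name = a_names[choiceA[i]] if pick_hap[i] else b_names[choiceB[i]]
        seq = contigs[name]
        isize = min(int(isizes[i]), len(seq))
        start = int(rng.integers(0, len(seq) - isize + 1))
        frag = seq[start : start + isize]
        left = frag[:read_len]
        right = revcomp(frag[-read_len:])
        lpos, rpos = start, start + isize - read_len
        if flip[i]:
            m1, m2 = right, left
            c1 = c2 = name
            p1, p2, s1, s2 = rpos, lpos, "-", "+"
            ne1, ne2 = nerr1[i], nerr2[i]
        else:
            m1, m2 = left, right
            c1 = c2 = name
            p1, p2, s1, s2 = lpos, rpos, "+", "-"
            ne1, ne2 = nerr1[i], nerr2[i]
        if ne1:
            m1 = _inject_errors(rng, m1, int(ne1))
        if ne2:
            m2 = _inject_errors(rng, m2, int(ne2))
        batch.seq1.append(m1)
        batch.seq2.append(m2)
        batch.contig1.append(c1)
        batch.contig2.append(c2)
        batch.pos1[i] = p1
        batch.pos2[i] = p2
        batch.strand1.append(s1)
        batch.strand2.append(s2)
    return batch


def _inject_errors(rng: np.random.Generator, seq: str, n: int) -> str:
    pos = rng.choice(len(seq), size=n, replace=False)
    s = list(seq)
    for p in pos:
        cur = "ACGT".index(s[p]) if s[p] in "ACGT" else 0
        s[p] = "ACGT"[(cur + int(rng.integers(1, 4))) % 4]
    return "".join(s)


@dataclass
class PopulationSim:
    genome: DiploidGenome
    tree: CloneTree
    truth: list[SomaticMutation]
    accessions: dict[str, AccessionGenome]
    reads: dict[str, ReadBatch]


def simulate_clonal_population(
    genome: DiploidGenome,
    tree: CloneTree,
    n_mutations: int = 600,
    matrix=None,
    indel_fraction: float = 0.1,
    coverage: float = 0.0,
    read_len: int = 150,
    insert: tuple[float, float] = (400.0, 60.0),
    error_rate: float = 0.002,
    seed: int = 0,
) -> PopulationSim:
    """Spike mutations along the tree and (optionally) simulate per-leaf reads.

    With coverage 0 no reads are simulated (truth + accession genomes only).
    Leaf-shared mutation structure matches the tree exactly: a leaf carries
    the union of mutations on its root-path branches.
    """
    truth = spike_somatic(genome, tree, n_mutations, matrix, indel_fraction, seed)
    accessions = {}
    reads = {}
    for j, leaf in enumerate(sorted(tree.leaves)):
        acc = build_accession_genome(genome, truth, tree, leaf)
        accessions[leaf] = acc
        if coverage > 0:
            reads[leaf] = simulate_reads(acc, coverage, read_len, insert, error_rate,
                                         seed=stage_seed_for_leaf(seed, leaf))
    return PopulationSim(genome, tree, truth, accessions, reads)


def stage_seed_for_leaf(seed: int, leaf: str) -> int:
    from ._rng import stage_seed

    return stage_seed(seed, f"leaf-{leaf}")


def write_manifest(path, config: GenomeConfig, extra: dict | None = None) -> None:
    doc = {"config": asdict(config)}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)


# --------------------------------------------------------------------------
# on-disk genome bundle (FASTA + truth tables)
# --------------------------------------------------------------------------

def save_genome(genome: DiploidGenome, outdir) -> None:
    """Genome bundle: FASTA, germline/ancestry TSV, homology TSV, manifest."""
    import os

    os.makedirs(outdir, exist_ok=True)
    from .io import write_fasta

    write_fasta(os.path.join(outdir, "genome.fasta"), genome.contigs)
    with open(os.path.join(outdir, "germline.tsv"), "w") as fh:
        fh.write("#contig\tpos1\tkind\trefA\taltB\tlength\n")
        for v in genome.germline:
            fh.write(f"{v.contig}\t{v.posA + 1}\t{v.kind}\t{v.refA}\t{v.altB}\t{v.length}\n")
    with open(os.path.join(outdir, "ancestry.tsv"), "w") as fh:
        fh.write("#haplotype\tcontig\tstart\tend\tdonor\n")
        for b in genome.ancestry:
            fh.write(f"{b.haplotype_id}\t{b.contig}\t{b.start}\t{b.end}\t{b.donor}\n")
    genome.homology.to_tsv(os.path.join(outdir, "homology.tsv"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump({"seed": genome.seed,
                   "hapA": sorted(genome.hapA), "hapB": sorted(genome.hapB)}, fh, indent=2)
    if genome.donors:
        for donor, seqs in genome.donors.items():
            write_fasta(os.path.join(outdir, f"donor_{donor}.fasta"), seqs)


def load_genome(indir) -> DiploidGenome:
    import os

    from .homology import HomologyMap
    from .io import read_fasta

    with open(os.path.join(indir, "manifest.json")) as fh:
        manifest = json.load(fh)
    contigs = read_fasta(os.path.join(indir, "genome.fasta"))
    hapA = {n: contigs[n] for n in manifest["hapA"]}
    hapB = {n: contigs[n] for n in manifest["hapB"]}
    germline = []
    with open(os.path.join(indir, "germline.tsv")) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            c, p, k, r, a, ln = line.rstrip("\n").split("\t")
            germline.append(GermlineHetVariant(c, int(p) - 1, k, r, a, int(ln)))
    ancestry = []
    anc_path = os.path.join(indir, "ancestry.tsv")
    if os.path.exists(anc_path):
        with open(anc_path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                h, c, s, e, d = line.rstrip("\n").split("\t")
                ancestry.append(AncestryBlock(h, c, int(s), int(e), d))
    hm = HomologyMap.from_tsv(os.path.join(indir, "homology.tsv"))
    donors = None
    if os.path.exists(os.path.join(indir, "donor_P.fasta")):
        donors = {d: read_fasta(os.path.join(indir, f"donor_{d}.fasta")) for d in ("P", "M")}
    return DiploidGenome(hapA, hapB, hm, germline, ancestry, manifest["seed"], donors)


def write_truth_tsv(path, truth: list[SomaticMutation]) -> None:
    with open(path, "w") as fh:
        fh.write("#id\thaplotype\tcontig\tpos1\tref\talt\tkind\tbranch\n")
        for m in truth:
            fh.write(f"{m.id}\t{m.haplotype_id}\t{m.contig}\t{m.pos0 + 1}\t"
                     f"{m.ref}\t{m.alt}\t{m.kind}\t{m.branch_id}\n")


def read_truth_tsv(path) -> list[SomaticMutation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            i, h, c, p, r, a, k, b = line.rstrip("\n").split("\t")
            out.append(SomaticMutation(i, h, c, int(p) - 1, r, a, k, b))
    return out
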