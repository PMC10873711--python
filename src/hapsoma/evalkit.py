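"""Method evaluation: recall / precision / F1 and genotype correctness for
the three mapping assumptions, across a coverage sweep.

The three modes mirror the evaluation design:
  single_genotype — single-reference mapping scored on position AND exact
                    diploid genotype;
  single_position — the same calls scored on position only;
  dual            — haplotype-resolved mapping scored on haplotype-resolved
                    position and allele (a deduplicated call in a collapsed
                    identical region counts for the mutation it represents).

Truth mutations on haplotype B are projected to haplotype-A coordinates
through the truth homology map for the single-reference modes; truth
positions falling in haplotype-specific gaps are unreachable there and are
reported separately (they still count against recall: they are mutations
the strategy cannot see).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import stage_seed
from .homology import HomologyMap
from .seqs import left_normalize
from .simgen import DiploidGenome, SomaticMutation

MODES = ("single_genotype", "single_position", "dual")


@dataclass
class EvalResult:
    mode: str
    coverage: float
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f1: float
    genotype_correct_fraction: float
    unreachable: int = 0
    n_truth: int = 0

    @classmethod
    def from_counts(cls, mode, coverage, tp, fp, fn, gt_correct, n_truth, unreachable=0):
        recall = tp / n_truth if n_truth else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        f1 = (2 * recall * precision / (recall + precision)) if recall + precision else 0.0
        return cls(mode, coverage, tp, fp, fn, recall, precision, f1,
                   gt_correct / n_truth if n_truth else 0.0, unreachable, n_truth)


# --------------------------------------------------------------------------
# truth bookkeeping
# --------------------------------------------------------------------------

def _truth_norm_key(genome: DiploidGenome, m: SomaticMutation):
    """Left-normalized (contig, pos, ref, alt) on the carrying haplotype."""
    seq = genome.contigs[m.contig]
    p, r, a = left_normalize(seq, m.pos0, m.ref, m.alt)
    return (m.contig, p, r, a)


def _call_symbolic_to_strings(reference: dict[str, str], c) -> tuple[int, str, str]:
    if c.alt.startswith("+"):
        return c.pos0, c.ref, c.ref + c.alt[1:]
    if c.alt.startswith("-"):
        n = int(c.alt[1:])
        seq = reference[c.contig]
        return c.pos0, seq[c.pos0 : c.pos0 + 1 + n], seq[c.pos0]
    return c.pos0, c.ref, c.alt


def _project_truth_single(genome: DiploidGenome, m: SomaticMutation):
    """Truth position on haplotype-A coordinates, or None if unreachable."""
    if m.haplotype_id == "A":
        return (m.contig, m.pos0)
    hom = genome.homology.lookup(m.contig, m.pos0)
    return None if hom is None else hom


def _expected_single_genotype(genome: DiploidGenome, m: SomaticMutation,
                              posA: tuple[str, int]) -> tuple[str, ...] | None:
    """Truth diploid genotype at the projected haplotype-A site (symbolic)."""
    contigA, pA = posA
    baseA = genome.hapA[contigA][pA]
    if m.kind == "SNP":
        if m.haplotype_id == "A":
            other = _hapB_allele_at(genome, contigA, pA)
            return tuple(sorted((m.alt, other))) if other else None
        return tuple(sorted((baseA, m.alt)))
    # InDels: expected genotype = somatic indel allele + the other copy's allele
    if m.kind == "INS":
        som = "+" + m.alt[1:]
    else:
        som = f"-{len(m.ref) - 1}"
    if m.haplotype_id == "A":
        other = _hapB_allele_at(genome, contigA, pA)
        return tuple(sorted((som, other))) if other else None
    return tuple(sorted((baseA, som)))


def _hapB_allele_at(genome: DiploidGenome, contigA: str, pA: int) -> str | None:
    """Haplotype B's symbolic allele at a haplotype-A coordinate."""
    cache = getattr(genome, "_germ_lookup", None)
    if cache is None:
        cache = {(v.contig, v.posA): v for v in genome.germline}
        genome._germ_lookup = cache
    v = cache.get((contigA, pA))
    if v is not None:
        if v.kind == "SNP":
            return v.altB
        if v.kind == "INS":
            return "+" + v.altB[1:]
        if v.kind == "DEL":
            return f"-{len(v.refA) - 1}"
        return None  # hemizygous segment
    hom = genome.homology.lookup(contigA, pA)
    if hom is None:
        return None
    return genome.hapB[hom[0]][hom[1]]


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def evaluate_calls(
    calls: list,
    truth: list[SomaticMutation],
    genome: DiploidGenome,
    mode: str,
    coverage: float = float("nan"),
    indel_window: int = 40,
) -> EvalResult:
    """Score retained calls against the spiked truth set.

    SNPs match on exact position + allele. InDels match when the retained
    InDel calls within +-`indel_window` bp reconstruct exactly the mutated
    local haplotype — pairwise alignment can fragment one InDel into
    equivalent representations, so reconstruction, not allele identity, is
    the robust criterion. See module docstring for per-mode genotype
    semantics.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    retained = [c for c in calls if c.retained]
    if mode == "dual":
        return _evaluate_dual(retained, truth, genome, coverage, indel_window)
    return _evaluate_single(retained, truth, genome, mode, coverage, indel_window)


def _apply_in_window(window_seq: str, events: list[tuple[int, str, str]]) -> str | None:
    """Apply (relative pos, ref, alt) events to a window; None on conflict."""
    from .seqs import SeqVariant, apply_variants

    try:
        derived, _ = apply_variants(window_seq, [SeqVariant(p, r, a) for p, r, a in events])
    except ValueError:
        return None
    return derived


def _window_events(reference, calls, contig, w0, w1, homology=None):
    """InDel calls falling inside [w0, w1) of `contig`, expressed as window-
    relative (pos, ref, alt) events; calls at homologous coordinates on the
    other haplotype (deduplication keeps one side) are mapped through."""
    events = []
    used = []
    for c in calls:
        if c.kind == "SNP":
            continue
        pos = None
        if c.contig == contig and w0 <= c.pos0 < w1:
            pos = c.pos0
        elif homology is not None and c.contig != contig:
            hom = homology.lookup(c.contig, c.pos0)
            if hom is not None and hom[0] == contig and w0 <= hom[1] < w1:
                pos = hom[1]
        if pos is None:
            continue
        _, ref_s, alt_s = _call_symbolic_to_strings(reference, c)
        if pos + len(ref_s) <= w1:
            events.append((pos - w0, reference[contig][pos : pos + len(ref_s)], alt_s))
            used.append(c)
    return events, used


def _match_indel_by_window(m, genome, retained, reference, contig, anchor,
                           homology=None, win: int = 40):
    """True + matched calls when the retained InDel calls around the truth
    site reconstruct exactly the mutated local haplotype (robust to
    alignment-representation fragmentation of InDels)."""
    seq = reference[contig]
    w0 = max(0, anchor - win)
    w1 = min(len(seq), anchor + len(m.ref) + win)
    if m.haplotype_id is not None and contig == m.contig:
        ref_str, alt_str = m.ref, m.alt
    else:
        # projected coordinates: deletion spans the homologous bases
        span = len(m.ref)
        ref_str = seq[anchor : anchor + span]
        alt_str = ref_str[0] + m.alt[1:] if len(m.alt) > 1 else ref_str[:1]
        if m.kind == "INS":
            alt_str = ref_str + m.alt[1:]
            ref_str = seq[anchor : anchor + 1]
            alt_str = ref_str + m.alt[1:]
    expected = _apply_in_window(seq[w0:w1], [(anchor - w0, ref_str, alt_str)])
    events, used = _window_events(reference, retained, contig, w0, w1, homology)
    if expected is None or not events:
        return False, []
    observed = _apply_in_window(seq[w0:w1], sorted(events))
    return observed == expected, used


def _evaluate_dual(retained, truth, genome, coverage, win):
    reference = genome.contigs
    snp_calls = {(c.contig, c.pos0, c.alt): c for c in retained if c.kind == "SNP"}
    indel_retained = [c for c in retained if c.kind != "SNP"]
    tp = 0
    gt_correct = 0
    matched_calls = set()
    for m in truth:
        if m.kind == "SNP":
            cand = snp_calls.get((m.contig, m.pos0, m.alt))
            if cand is None:
                hom = genome.homology.lookup(m.contig, m.pos0)
                if hom is not None:
                    cand = snp_calls.get((hom[0], hom[1], m.alt))
            if cand is None:
                continue
            tp += 1
            matched_calls.add(id(cand))
            if cand.collapsed or cand.contig == m.contig:
                # a collapsed merged call represents the heterozygous
                # mutation; haplotype is unresolvable there by construction
                gt_correct += 1
        else:
            ok, used = _match_indel_by_window(m, genome, indel_retained, reference,
                                              m.contig, m.pos0, genome.homology, win)
            if not ok:
                continue
            tp += 1
            matched_calls.update(id(c) for c in used)
            if all(c.collapsed or c.contig == m.contig or
                   (c.hom_pos is not None and c.hom_pos[0] == m.contig) for c in used):
                gt_correct += 1
    fp = len(retained) - len(matched_calls)
    fn = len(truth) - tp
    return EvalResult.from_counts("dual", coverage, tp, fp, fn, gt_correct, len(truth))


def _evaluate_single(retained, truth, genome, mode, coverage, win):
    reference = dict(genome.hapA)
    snp_calls = {(c.contig, c.pos0): c for c in retained if c.kind == "SNP"}
    indel_retained = [c for c in retained if c.kind != "SNP"]
    pos_calls: dict[tuple[str, int], list] = {}
    for c in retained:
        pos_calls.setdefault((c.contig, c.pos0), []).append(c)
    tp = 0
    gt_correct = 0
    unreachable = 0
    matched_calls = set()
    for m in truth:
        posA = _project_truth_single(genome, m)
        if posA is None:
            unreachable += 1
            continue
        if mode == "single_position":
            tol = 0 if m.kind == "SNP" else win // 2
            cand = None
            for d in range(tol + 1):
                for p in (posA[1] - d, posA[1] + d):
                    if (posA[0], p) in pos_calls:
                        cand = pos_calls[(posA[0], p)][0]
                        break
                if cand:
                    break
            if cand is None:
                continue
            tp += 1
            matched_calls.add(id(cand))
            continue
        if m.kind == "SNP":
            cand = snp_calls.get(posA)
            if cand is None or cand.alt != m.alt:
                continue
            tp += 1
            matched_calls.add(id(cand))
            expected = _expected_single_genotype(genome, m, posA)
            if expected is not None and tuple(cand.genotype) == expected:
                gt_correct += 1
        else:
            m_proj = SomaticMutation(m.id, None, posA[0], posA[1], m.ref, m.alt,
                                     m.kind, m.branch_id)
            ok, used = _match_indel_by_window(m_proj, genome, indel_retained,
                                              reference, posA[0], posA[1], None, win)
            if not ok:
                continue
            tp += 1
            matched_calls.update(id(c) for c in used)
            # het-ness: every contributing call keeps a non-indel allele
            if all(any(not (a.startswith("+") or a.startswith("-")) for a in c.genotype)
                   and c.genotype[0] != c.genotype[1] for c in used):
                gt_correct += 1
    fp = len(retained) - len(matched_calls)
    fn = len(truth) - tp
    return EvalResult.from_counts(mode, coverage, tp, fp, fn, gt_correct,
                                  len(truth), unreachable)


# --------------------------------------------------------------------------
# pipeline orchestration
# --------------------------------------------------------------------------

@dataclass
class StudyResult:
    """One full simulation-study run at a fixed coverage."""

    results: dict[str, EvalResult]
    n_truth: int
    n_retained: dict[str, int]
    blacklist_sizes: dict[str, int]

    def as_dict(self) -> dict:
        return {m: asdict(r) for m, r in self.results.items()}


def run_calling(
    genome: DiploidGenome,
    truth: list[SomaticMutation],
    coverage: float,
    seed: int,
    read_len: int = 150,
    insert: tuple[float, float] = (400.0, 60.0),
    error_rate: float = 0.002,
    min_qual: float = 50.0,
    min_depth: int = 2,
    modes: tuple[str, ...] = MODES,
    blacklists: dict[str, object] | None = None,
    mappers: dict[str, object] | None = None,
) -> StudyResult:
    """Simulate reads for the accession carrying `truth`, run both mapping
    strategies, call, filter, dedup, and score all requested modes."""
    from .mapping import ReadMapper
    from .pileup import build_pileup
    from .simgen import CloneTree, build_accession_genome, simulate_reads
    from .somacall import build_blacklist, call_somatic, germline_genotypes

    tree = CloneTree.linear(1)
    acc = build_accession_genome(genome, truth, tree, "acc0")
    batch = simulate_reads(acc, coverage, read_len, insert, error_rate, seed=seed)

    need_dual = "dual" in modes
    need_single = any(m.startswith("single") for m in modes)
    mappers = mappers or {}
    blacklists = blacklists or {}
    results: dict[str, EvalResult] = {}
    n_retained: dict[str, int] = {}
    bl_sizes: dict[str, int] = {}

    if need_dual:
        ref = genome.contigs
        mapper = mappers.get("dual") or ReadMapper(ref)
        bl = blacklists.get("dual")
        if bl is None:
            bl = build_blacklist(genome, "dual", coverage, read_len, insert,
                                 error_rate, seed=stage_seed(seed, "null-dual"),
                                 mapper=mapper)
        recs = mapper.map_pairs(batch, insert_mean=insert[0])
        pp = build_pileup(recs, ref)
        calls = call_somatic(pp, ref, "dual", blacklist=bl, min_qual=min_qual,
                             min_depth=min_depth, error_rate=error_rate,
                             homology=genome.homology)
        results["dual"] = evaluate_calls(calls, truth, genome, "dual", coverage)
        n_retained["dual"] = sum(c.retained for c in calls)
        bl_sizes["dual"] = len(bl)
    if need_single:
        ref1 = dict(genome.hapA)
        mapper1 = mappers.get("single") or ReadMapper(ref1)
        bl1 = blacklists.get("single")
        if bl1 is None:
            bl1 = build_blacklist(genome, "single", coverage, read_len, insert,
                                  error_rate, seed=stage_seed(seed, "null-single"),
                                  mapper=mapper1)
        recs1 = mapper1.map_pairs(batch, insert_mean=insert[0])
        pp1 = build_pileup(recs1, ref1)
        calls1 = call_somatic(pp1, ref1, "single", germline=germline_genotypes(genome),
                              blacklist=bl1, min_qual=min_qual, min_depth=min_depth,
                              error_rate=error_rate)
        for m in modes:
            if m.startswith("single"):
                results[m] = evaluate_calls(calls1, truth, genome, m, coverage)
        n_retained["single"] = sum(c.retained for c in calls1)
        bl_sizes["single"] = len(bl1)
    return StudyResult(results, len(truth), n_retained, bl_sizes)


def run_simulation_study(
    seed: int,
    contig_length: int = 1_000_000,
    n_mutations: int = 600,
    coverage: float = 35.0,
    **kwargs,
) -> dict:
    """The full scaled-down simulation study at one coverage.

    Generates the sweet-orange-like diploid genome, spikes heterozygous
    somatic SNPs/InDels, simulates paired reads, runs dual- and
    single-reference calling with blacklists, filters and dedup, and scores
    the three evaluation modes. Returns the headline percentages:
    dual-mode position+genotype recall, single-reference position recall,
    and single-reference genotype-correct fraction.
    """
    from .simgen import CloneTree, GenomeConfig, generate_diploid, spike_somatic

    genome = generate_diploid(GenomeConfig(contigs={"chr1": contig_length}, seed=seed))
    truth = spike_somatic(genome, CloneTree.linear(1), n_mutations,
                          seed=stage_seed(seed, "spike"))
    study = run_calling(genome, truth, coverage, seed=stage_seed(seed, "study"), **kwargs)
    r = study.results
    n_single = study.n_retained.get("single", 0)
    return {
        "dual_recall_pct": 100.0 * r["dual"].recall,
        "dual_genotype_recall_pct": 100.0 * r["dual"].genotype_correct_fraction,
        "single_position_recall_pct": 100.0 * r["single_position"].recall,
        "single_genotype_correct_pct": 100.0 * r["single_genotype"].genotype_correct_fraction,
        "single_genotype_recall_pct": 100.0 * r["single_genotype"].recall,
        "map_size_ratio_dual_over_single": (study.n_retained.get("dual", 0) / n_single
                                            if n_single else float("nan")),
        "n_truth": study.n_truth,
        "results": study.as_dict(),
    }


def coverage_sweep(
    genome: DiploidGenome,
    truth: list[SomaticMutation],
    coverages: tuple[float, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50),
    modes: tuple[str, ...] = MODES,
    seeds: tuple[int, ...] = (0,),
    **kwargs,
) -> pd.DataFrame:
    """One EvalResult per (mode, coverage, seed); blacklists and mappers are
    rebuilt per coverage (the null simulation is coverage-matched)."""
    from .mapping import ReadMapper

    rows = []
    mappers = {"dual": ReadMapper(genome.contigs), "single": ReadMapper(dict(genome.hapA))}
    for cov in coverages:
        for sd in seeds:
            study = run_calling(genome, truth, cov, seed=stage_seed(sd, f"cov{cov}"),
                                modes=modes, mappers=mappers, **kwargs)
            for m, r in study.results.items():
                d = asdict(r)
                d["seed"] = sd
                rows.append(d)
    return pd.DataFrame(rows)


def compare_strategies(sweep: pd.DataFrame, plateau_tol: float = 0.01) -> dict:
    """Per-mode plateau summary and cross-mode ordering checks.

    The plateau coverage is the smallest coverage whose recall is within
    `plateau_tol` of the max-coverage recall (per mode, averaged over
    seeds). Flags any violated expected ordering.
    """
    summary: dict = {"modes": {}, "violations": []}
    by_mode = sweep.groupby("mode")
    for mode, df in by_mode:
        mean = df.groupby("coverage", as_index=True).agg(
            recall=("recall", "mean"),
            genotype_correct=("genotype_correct_fraction", "mean"),
            precision=("precision", "mean"),
            f1=("f1", "mean"),
        ).sort_index()
        max_cov = mean.index.max()
        target = mean.loc[max_cov, "recall"] - plateau_tol
        plateau = next((c for c in mean.index if mean.loc[c, "recall"] >= target), max_cov)
        summary["modes"][mode] = {
            "plateau_coverage": float(plateau),
            "plateau_recall": float(mean.loc[plateau, "recall"]),
            "max_recall": float(mean.loc[max_cov, "recall"]),
            "genotype_correct_at_plateau": float(mean.loc[plateau, "genotype_correct"]),
            "by_coverage": mean.reset_index().to_dict("records"),
        }
    m = summary["modes"]
    if {"single_position", "single_genotype"} <= m.keys():
        if m["single_position"]["plateau_recall"] < m["single_genotype"]["plateau_recall"] - 1e-9:
            summary["violations"].append("single_position recall < single_genotype recall")
    if {"dual", "single_genotype"} <= m.keys():
        d = m["dual"]["genotype_correct_at_plateau"]
        s = m["single_genotype"]["genotype_correct_at_plateau"]
        if d < s - 1e-9:
            summary["violations"].append("dual genotype-correct < single genotype-correct")
    missing = set(MODES) - set(m)
    if missing:
        summary["warning"] = f"missing modes: {sorted(missing)}"
    return summary


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
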