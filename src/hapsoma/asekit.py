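"""Allele-specific expression (ASE) and extreme ASE (EASE) classification.

Reads overlapping heterozygous coding SNPs vote for the haplotype whose
allele they carry; per-gene haplotype read counts are tested against a
50:50 binomial, FDR-corrected within each developmental stage
(Benjamini-Hochberg). A gene is ASE at FDR < 0.05; EASE additionally
requires fold-change > 2 between alleles, > 100 reads for the highly
expressed allele, and FDR < 0.001. EASE genes are finally associated with
heterozygous structural variants in the 3-kb putative promoter upstream of
the transcription start site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# --------------------------------------------------------------------------
# allelic counting
# --------------------------------------------------------------------------

def count_alleles(
    alignments,
    het_snps: pd.DataFrame,
    genes: pd.DataFrame,
    stage: str = "stage1",
    replicate: str = "rep1",
) -> pd.DataFrame:
    """Assign reads to haplotypes by majority vote over covered het SNPs.

    `het_snps` columns: contig, pos0, allele_A, allele_B, gene_id (phased to
    haplotypes). `genes` columns: gene_id (used to restrict/label genes and
    count het coding SNPs). Ties are discarded but counted. Genes with no
    covered het SNP are excluded. Returns an AllelicCountTable-style frame
    with columns gene_id, stage, replicate, count_A, count_B, n_ties,
    n_het_coding_snps.
    """
    snp_by_site = {}
    for row in het_snps.itertuples(index=False):
        snp_by_site[(row.contig, int(row.pos0))] = (row.allele_A, row.allele_B, row.gene_id)
    votes: dict[str, list[int]] = {}  # gene -> [A, B, ties]
    for rec in alignments:
        if getattr(rec, "is_unmapped", False):
            continue
        a_votes: dict[str, int] = {}
        b_votes: dict[str, int] = {}
        gene_hit = None
        rpos = rec.pos0
        qpos = 0
        from .mapping import cigar_ops

        for n, op in cigar_ops(rec.cigar):
            if op in "=XM":
                for j in range(n):
                    site = (rec.contig, rpos + j)
                    snp = snp_by_site.get(site)
                    if snp is None:
                        continue
                    base = rec.seq[qpos + j]
                    a, b, gene = snp
                    gene_hit = gene
                    if base == a:
                        a_votes[gene] = a_votes.get(gene, 0) + 1
                    elif base == b:
                        b_votes[gene] = b_votes.get(gene, 0) + 1
                rpos += n
                qpos += n
            elif op == "I":
                qpos += n
            elif op == "D":
                rpos += n
        if gene_hit is None:
            continue
        for gene in set(a_votes) | set(b_votes):
            av, bv = a_votes.get(gene, 0), b_votes.get(gene, 0)
            rec_votes = votes.setdefault(gene, [0, 0, 0])
            if av > bv:
                rec_votes[0] += 1
            elif bv > av:
                rec_votes[1] += 1
            else:
                rec_votes[2] += 1
    n_snps = het_snps.groupby("gene_id").size().to_dict()
    rows = []
    for gene, (a, b, t) in sorted(votes.items()):
        rows.append((gene, stage, replicate, a, b, t, n_snps.get(gene, 0)))
    return pd.DataFrame(rows, columns=["gene_id", "stage", "replicate", "count_A",
                                       "count_B", "n_ties", "n_het_coding_snps"])


# --------------------------------------------------------------------------
# ASE / EASE statistics
# --------------------------------------------------------------------------

def test_ase(
    table: pd.DataFrame,
    alpha_ase: float = 0.05,
    pool_replicates: bool = True,
    stratify_by_stage: bool = True,
) -> pd.DataFrame:
    """Two-sided exact binomial test of allelic balance per gene per stage.

    Replicates are pooled by default; FDR (Benjamini-Hochberg) is applied
    across genes within each stage (or globally with
    stratify_by_stage=False). Genes with no het coding SNP are excluded from
    testing. Adds p_value, fdr, fold_change (high/low allele; inf when the
    low allele has zero reads), high_haplotype and the ASE flag.
    """
    df = table[table["n_het_coding_snps"] > 0].copy()
    if pool_replicates:
        df = (df.groupby(["gene_id", "stage"], as_index=False)
                .agg(count_A=("count_A", "sum"), count_B=("count_B", "sum"),
                     n_het_coding_snps=("n_het_coding_snps", "max")))
    out = []
    for row in df.itertuples(index=False):
        a, b = int(row.count_A), int(row.count_B)
        n = a + b
        if n < 1:
            continue
        p = stats.binomtest(a, n, 0.5, alternative="two-sided").pvalue
        hi, lo = max(a, b), min(a, b)
        fold = float("inf") if lo == 0 else hi / lo
        out.append((row.gene_id, row.stage, a, b, p, fold,
                    "A" if a >= b else "B", hi))
    res = pd.DataFrame(out, columns=["gene_id", "stage", "count_A", "count_B",
                                     "p_value", "fold_change", "high_haplotype",
                                     "high_count"])
    if res.empty:
        res["fdr"] = []
        res["ase"] = []
        return res
    res["fdr"] = np.nan
    groups = res.groupby("stage").groups if stratify_by_stage else {"all": res.index}
    for _, idx in groups.items():
        res.loc[idx, "fdr"] = multipletests(res.loc[idx, "p_value"], method="fdr_bh")[1]
    res["ase"] = res["fdr"] < alpha_ase
    return res


def classify_ease(
    results: pd.DataFrame,
    fold_threshold: float = 2.0,
    min_high_count: int = 100,
    alpha_ease: float = 0.001,
) -> pd.DataFrame:
    """EASE flag: fold-change > 2 AND high-allele reads > 100 AND FDR < 0.001.

    All inequalities are strict, so a fold-change of exactly 2 or a high
    count of exactly 100 does not qualify.
    """
    res = results.copy()
    res["ease"] = (
        (res["fold_change"] > fold_threshold)
        & (res["high_count"] > min_high_count)
        & (res["fdr"] < alpha_ease)
    )
    return res


# --------------------------------------------------------------------------
# promoter SV association
# --------------------------------------------------------------------------

def promoter_sv_association(
    ease_genes: pd.DataFrame,
    het_svs: pd.DataFrame,
    gene_models: pd.DataFrame,
    promoter: int = 3_000,
    include_gene_body: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Flag EASE genes with a heterozygous SV in the putative promoter.

    The promoter is the `promoter` bp upstream of the transcription start
    site on the coding strand: [TSS - 3000, TSS) for '+' genes,
    (TES, TES + 3000] equivalent for '-' genes. `het_svs` columns:
    contig, start, end. `gene_models` columns: gene_id, contig, start, end,
    strand. Genes without strand are skipped with a warning. Returns the
    per-gene flag table and the flagged fraction.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for sv in het_svs.itertuples(index=False):
        trees.setdefault(sv.contig, IntervalTree()).addi(int(sv.start), max(int(sv.end), int(sv.start) + 1))
    gm = gene_models.set_index("gene_id")
    rows = []
    skipped = []
    for gene in ease_genes["gene_id"]:
        if gene not in gm.index:
            skipped.append(gene)
            continue
        info = gm.loc[gene]
        strand = info.get("strand", None)
        if strand not in ("+", "-"):
            skipped.append(gene)
            continue
        if strand == "+":
            lo, hi = int(info.start) - promoter, int(info.start)
        else:
            lo, hi = int(info.end), int(info.end) + promoter
        tree = trees.get(info.contig, IntervalTree())
        flagged = bool(tree.overlap(max(lo, 0), max(hi, 1)))
        if include_gene_body and not flagged:
            flagged = bool(tree.overlap(int(info.start), int(info.end)))
        rows.append((gene, flagged))
    if skipped:
        import warnings

        warnings.warn(f"genes skipped (missing model or strand): {skipped}")
    out = pd.DataFrame(rows, columns=["gene_id", "promoter_sv"])
    frac = float(out["promoter_sv"].mean()) if len(out) else float("nan")
    return out, frac
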