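"""Standard-format I/O: FASTA, FASTQ, SAM, VCF 4.2, GFF3, BED.

Reading of external files goes through pysam / Biopython / gffutils;
writing of our own records is plain text in the standard layouts.
"""

from __future__ import annotations

import pandas as pd


# ------------------------------------------------------------------ FASTA
def write_fasta(path, seqs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------ FASTQ
def read_fastq_pairs(path1, path2) -> tuple[list[str], list[str], list[str]]:
    """(ids, mate1 seqs, mate2 seqs) from a FASTQ pair."""
    import pysam

    ids, s1, s2 = [], [], []
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        for r1, r2 in zip(f1, f2):
            ids.append(r1.name.split("/")[0])
            s1.append(r1.sequence.upper())
            s2.append(r2.sequence.upper())
    return ids, s1, s2


# -------------------------------------------------------------------- SAM
def write_sam(path, records, reference: dict[str, str]) -> None:
    """Alignment records as SAM; mates are written as two consecutive lines."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in reference.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for rec in records:
            if rec.is_unmapped:
                flag = 4
                fh.write(f"{rec.read_id}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{rec.seq}\t*\n")
                continue
            flag = 0
            if rec.strand == "-":
                flag |= 16
            cigar = rec.cigar.replace("=", "M").replace("X", "M") or "*"
            cigar = _merge_cigar(cigar)
            mate_c = rec.mate_contig or "*"
            mate_p = rec.mate_pos0 + 1 if rec.mate_pos0 >= 0 else 0
            if mate_c == rec.contig:
                mate_c = "="
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.contig}\t{rec.pos0 + 1}\t{rec.mapq}\t"
                f"{cigar}\t{mate_c}\t{mate_p}\t0\t{rec.seq}\t*\tNM:i:{rec.nm}\n"
            )


def _merge_cigar(cigar: str) -> str:
    import re

    out = []
    for n, op in re.findall(r"(\d+)([MIDSH])", cigar):
        if out and out[-1][1] == op:
            out[-1][0] += int(n)
        else:
            out.append([int(n), op])
    return "".join(f"{n}{op}" for n, op in out)


def read_sam(path) -> list:
    """External SAM -> AlignmentRecord list (pysam-backed)."""
    import pysam

    from .mapping import AlignmentRecord

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for r in sam:
            if r.is_unmapped:
                out.append(AlignmentRecord(r.query_name, None, -1, "+", "", -1, 0,
                                           r.query_sequence or "", is_unmapped=True))
                continue
            out.append(AlignmentRecord(
                r.query_name, r.reference_name, r.reference_start,
                "-" if r.is_reverse else "+", r.cigarstring or "",
                int(r.get_tag("NM")) if r.has_tag("NM") else 0,
                r.mapping_quality, r.query_sequence or ""))
    return out


# -------------------------------------------------------------------- VCF
VCF_HEADER = """##fileformat=VCFv4.2
##source=hapsoma
##INFO=<ID=HAP,Number=1,Type=String,Description="Carrying haplotype (A or B)">
##INFO=<ID=HOMPOS,Number=1,Type=String,Description="Homologous partner coordinate contig:pos1">
##INFO=<ID=DUPGRP,Number=1,Type=Integer,Description="Duplicate group id">
##INFO=<ID=MODE,Number=1,Type=String,Description="Calling mode (single or dual)">
##INFO=<ID=COLLAPSED,Number=0,Type=Flag,Description="Balanced column in a haplotype-collapsed region">
##FILTER=<ID=LOWQUAL,Description="Genotype quality below threshold">
##FILTER=<ID=LOWDEPTH,Description="Read depth below threshold">
##FILTER=<ID=BLACKLIST,Description="Position called on mutation-free simulation">
##FILTER=<ID=DUP,Description="Duplicate of a homologous call">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting reads">
"""


def write_vcf(path, calls, reference: dict[str, str], sample: str = "S1") -> None:
    lines = [VCF_HEADER]
    for name, seq in reference.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
    for c in sorted(calls, key=lambda c: (c.contig, c.pos0)):
        seq = reference[c.contig]
        if c.alt.startswith("+"):
            ref_s, alt_s = seq[c.pos0], seq[c.pos0] + c.alt[1:]
        elif c.alt.startswith("-"):
            n = int(c.alt[1:])
            ref_s, alt_s = seq[c.pos0 : c.pos0 + 1 + n], seq[c.pos0]
        else:
            ref_s, alt_s = c.ref, c.alt
        filt = ";".join(sorted(c.filters)) if c.filters else "PASS"
        info = [f"MODE={c.mode}"]
        if c.haplotype:
            info.append(f"HAP={c.haplotype}")
        if c.hom_pos:
            info.append(f"HOMPOS={c.hom_pos[0]}:{c.hom_pos[1] + 1}")
        if c.dup_group is not None:
            info.append(f"DUPGRP={c.dup_group}")
        if c.collapsed:
            info.append("COLLAPSED")
        gt = "1" if c.mode == "dual" and not c.collapsed else "0/1"
        lines.append(
            f"{c.contig}\t{c.pos0 + 1}\t{c.id}\t{ref_s}\t{alt_s}\t{c.qual:.0f}\t{filt}\t"
            f"{';'.join(info)}\tGT:DP:AD\t{gt}:{c.depth}:{c.support}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_vcf(path) -> pd.DataFrame:
    """External VCF -> tidy DataFrame (pysam-backed)."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filt = ",".join(rec.filter.keys()) or "PASS"
            for alt in rec.alts or (".",):
                rows.append((rec.chrom, rec.pos - 1, rec.id, rec.ref, alt,
                             rec.qual, filt, dict(rec.info)))
    return pd.DataFrame(rows, columns=["contig", "pos0", "id", "ref", "alt",
                                       "qual", "filter", "info"])


# ------------------------------------------------------------------- GFF3
def read_gff3_cds(path) -> list:
    """CDS models per transcript from a GFF3 file (gffutils-backed)."""
    import gffutils

    from .selscan import Transcript

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    tx: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parent = (cds.attributes.get("Parent") or [cds.id or "tx"])[0]
        t = tx.setdefault(parent, {"contig": cds.seqid, "strand": cds.strand, "cds": []})
        t["cds"].append((cds.start - 1, cds.end))
    return [Transcript(k, v["contig"], v["strand"], v["cds"]) for k, v in sorted(tx.items())]


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene table (gene_id, contig, start, end, strand) from GFF3."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    rows = []
    for g in db.features_of_type("gene"):
        gid = (g.attributes.get("ID") or [g.id])[0]
        rows.append((gid, g.seqid, g.start - 1, g.end, g.strand))
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])


def write_gff3(path, genes: pd.DataFrame, cds: list | None = None) -> None:
    """Minimal GFF3 writer for synthetic gene models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            fh.write(f"{g.contig}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            fh.write(f"{g.contig}\t.\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}.t1;Parent={g.gene_id}\n")
        for tx in cds or []:
            for s, e in tx.cds:
                fh.write(f"{tx.contig}\t.\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t0\t"
                         f"ID=cds_{tx.tx_id};Parent={tx.tx_id}\n")


# -------------------------------------------------------------------- BED
def write_bed(path, intervals) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(map(str, iv)) + "\n")
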