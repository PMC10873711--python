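"""Population-level somatic variation map and downstream screens.

Per-accession call sets are merged into a variants x accessions genotype
matrix (0 absent, 1 present-het, 2 present-hom, NaN no-call); a binomial
test over non-overlapping 50-kb windows removes regions whose mutation
load is incompatible with a uniform genome-wide distribution; alleles are
polarized against an outgroup clade to build the derived-allele frequency
spectrum; group-specific heterozygous variants are screened and annotated
with nearby genes; and an allele-sharing distance matrix is exported as a
NEXUS DISTANCES block for network phylogeny (SplitsTree-style) input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VariantKey = tuple  # (haplotype, contig, pos0, ref, alt)


@dataclass
class PopulationMap:
    genotypes: pd.DataFrame  # index: variant keys; columns: accessions; values 0/1/2/NaN
    metadata: pd.DataFrame | None = None  # per-accession metadata (e.g. clade labels)

    @property
    def accessions(self) -> list[str]:
        return list(self.genotypes.columns)

    def occupancy(self) -> pd.Series:
        """Number of accessions carrying each variant (genotype > 0)."""
        return (self.genotypes > 0).sum(axis=1)

    def to_tsv(self, path) -> None:
        df = self.genotypes.copy()
        df.index = [f"{h}|{c}|{p}|{r}|{a}" for h, c, p, r, a in df.index]
        df.to_csv(path, sep="\t", na_rep="NA")


def merge_population(
    calls_per_accession: dict[str, list],
    depth_of: dict[str, callable] | None = None,
    min_depth: int = 2,
) -> PopulationMap:
    """Merge per-accession somatic calls into a genotype matrix.

    Variants are keyed by (haplotype, contig, pos0, ref, alt). An accession
    without a call at a key is 0 (reference) unless `depth_of[acc](contig,
    pos0) < min_depth`, in which case the entry is NaN — no-call is not
    evidence of absence. Conflicting reference alleles at one key indicate a
    reference-build mismatch and raise.
    """
    keys: dict[VariantKey, dict[str, float]] = {}
    ref_seen: dict[tuple, str] = {}
    for acc, calls in calls_per_accession.items():
        for c in calls:
            if not getattr(c, "retained", True):
                continue
            hap = getattr(c, "haplotype", None) or "A"
            key = (hap, c.contig, c.pos0, c.ref, c.alt)
            site = (c.contig, c.pos0)
            if site in ref_seen and ref_seen[site] != c.ref:
                raise ValueError(f"conflicting ref alleles at {site}: build mismatch")
            ref_seen[site] = c.ref
            gt = 2.0 if tuple(getattr(c, "genotype", ())) == (c.alt, c.alt) else 1.0
            keys.setdefault(key, {})[acc] = gt
    accs = sorted(calls_per_accession)
    index = sorted(keys)
    mat = pd.DataFrame(0.0, index=pd.Index(index, tupleize_cols=False), columns=accs)
    for key, row in keys.items():
        for acc, gt in row.items():
            mat.loc[[key], acc] = gt
    if depth_of:
        for key in index:
            _, contig, pos, _, _ = key
            for acc in accs:
                fn = depth_of.get(acc)
                if fn is not None and mat.loc[[key], acc].iloc[0] == 0.0 and fn(contig, pos) < min_depth:
                    mat.loc[[key], acc] = np.nan
    return PopulationMap(mat)


# --------------------------------------------------------------------------
# binomial window filter
# --------------------------------------------------------------------------

@dataclass
class WindowStat:
    contig: str
    start: int
    end: int
    observed: int
    expected: float
    p_value: float
    removed: bool


def binomial_window_filter(
    pmap: PopulationMap,
    contig_lengths: dict[str, int],
    window: int = 50_000,
    alpha: float = 0.001,
    correction: str = "bonferroni",
) -> tuple[PopulationMap, list[WindowStat]]:
    """Remove windows whose variant count departs from a uniform binomial.

    Each non-overlapping `window`-bp window is tested two-sided against
    Binomial(N_total, window_len / genome_len); windows with corrected
    p < alpha are removed together with their variants.
    """
    base_lengths: dict[str, int] = {}
    for contig, length in contig_lengths.items():
        base = _base_contig(contig)
        base_lengths[base] = max(base_lengths.get(base, 0), length)
    genome_len = sum(base_lengths.values())
    variants = list(pmap.genotypes.index)
    n_total = len(variants)
    counts: dict[tuple[str, int], int] = {}
    for (hap, contig, pos, ref, alt) in variants:
        base = _base_contig(contig)
        counts[(base, pos // window)] = counts.get((base, pos // window), 0) + 1
    stats_out: list[WindowStat] = []
    removed_windows: set[tuple[str, int]] = set()
    windows = []
    for base, length in base_lengths.items():
        for wi in range(max(1, -(-length // window))):
            windows.append((base, wi, min(window, length - wi * window)))
    windows = sorted(windows)
    n_tests = len(windows)
    for base, wi, wlen in windows:
        obs = counts.get((base, wi), 0)
        p_win = wlen / genome_len
        if n_total == 0:
            pv = 1.0
        else:
            pv = stats.binomtest(obs, n_total, p_win, alternative="two-sided").pvalue
        p_corr = min(1.0, pv * n_tests) if correction == "bonferroni" else pv
        rm = p_corr < alpha
        if rm:
            removed_windows.add((base, wi))
        stats_out.append(WindowStat(base, wi * window, wi * window + wlen, obs,
                                    n_total * p_win, p_corr, rm))
    keep = [
        k for k in variants
        if (_base_contig(k[1]), k[2] // window) not in removed_windows
    ]
    filtered = PopulationMap(pmap.genotypes.loc[keep], pmap.metadata)
    return filtered, stats_out


def _base_contig(contig: str) -> str:
    """Collapse haplotype-suffixed contig names onto their chromosome.

    Windows are defined on chromosomes so a mutation hotspot is judged on
    the combined haplotypes; un-suffixed names pass through."""
    for suf in ("_A", "_B"):
        if contig.endswith(suf):
            return contig[: -len(suf)]
    return contig


# --------------------------------------------------------------------------
# outgroup polarization & frequency spectrum
# --------------------------------------------------------------------------

@dataclass
class SpectrumResult:
    counts: dict[int, int]  # occupancy k -> number of variants
    n_ingroup: int
    unresolved: int
    derived_labels: pd.Series  # per-variant: 'alt' | 'ref' | 'unresolved'

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unresolved

    def low_frequency_fraction(self, below: int = 3) -> float:
        resolved = sum(self.counts.values())
        if resolved == 0:
            return float("nan")
        low = sum(n for k, n in self.counts.items() if k < below)
        return low / resolved


def polarize_and_spectrum(pmap: PopulationMap, outgroup: list[str]) -> SpectrumResult:
    """Outgroup-polarized derived-allele frequency spectrum.

    The ancestral allele at a variant is the allele fixed across all
    genotyped outgroup accessions; variants polymorphic in the outgroup or
    with no genotyped outgroup member are unresolved and excluded from the
    spectrum (but counted). Occupancy is the number of ingroup accessions
    carrying the derived allele.
    """
    missing = [o for o in outgroup if o not in pmap.genotypes.columns]
    if missing or not outgroup:
        raise ValueError(f"outgroup accessions absent from map: {missing or 'none given'}")
    ingroup = [a for a in pmap.accessions if a not in set(outgroup)]
    og = pmap.genotypes[outgroup]
    ig = pmap.genotypes[ingroup]
    labels = {}
    counts: dict[int, int] = {}
    unresolved = 0
    for key in pmap.genotypes.index:
        o = og.loc[[key]].iloc[0]
        known = o.dropna()
        if len(known) == 0:
            labels[key] = "unresolved"
            unresolved += 1
            continue
        present = known > 0
        if present.all():
            derived = "ref"  # ancestral state carries the variant
        elif (~present).all():
            derived = "alt"
        else:
            labels[key] = "unresolved"
            unresolved += 1
            continue
        labels[key] = derived
        i = ig.loc[[key]].iloc[0]
        if derived == "alt":
            k = int((i > 0).sum())
        else:
            k = int((i.dropna() == 0).sum())
        counts[k] = counts.get(k, 0) + 1
    return SpectrumResult(counts, len(ingroup), unresolved,
                          pd.Series(labels, index=pmap.genotypes.index))


# --------------------------------------------------------------------------
# group-specific screen with gene proximity
# --------------------------------------------------------------------------

def group_specific_screen(
    pmap: PopulationMap,
    group: list[str],
    genes: pd.DataFrame | None = None,
    proximity: int = 3_000,
    relaxed: bool = False,
    allow_na_outside: bool = False,
) -> pd.DataFrame:
    """Heterozygous variants private to a group of accessions.

    Strict screen: genotype 1 (present-het) in every group member and 0
    (explicitly absent) in every non-member; `relaxed` demands presence in
    at least one member instead of all. Each retained variant is annotated
    with genes whose body or +-`proximity` bp flank contains it, when a gene
    table (columns contig/start/end/strand/gene_id) is provided.
    """
    accs = set(pmap.accessions)
    if not group or not set(group) < accs:
        raise ValueError("group must be a nonempty strict subset of accessions")
    others = sorted(accs - set(group))
    g = pmap.genotypes
    in_g = g[list(group)]
    out_g = g[others]
    if relaxed:
        present = (in_g == 1).any(axis=1)
    else:
        present = (in_g == 1).all(axis=1)
    if allow_na_outside:
        absent = ((out_g == 0) | out_g.isna()).all(axis=1)
    else:
        absent = (out_g == 0).all(axis=1)
    hits = g.index[present & absent]
    rows = []
    for key in hits:
        hap, contig, pos, ref, alt = key
        nearby = []
        if genes is not None and len(genes):
            base = _base_contig(contig)
            sel = genes[(genes["contig"].map(_base_contig) == base)
                        & (genes["start"] - proximity <= pos)
                        & (genes["end"] + proximity > pos)]
            nearby = list(sel["gene_id"])
        rows.append((hap, contig, pos, ref, alt, ",".join(nearby)))
    return pd.DataFrame(rows, columns=["haplotype", "contig", "pos0", "ref", "alt", "genes"])


# --------------------------------------------------------------------------
# distances for network phylogeny
# --------------------------------------------------------------------------

def pairwise_distances(pmap: PopulationMap) -> pd.DataFrame:
    """Allele-sharing Hamming distance on presence/absence, NaN-pairs
    excluded and normalized by the number of compared sites."""
    g = pmap.genotypes
    drop = [a for a in g.columns if g[a].isna().all()]
    if drop:
        import warnings

        warnings.warn(f"accessions with no genotyped sites dropped: {drop}")
        g = g.drop(columns=drop)
    accs = list(g.columns)
    pres = (g > 0).to_numpy(dtype=float)
    known = ~g.isna().to_numpy()
    n = len(accs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = known[:, i] & known[:, j]
            m = both.sum()
            d[i, j] = d[j, i] = (
                np.abs(pres[both, i] - pres[both, j]).sum() / m if m else np.nan
            )
    return pd.DataFrame(d, index=accs, columns=accs)


def export_distance_nexus(pmap: PopulationMap, path) -> pd.DataFrame:
    """Write a NEXUS DISTANCES block suitable for network inference input."""
    d = pairwise_distances(pmap)
    if len(d) < 3:
        raise ValueError("need >= 3 accessions for a distance export")
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(d)};\n  TAXLABELS\n")
        for a in d.index:
            fh.write(f"    {a}\n")
        fh.write("  ;\nEND;\n\nBEGIN DISTANCES;\n")
        fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n  MATRIX\n")
        for a in d.index:
            vals = " ".join(f"{d.loc[a, b]:.6f}" for b in d.columns)
            fh.write(f"    {a} {vals}\n")
        fh.write("  ;\nEND;\n")
    return d


def read_distance_nexus(path) -> pd.DataFrame:
    """Parse a DISTANCES block written by export_distance_nexus."""
    taxa: list[str] = []
    rows: dict[str, list[float]] = {}
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.upper().startswith("MATRIX"):
                in_matrix = True
                continue
            if in_matrix:
                if s == ";" or s.upper().startswith("END"):
                    in_matrix = False
                    continue
                parts = s.split()
                if parts:
                    rows[parts[0]] = [float(x) for x in parts[1:]]
                    taxa.append(parts[0])
    return pd.DataFrame([rows[t] for t in taxa], index=taxa, columns=taxa)
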