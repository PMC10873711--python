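# Methods

This note documents the models, algorithms and numerical choices behind
`hapsoma`, in the order data flows through the package.

## Synthetic diploid genome (`simgen`)

The generator emulates a sweet-orange-like diploid at desk scale. A base
sequence is laid down as a mixture of unique segments (exponential lengths,
mean 2 kb) and interspersed repeat-family copies covering ≈45% of the
sequence — citrus genomes are roughly that repetitive — with eight families
of 0.5–5-kb consensus length. Thirty percent of copies are "young"
(0–0.5% diverged from consensus, the part of the repeat landscape that
actually defeats short-read mapping) and the rest are older (1–15%
diverged). Two donor genomes ("P", pummelo-like; "M", mandarin-like) are
derived from the base at 2% total divergence, and haplotype A is a mosaic
of donor blocks (exponential lengths, mean 100 kb, 10-kb floor),
reproducing the two-donor admixture structure.

Haplotype B is then derived from haplotype A by sampled heterozygous
variants, which makes three truths exact by construction: re-applying the
germline list to hapA reproduces hapB byte-for-byte; the homology map comes
from the coordinate map of the splice; and every variant's haplotype of
origin is known. Defaults: het SNPs at 0.018/bp in aligned sequence (the
measured sweet-orange density), het InDels at 0.0018/bp (a 10:1 SNP:InDel
ratio, typical of plant resequencing), geometric(0.5) lengths capped at
20 bp, and four haplotype-specific segments of 5–20 kb per Mb (half present
only on A, half only on B), scaled-down analogues of the multi-kb-to-180-kb
haplotype-specific regions of the real genome. SNP rates ≥ 0.75 are
rejected (Jukes–Cantor saturation).

Somatic mutations are spiked uniformly over both haplotypes — each is
heterozygous by construction, present on exactly one haplotype — and
assigned to branches of a clone-propagation tree; a leaf (accession)
carries exactly the union of mutations on its root path. Alternate bases
come from a 4×4 base-mutation matrix (equal-rate by default); 10% of
spikes are InDels (geometric(0.5) lengths, max 20 bp). Position collisions
are re-sampled, never overwritten.

Paired-end reads: total bases = coverage × len(hapA), split evenly between
the two chromosome copies (each copy sees coverage/2 — the diploid WGS
convention, and what a coverage number normalized to one haplotype means).
Fragment lengths are Normal(400, 60) clipped below at the read length;
150-bp mates in FR orientation; substitution errors i.i.d. per base at
0.2%; base qualities constant Q30 (errors are not quality-dependent; the
mapper and caller never read qualities). Read length, insert and error rate
are configurable defaults, not measured values. All randomness descends
from one master seed through stable per-stage child seeds, so any stage
reproduces in isolation.

### What the generator does not emulate

No sequencing-platform error profiles (indel errors, quality decay,
GC bias), no TE grammar beyond divergence-scattered copies, no CNVs or
inversions, no chimeric reads. Passing tests therefore demonstrate the
pipeline's behaviour under idealized noise on a repeat-structured genome;
absolute recall on real data will be lower and instrument-dependent.

## Mapper (`mapping`)

A seed-and-verify mapper: canonical (strand-min) k-mers at four fixed
offsets per 150-bp read (k = 31) are looked up in a positional index;
candidate diagonals are verified by Myers bit-vector edit distance (edlib)
over a ±24-bp padded window; the best placement is the minimum edit
distance with at most `read_len/5` edits. MAPQ is 60 when the runner-up is
≥ 2 edits worse, 30 at a 1-edit gap, and 0 for exact ties; all tied
placements are retained and the primary is the lexicographically first
(contig, position) — a deterministic rule the homology dedup downstream
depends on. Seeds hitting more than 24 positions are skipped (repeat
protection); a read with no usable seed is reported unmapped. When one
mate ties and the other is uniquely placed, the tie closest to the expected
insert on the mate's contig is chosen (MAPQ 20). There is no BWT index, no
affine-gap scoring, no spliced alignment, and no inversion awareness.

## Pileup (`pileup`)

Dense per-position A/C/G/T counts plus sparse InDel alleles keyed by their
anchor column ('+SEQ' insertion after the anchor, '-N' deletion of the next
N bases). A read carrying an InDel contributes its anchor-base observation
to the InDel allele rather than the reference base, so allele counts
partition reads and Σ column depths equals Σ aligned bases. MAPQ-0 reads
are counted by default (they carry the signal in collapsed regions) and
each column records its MAPQ-0 fraction.

## Somatic caller (`somacall`)

"Somatic" means: a difference from the reference individual's diploid
genome; there is no tumor/normal pairing. Genotyping is maximum-posterior
under binomial allele sampling with per-base error e (flat prior over
genotypes; qual = Phred of 1 − posterior, capped at 1000):

* **single mode** (reads on hapA only): diploid genotypes over all allele
  pairs. A site is somatic when the genotype departs from the individual's
  germline expectation — reference-homozygous away from het sites, the
  known het genotype at them — which naturally covers tri-allelic sites
  where a somatic allele arises at a germline-heterozygous position.
* **dual mode**: each haplotype contig is haploid; a somatic het mutation
  is a near-fixed allele on one copy. When ≥ 70% of a column's reads are
  MAPQ 0 — in a region truly identical between haplotypes essentially every
  read ties between the two copies and stacks on one position — an explicit
  50:50 "collapsed het" hypothesis joins the model, so mutations in such
  regions are still called (as one haplotype-unresolved call). The gate and
  its level both matter: ungated, the mixture hypothesis competes with every
  pure column and caps call quality around Phred 24, far below the quality
  filter; gated too low it misfires on partial interspersed-repeat ambiguity
  (MAPQ-0 fractions of 0.2-0.6), where the column still represents one
  chromosome copy and must be genotyped haploid.

Filters follow the quality ≥ 50 / read-depth ≥ 2 rule (both configurable;
the depth rule is applied per pileup column, i.e. per haplotype copy in
dual mode, with the combined behaviour available through the column depth
itself). The false-positive blacklist is every candidate site emitted on a
mutation-free simulation of the same genome — deliberately including
sub-threshold candidates, since a systematically artifact-prone position
should be excluded even when its null-run quality is marginal (this keeps
the null clean across independent read seeds).

Duplicate resolution: for each dual-mode call the 150 bp flanking the site
and its homologous position are compared (truncated symmetrically at contig
ends); exactly identical flank pairs mean one mutation seen at two
coordinates: the call passing the other filters is kept (haplotype-A,
i.e. the lexicographically first coordinate, as the tie-break), the partner
is flagged DUP, and both records share a dup_group with the partner
coordinate in INFO/HOMPOS. The operation is idempotent.

## Homology map (`homology`)

Mutually unique shared canonical 31-mers between the haplotypes are chained
by longest increasing subsequence per contig pair; runs of constant offset
become blocks; inter-run spans are interpolated only over the span length
the two haplotypes share (an InDel between runs leaves a small unmapped
sliver), which keeps lookup an exact involution on block interiors.
Unanchored spans ≥ 50 bp are reported as haplotype-specific gaps — 50 bp
being the conventional SV floor. Collinear ('+') chains only; inversions
are out of scope. The simulator's truth map is exact and used for
evaluation; the anchor-based estimate exists for genomes without truth and
agrees with it at ≥ 99.9% of SNP-only positions in tests.

## Evaluation (`evalkit`)

Three modes mirror the method-comparison design: `single_genotype`
(position + exact diploid genotype), `single_position` (position only),
and `dual` (haplotype-resolved position + allele; a collapsed merged call
counts as genotype-correct because "heterozygous, haplotype-unresolvable"
is the true state of an identical region). Truth on haplotype B is
projected to hapA coordinates through the truth homology map for the
single-reference modes; truths falling in haplotype-specific gaps are
unreachable there, reported separately, and still count against recall.
SNPs match on exact position and allele. InDels match when the retained
InDel calls within ±40 bp reconstruct exactly the mutated local haplotype:
pairwise alignment legitimately fragments one InDel into equivalent
representations (a 6-bp insertion can align as 5I + 1= + 1I), so
reconstruction, not allele identity, is the robust criterion. Recall uses
all spiked mutations as denominator; F1 is reported alongside.

The coverage sweep rebuilds blacklists per coverage (the null simulation
is coverage-matched) and reports, per mode, the plateau coverage — the
smallest coverage whose recall is within 1% of the max-coverage recall
(2% in the acceptance suite, where 150 spiked mutations put ~0.7-pp
granularity on recall).

### Problem sizes

The acceptance-grade study uses two ~1-Mb haplotypes, 600 spiked mutations
and 35× reads (a few minutes end to end); the coverage sweep uses a 150-kb
genome with 150 mutations over {5, 10, 20, 35, 50}×; specificity and dedup
checks use 100-kb and 40-kb genomes. These sizes give binomial counting
noise of 1–4 pp on the reported fractions, which the test tolerances
reflect.

On these clean synthetic genomes this package's mapper and caller recover
a larger fraction of spiked mutations than a production short-read pipeline
(BWA-MEM alignment with a learned variant caller) achieves on a real
600-Mb citrus genome; the cross-mode *orderings* — position recall ≥
genotype recall, dual genotype-correctness ≥ single — and the coverage
plateau shape are the transferable results, and those are what the
acceptance suite asserts.

## Population map (`popmap`)

The genotype matrix distinguishes 0 (explicitly reference at adequate
depth) from NA (no evidence): an accession with depth < 2 at a site is NA,
never 0 — anything else silently deflates spectra. The binomial window
filter tests each non-overlapping 50-kb window (windows are defined on
chromosomes, haplotypes combined) two-sided against
Binomial(N_total, w/G) with Bonferroni correction at α = 0.001; the test
direction and correction are package choices, exposed as parameters.
Outgroup polarization calls the ancestral allele as the state fixed across
all genotyped outgroup accessions; outgroup-polymorphic or outgroup-NA
variants are unresolved, excluded from the spectrum but counted, so
Σ spectrum + unresolved = total. The group-specific screen is strict by
default (present-het in every group member, explicitly absent in every
non-member; NA fails the absence requirement) with a relaxed ≥ 1-member
mode; hits are annotated with genes whose body or ±3-kb flank contains
them. Distances are presence/absence Hamming, NA-pairs excluded,
normalized by compared sites, exported as a NEXUS DISTANCES block for
network-phylogeny programs (the network inference itself is out of scope).

## Selection (`selscan`)

Site-counting dN/dS, not a codon-model ML fit — the appropriate tool for a
population this young. N/S opportunity sites come from enumerating all
three single-base changes at every CDS position (stop-affecting changes
count as nonsynonymous); observed pN = N_obs/N_sites and pS = S_obs/S_sites
are Jukes–Cantor corrected and ratioed. The base-mutation matrix is
estimated from observed SNPs on the reference strand as printed (no
pyrimidine collapsing). Neutral replicates (R = 100 default) drop the same
number of mutations uniformly with matrix-drawn alternates; the normalized
value is obs/mean(neutral), with the replicate sd and the 2.5–97.5
percentile interval of obs/neutral both reported (which of the two a "±"
shorthand means is ambiguous, so both are given). A 0.5 pseudo-count
replaces S_obs = 0 and is flagged. Effect classes: synonymous / missense /
stop_gain / stop_loss / start_loss for CDS SNPs (most severe across
overlapping transcripts wins; per-transcript detail available), frameshift
vs inframe_indel for CDS InDels by length % 3, noncoding otherwise;
LoF = {stop_gain, frameshift, start_loss}. No deleteriousness scoring.

## ASE (`asekit`)

Reads vote for a haplotype by majority over the het coding SNPs they cover;
ties are discarded but counted, so assigned A + assigned B + ties equals
reads overlapping ≥ 1 het coding SNP. Genes need ≥ 1 het coding SNP to be
testable ("biallelic"). Replicates are pooled before testing by default
(a per-replicate mode exists); the test is two-sided exact binomial against
0.5 with BH-FDR stratified within stage (a global-FDR switch exists,
since "ASE during at least one stage" is the usual claim). ASE: FDR < 0.05.
EASE: fold-change > 2 (strict; raw counts, no pseudo-count — a zero low
allele gives fold = ∞ and qualifies through the other thresholds), high
allele > 100 reads (strict), FDR < 0.001. Promoter association flags a
gene when a heterozygous SV overlaps the 3-kb window upstream of the TSS on
the coding strand (gene-body overlap available behind a flag).

## Known limitations

* The mapper's exactness makes some classic short-read artifacts (random
  multi-mapping placement, soft-clip misalignment) rarer than with
  production aligners, so blacklists are smaller and recall higher than a
  BWA-based pipeline would show on the same input.
* InDel calls near germline InDels in single-reference mode inherit
  alignment-representation ambiguity; evaluation absorbs it, the VCF
  records keep the aligned representation.
* Structural variants are not called from short reads (haplotype-specific
  segments enter as simulator truth and as homology-map gaps only).
* The collapsed-het model assumes exactly two collapsed copies; mutations
  in higher-multiplicity repeats dilute below its 50:50 assumption and are
  the dominant remaining false-negative class.
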