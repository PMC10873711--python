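# hapsoma

Haplotype-resolved ("dual-reference") somatic mutation detection for highly
heterozygous clonal genomes, with a synthetic diploid-genome and read
simulator, population-map analyses, neutral-normalized dN/dS, and
allele-specific expression (ASE) classification.

## The problem

Clonally propagated crops — sweet orange is the motivating case — accumulate
somatic mutations over centuries of grafting, and those mutations underlie
much of the phenotypic variation between varieties. The genome is an ancient
pummelo × mandarin admixture with ~18 heterozygous SNPs per kb and large
haplotype-specific segments, so mapping short reads to a single haploid
reference leaves every read from the other haplotype mismatched: genuine
somatic mutations hide inside a dense germline-heterozygous background, and
genotypes come out wrong even when positions are found.

The dual-reference strategy maps reads against **both** assembled haplotypes
concatenated. Germline heterozygosity then vanishes — each read lands on its
own haplotype — and a heterozygous somatic mutation appears as a near-fixed
allele on one haplotype's pileup. Two complications remain, and this package
implements both remedies:

* **Regions identical between haplotypes** make placement ambiguous; reads
  stack on one copy and the same mutation can surface at two homologous
  coordinates. Calls whose flanking 150 bp are identical at the homologous
  position are merged into a single call (flanking-homology deduplication).
* **Systematic mapping artifacts** (collapsed repeats, duplications) are
  removed by a blacklist of every position called variant on a mutation-free
  simulation of the same genome.

Downstream, per-accession call sets merge into a variants × accessions map;
non-overlapping 50-kb windows whose mutation load violates a uniform
binomial are dropped; alleles are polarized against an outgroup clade to
build the derived-allele frequency spectrum; selection is assessed by a
neutral-normalized dN/dS; and allelic read counts classify ASE/EASE genes.

Key statistics, in the field's notation:

* Jukes–Cantor correction: `d = -(3/4) ln(1 - (4/3) p)` for observed
  mismatch proportion `p`.
* Normalized dN/dS: `(dN/dS)_obs / mean[(dN/dS)_neutral]` over R = 100
  simulations that drop the observed number of mutations uniformly over the
  genome with alternate alleles drawn from the empirical 4×4 base-mutation
  matrix. Values > 1 indicate an excess of protein-changing mutations.
* ASE: two-sided exact binomial test of per-gene haplotype read counts
  against 0.5, Benjamini–Hochberg FDR < 0.05 within each stage. EASE
  additionally requires fold-change > 2, > 100 reads on the high allele, and
  FDR < 0.001.

## Worked example

Simulate a 200-kb sweet-orange-like diploid, spike 100 heterozygous somatic
mutations, sequence to 35×, and compare the three calling assumptions:

```python
from hapsoma import CloneTree, GenomeConfig, generate_diploid, spike_somatic
from hapsoma.evalkit import run_calling
from hapsoma._rng import stage_seed

genome = generate_diploid(GenomeConfig(contigs={"chr1": 200_000}, seed=1))
truth = spike_somatic(genome, CloneTree.linear(1), 100, seed=stage_seed(1, "spike"))
study = run_calling(genome, truth, coverage=35, seed=stage_seed(1, "study"))
for mode, r in study.results.items():
    print(f"{mode:16s} recall={r.recall:.2f} precision={r.precision:.2f} "
          f"genotype_correct={r.genotype_correct_fraction:.2f}")
```

```
dual             recall=1.00 precision=1.00 genotype_correct=1.00
single_genotype  recall=0.91 precision=0.86 genotype_correct=0.90
single_position  recall=0.92 precision=0.84 genotype_correct=0.00
```

Read it as: at 35× on this 200-kb toy the dual reference recovers all 100
spiked mutations with the correct haplotype-resolved genotype and no false
positives; the single reference misses some positions outright (mutations
in haplotype-specific sequence have no coordinate there), mislabels a
genotype, and lets mapping artifacts through (lower precision).
`genotype_correct` is not meaningful for the position-only mode and is
reported as 0.

The same pipeline is scriptable from the shell:

```bash
hapsoma --seed 1 simulate --outdir sim --contig-length 200000 --n-mutations 100
hapsoma map --reference sim/genome.fasta --fastq1 sim/reads_1.fastq \
            --fastq2 sim/reads_2.fastq --out sim/aln.sam
hapsoma --seed 2 blacklist --genome-dir sim --mode dual --out sim/bl.bed
hapsoma call --genome-dir sim --sam sim/aln.sam --mode dual \
             --blacklist sim/bl.bed --out sim/calls.vcf
```

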