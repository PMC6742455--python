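# mesnp — methylation-relevant SNP toolkit

`mesnp` identifies and analyses **meSNPs**: single-nucleotide polymorphisms
whose two alleles differ in whether (or where) a CpG dinucleotide exists in
the trinucleotide window around the variant. Because DNA methylation in
vertebrates happens almost exclusively at CpG sites, such variants can
create, destroy or displace a methylation target and thereby couple genetic
variation to epigenetic state. The package is aimed at researchers working
with livestock or other vertebrate genomes who have a reference FASTA, a
SNP call set (VCF) and interval-based methylation data (CpG islands,
MeDIP/MIRA-seq peaks, differentially methylated regions).

## What it does

1. **Classification.** For a SNP with reference allele *r* and alternate
   allele *a* at position *p*, only the two dinucleotide slots inside the
   window `(p−1, p, p+1)` can hold a CpG containing the variant base.
   Writing R and A for the sets of slots reading `CG` under each allele,
   the SNP is classified as

   | R | A | class |
   |---|---|-------|
   | ∅ | ≠∅ | CREATE |
   | ≠∅ | ∅ | DESTROY |
   | ≠∅ | ≠∅ | DISPLACE (the slots necessarily differ) |
   | ∅ | ∅ | NONE |

   The allele that forms the CpG is the **MSC** (methylation-site creating)
   allele; the other is the **MSD** allele.

2. **CpG islands.** Islands are detected under relaxed (≥200 bp) or strict
   (≥500 bp) criteria with GC ≥ 0.50 and observed/expected CpG ≥ 0.60,
   where `obs/exp = n_CpG · L / (n_C · n_G)`.

3. **Enrichment.** Per chromosome, the observed number of meSNPs inside a
   feature set is compared with the uniform-placement expectation
   `n · feature_bp / chrom_length` by a two-cell chi-square test (df = 1,
   α = 0.01 by default).

4. **Concordance.** From per-sample methylation peak sets of two phenotype
   groups, regions present in ≥3 samples of one group and absent from the
   other are derived. For meSNPs inside them, per-group alternate-allele
   frequencies `AF = (Σ alt alleles) / (2 · n called)` are computed over
   non-missing genotypes; loci with |AF₁ − AF₂| ≥ 0.5 and ≥3 calls per
   group are kept and tested for **methylation compatibility**: the MSC
   allele must be at strictly higher frequency in the hypermethylated
   group.

5. **Simulation.** A seeded generator produces a synthetic genome with
   planted islands, SNPs of every class, per-sample peak files and
   genotyped cohorts with planned allele-frequency differences, plus truth
   tables, so the whole pipeline is testable without external data.

## Worked example

```bash
mesnp simulate --seed 11 --outdir sim
mesnp classify --vcf sim/snps.vcf --fasta sim/genome.fa \
    --out mesnp.tsv --summary summary.tsv
# classified 30 SNPs -> mesnp.tsv

mesnp peaks-intersect \
    --group-a sim/peaks_HFE_1.bed,sim/peaks_HFE_2.bed,sim/peaks_HFE_3.bed,sim/peaks_HFE_4.bed \
    --group-b sim/peaks_LFE_1.bed,sim/peaks_LFE_2.bed,sim/peaks_LFE_3.bed,sim/peaks_LFE_4.bed \
    --name-a HFE --name-b LFE --out regions.bed
# 4 group-specific regions -> regions.bed

mesnp concordance --vcf sim/cohort.vcf --fasta sim/genome.fa \
    --dmr regions.bed --groups sim/groups.tsv --tissue SI --out candidates.tsv
# 4 candidates (2 compatible) -> candidates.tsv
```

`mesnp.tsv` is a tab-separated table (columns `Chr, Position, Genome, Ref,
Alt, AF, rsID, Consequence, Gene, Functionality, Biotype, meSNP_class`)
with one row per SNP; the `Genome` column holds the trinucleotide context
with the variant as the middle base. `summary.tsv` counts classes per
chromosome — for the simulated input, 10 CREATE, 10 DESTROY, 5 DISPLACE
and 5 NONE. `candidates.tsv` splits candidate meSNPs into compatible /
incompatible sections with the per-group allele frequencies; in the
simulation two loci have the CpG-forming allele at frequency 1.0 in the
hypermethylated group (compatible) and two show the reverse pattern
(incompatible).

The same functionality is available as a library:

```python
from mesnp import load_genome, read_snps, scan, summarize_classes

genome = load_genome("sim/genome.fa")
table = summarize_classes(scan(read_snps("sim/snps.vcf"), genome))
print(table[["create", "destroy", "displace"]].loc["Total"])
# create      10
# destroy     10
# displace     5
# Name: Total, dtype: int64
```

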