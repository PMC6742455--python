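# Methods

## The classification model

A single-base substitution can only change CpG dinucleotides that contain
the substituted base, so the trinucleotide window centred on the variant is
a *sufficient statistic* for the classification. Within the window there
are two dinucleotide slots: the left slot (flank + centre) holds a CpG only
when the centre base is G, the right slot (centre + flank) only when it is
C. Since no base is both C and G, at most one slot can be occupied per
allele (*slot exclusivity*); consequently a substitution can never create
or destroy two CpGs at once, and DISPLACE (both alleles CpG-bearing) always
moves the CpG between the two slots. The windowed classifier is verified
against an independent brute-force classifier
(`mesnp.validation.classify_by_sequence_diff`) that rebuilds the whole
mutated sequence and diffs the complete sets of CpG start offsets; the two
agree on every one of 10,000 random cases in the acceptance run, and two
algebraic symmetries are checked on the same cases: swapping ref/alt maps
CREATE↔DESTROY and fixes DISPLACE/NONE, and classification is invariant
under reverse complementation (CpG is its own reverse complement, which is
also why forward-strand classification loses no information).

Edge handling: a flank that does not exist (positions 1 and chromosome
end) is a definitively empty slot, and the SNP is classified from the
remaining slot. A flank read as `N` is *unknown*: the classifier
enumerates all four concrete substitutions and returns the class only if
they agree, otherwise UNCLASSIFIABLE. An `N` centre allele is always
UNCLASSIFIABLE; `N` is never coerced to a base.

Multi-allelic VCF records are split into one biallelic record per
alternate allele and classified independently; INDEL alleles are dropped
with a counted warning. Soft-masked (lower-case) reference bases are
uppercased; masking carries no information for this analysis.

## CpG islands

Criteria: length ≥ 200 bp (relaxed) or ≥ 500 bp (strict), G+C ≥ 0.50, and
observed/expected CpG ≥ 0.60 with the Gardiner-Garden & Frommer ratio
`n_CpG · L / (n_C · n_G)` (defined 0 when the segment lacks C or G;
non-ACGT bases count as neither). Detection slides a fixed 200-bp window
at 1-bp steps, merges qualifying windows that overlap or touch, trims each
merged run so it begins and ends with a CpG, applies the length filter,
and re-checks the trimmed run against all criteria, dropping runs that
fail on recomputation. The trim matters: qualifying windows extend up to
one window length beyond a CpG-dense block into its flanks, and without it
a 300-bp block inside neutral flanks would inflate to a nominal 500 bp and
spuriously satisfy the strict length criterion. The scheme is
deterministic and every emitted island provably re-satisfies the criteria
(closure), but it is not intended to reproduce any particular database's
island annotation bit-for-bit — published island files can be supplied
directly as BED via `read_intervals`.

## Enrichment

The null model places SNPs uniformly along each chromosome, deliberately
ignoring nucleotide composition; the expectation inside a feature set with
`F` merged base pairs on a chromosome of length `L` is `nF/L`. The test is
a two-cell Pearson goodness-of-fit (inside/outside, df = 1), significant
at α = 0.01 by default, with no continuity correction (counts are large in
the intended use; a flag enables it). Features are unioned per chromosome
before `F` is summed so overlapping intervals are not double-counted. The
genome-wide "average enrichment" is by default the unweighted mean of
per-chromosome folds; a pooled observed/expected ratio is available via
`pooled=True` (CLI `--pooled`) since the two conventions are both used in
practice. Calibration is verified empirically: over 1,000 uniform-null
replicates the significant fraction at α = 0.01 stays within the binomial
99% band, and a planted 2.5-fold enrichment at n = 5,000 is recovered
within ±0.15.

## Group-specific regions and concordance

A region is specific to group A when ≥ `min_present` (default 3, matching
a 3-of-4 design) of A's samples have an overlapping peak (≥ 1 shared bp)
and *no* sample of group B has any overlapping peak. The emitted span is
by default the intersection — the run where the supporting peaks overlap
simultaneously, computed by a coverage sweep — which is the conservative
choice; `mode="union"` emits the merged span of the supporting peaks
instead. The rule is antisymmetric (no region can be specific to both
groups) and monotone in `min_present`.

Per-group alternate-allele frequency is
`AF = (Σ alt alleles among called samples) / (2 · n_called)`; missing
genotypes contribute to neither numerator nor denominator. A locus passes
the concordance filter when both groups have ≥ 3 called genotypes and
|AF₁ − AF₂| ≥ 0.5 (both thresholds are parameters). Compatibility then
requires the MSC allele (alternate for CREATE, reference for DESTROY) to
be at *strictly* higher frequency in the hypermethylated group; ties carry
no signal and are incompatible, and DISPLACE/NONE records are routed to an
"indeterminate" report section since they have no MSC/MSD allele.

With four diploid samples and four genotype states (missing, hom-ref, het,
hom-alt) there are 4⁴ = 256 genotype-vector combinations per group;
exhaustive enumeration gives 189 of them with ≥ 3 non-missing genotypes
(3⁴ all-called + 4·3³ with exactly one missing). A commonly quoted figure
of 245 for this quantity is not reproducible by enumeration; the package
reports the enumerated value.

The paired-GLM likelihood-ratio DMR test (with FDR control) used by some
peak-calling pipelines is *not* reimplemented: the concordance module
consumes any interval file, so regions from that or any other caller can
be supplied.

## Synthetic fixtures

The generator emulates the shape of a two-group (4 + 4 samples, e.g. high
vs low feed efficiency) methylation-peak study on a small genome: default
two chromosomes of 50 kb at 35% background GC, three planted CpG islands
(lengths 400–800 bp at CpG dinucleotide density 0.3, which yields
GC ≈ 0.7 and obs/exp ≈ 1.2, comfortably above the criteria), 30 planted
SNPs (10 CREATE / 10 DESTROY / 5 DISPLACE / 5 NONE), and four planted
group-specific regions each containing one concordance meSNP. The genome
is edited *before* FASTA emission so the emitted reference is
self-consistent and every planted SNP's class is its truth label by
construction. Genotypes realise planned per-group allele frequencies by
exact allocation (`round(af · 2n)` alternate alleles distributed as
hom-alt/het, order shuffled by the seeded generator), so planned
frequencies of 0 or 1 are realised exactly and truth
compatibility/filter labels — recomputed from the realised allele counts
by direct arithmetic — are deterministic. The default missing-genotype
rate is 0; when raised, truth labels still follow the realised (post-
missingness) genotypes. Decoy peaks (one shared by all samples of both
groups, one present in too few samples) are planted to exercise the
absence and minimum-presence rules.

What the fixtures do **not** emulate: read-level noise, peak-boundary
jitter between samples (supporting peaks of a planted region are
identical, so intersection-mode recovery is exact), linkage between loci,
non-uniform SNP density, and composition-dependent SNP placement. Passing
the recovery tests therefore demonstrates correctness of the interval and
allele bookkeeping, not robustness to noisy peak calls.

## Numerical and design choices

- Coordinates: VCF and in-memory SNPs are 1-based; BED and intervals are
  0-based half-open; every conversion happens in `genomic_io`. A SNP at
  1-based position p is inside [s, e) iff s ≤ p−1 < e.
- Class-count summaries report fractions relative to the total number of
  input SNPs (the convention used for genome-wide class percentages).
- Consequence binning uses a standard variant-effect severity ranking over
  ~36 sequence-ontology terms mapped to broad genomic categories
  (intergenic, intron, coding, splice site, UTRs, promoter-proximal,
  regulatory, ...); the mapping and severity order are overridable because
  category schemes differ between annotation pipelines. Multiple terms on
  one variant resolve to the most severe term's category; unknown terms go
  to "other" with a warning; an empty list is "unannotated".
- Chi-square results with degenerate expectations (E ≤ 0 or E ≥ total) are
  flagged untestable rather than raising.
- Problem sizes in the test suite and acceptance script (10,000 classifier
  cases, 1,000 null replicates, n = 5,000 planted enrichment, 50-kb
  chromosomes) were chosen so the full verification completes in seconds
  while keeping Monte-Carlo bands narrow enough to be informative.

## Known limitations

- The island scanner's 200-bp window cannot resolve islands shorter than
  the window or separate islands closer than one window length.
- Enrichment treats SNP placement as uniform; composition-aware nulls
  (GC- or dinucleotide-matched) are out of scope by design.
- The concordance analysis assumes two groups; multi-group designs require
  pairwise runs.
- `verify_reference_consistency` checks REF alleles only; it does not
  validate genotype plausibility.
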