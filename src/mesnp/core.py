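"""meSNP classification: the change a SNP induces at CpG dinucleotides.

A single-base substitution can only affect a CpG dinucleotide that
contains the substituted base, so the trinucleotide window centred on the
variant carries all the information needed. Within that window there are
two dinucleotide slots: the *left* slot (flank + centre, a CpG only when
the centre base is G) and the *right* slot (centre + flank, a CpG only
when the centre base is C). Comparing which slots read "CG" under the
reference and the alternate allele yields the four-way classification

* CREATE   — no CpG with the reference allele, a CpG with the alternate
* DESTROY  — a CpG with the reference allele, none with the alternate
* DISPLACE — both alleles support a CpG, but in different slots
* NONE     — neither allele touches a CpG

Classification is on the forward strand; because CpG is its own reverse
complement, classifying on the reverse strand gives the same answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

from mesnp.genomic_io import GenomeSequence, SnpRecord

logger = logging.getLogger(__name__)

_ACGT = "ACGT"


class MeSnpClass(Enum):
    CREATE = "create"
    DESTROY = "destroy"
    DISPLACE = "displace"
    NONE = "none"
    UNCLASSIFIABLE = "unclassifiable"

    @property
    def is_mesnp(self) -> bool:
        return self in (MeSnpClass.CREATE, MeSnpClass.DESTROY, MeSnpClass.DISPLACE)


@dataclass(frozen=True)
class CpGContext:
    """The 3-base window centred on a SNP (forward strand).

    ``left_base``/``right_base`` are ``None`` at chromosome ends: an
    absent slot cannot hold a CpG and is treated as definitively empty,
    whereas an ``N`` flank leaves the slot's status unknown.
    """

    left_base: Optional[str]
    center_ref: str
    center_alt: str
    right_base: Optional[str]


def _slots(left: Optional[str], center: str, right: Optional[str]) -> frozenset[str]:
    """CpG slots occupied in a fully-determined trinucleotide."""
    slots = set()
    if left == "C" and center == "G":
        slots.add("L")
    if center == "C" and right == "G":
        slots.add("R")
    return frozenset(slots)


def _classify_determined(
    left: Optional[str], ref: str, alt: str, right: Optional[str]
) -> MeSnpClass:
    r_slots = _slots(left, ref, right)
    a_slots = _slots(left, alt, right)
    if not r_slots and not a_slots:
        return MeSnpClass.NONE
    if not r_slots:
        return MeSnpClass.CREATE
    if not a_slots:
        return MeSnpClass.DESTROY
    # both non-empty; slot exclusivity forces them to differ
    return MeSnpClass.DISPLACE


def classify_cpg_variant(context: CpGContext) -> MeSnpClass:
    """Classify a substitution by its effect on CpG slots in the window.

    ``N`` flanks are never coerced: all four concrete substitutions are
    enumerated, and the class is returned only when every substitution
    agrees; otherwise UNCLASSIFIABLE. An ``N`` centre allele is always
    UNCLASSIFIABLE.
    """
    ref, alt = context.center_ref, context.center_alt
    if ref == alt:
        raise ValueError("ref and alt centre alleles must differ")
    if ref not in _ACGT or alt not in _ACGT:
        return MeSnpClass.UNCLASSIFIABLE

    lefts = [context.left_base] if context.left_base != "N" else list(_ACGT)
    rights = [context.right_base] if context.right_base != "N" else list(_ACGT)
    classes = {
        _classify_determined(lb, ref, alt, rb) for lb in lefts for rb in rights
    }
    if len(classes) == 1:
        return classes.pop()
    return MeSnpClass.UNCLASSIFIABLE


@dataclass
class MeSnpRecord:
    """A SNP together with its window context and meSNP classification.

    ``features`` accumulates membership labels (relaxed/strict CGI, DMR
    or QTL identifiers) across annotation passes. Annotation columns
    (consequence, gene, ...) are consumed from external annotation input,
    never computed here.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    context: CpGContext
    mesnp_class: MeSnpClass
    rsid: Optional[str] = None
    genotypes: Optional[tuple] = None
    af: Optional[float] = None
    features: set[str] = field(default_factory=set)
    category: Optional[str] = None
    consequence: Optional[str] = None
    gene: Optional[str] = None
    functionality: Optional[str] = None
    biotype: Optional[str] = None

    @property
    def msc_allele(self) -> Optional[str]:
        """The methylation-site-creating allele (the one forming the CpG)."""
        if self.mesnp_class is MeSnpClass.CREATE:
            return self.alt_allele
        if self.mesnp_class is MeSnpClass.DESTROY:
            return self.ref_allele
        return None

    @property
    def msd_allele(self) -> Optional[str]:
        """The methylation-site-destroying allele (the CpG-free one)."""
        if self.mesnp_class is MeSnpClass.CREATE:
            return self.ref_allele
        if self.mesnp_class is MeSnpClass.DESTROY:
            return self.alt_allele
        return None


@dataclass
class ScanStats:
    n_scanned: int = 0
    n_unknown_chrom: int = 0


def scan(
    snps: Iterable[SnpRecord],
    genome: GenomeSequence,
    stats: Optional[ScanStats] = None,
) -> Iterator[MeSnpRecord]:
    """Classify a stream of SNPs against the reference genome.

    Flanking bases are read from the genome; SNPs at position 1 or at the
    chromosome end are classified from the single available slot. SNPs on
    chromosomes absent from the genome are counted and skipped. Input
    SNPs are assumed reference-consistent (see
    :func:`mesnp.genomic_io.verify_reference_consistency`).
    """
    if stats is None:
        stats = ScanStats()
    for snp in snps:
        if snp.chrom not in genome:
            stats.n_unknown_chrom += 1
            continue
        length = genome.lengths[snp.chrom]
        left = genome.base(snp.chrom, snp.pos - 1) if snp.pos > 1 else None
        right = genome.base(snp.chrom, snp.pos + 1) if snp.pos < length else None
        context = CpGContext(left, snp.ref_allele, snp.alt_allele, right)
        stats.n_scanned += 1
        yield MeSnpRecord(
            chrom=snp.chrom,
            pos=snp.pos,
            ref_allele=snp.ref_allele,
            alt_allele=snp.alt_allele,
            context=context,
            mesnp_class=classify_cpg_variant(context),
            rsid=snp.rsid,
            genotypes=snp.genotypes,
            af=snp.af,
        )


def summarize_classes(records: Iterable[MeSnpRecord]) -> pd.DataFrame:
    """Per-chromosome meSNP class counts with a grand-total row.

    Fraction columns are relative to the total number of input SNPs
    (including the NONE class), matching how genome-wide class
    percentages are conventionally reported. Returns an empty frame for
    empty input.
    """
    counts: dict[str, dict[str, int]] = {}
    total_snps = 0
    for rec in records:
        total_snps += 1
        row = counts.setdefault(
            rec.chrom,
            {"create": 0, "destroy": 0, "displace": 0, "none": 0, "unclassifiable": 0},
        )
        row[rec.mesnp_class.value] += 1
    if not counts:
        return pd.DataFrame(
            columns=[
                "create", "destroy", "displace", "none", "unclassifiable",
                "mesnp_total", "n_snps",
                "create_frac", "destroy_frac", "displace_frac",
            ]
        )
    df = pd.DataFrame.from_dict(counts, orient="index")
    df.index.name = "chrom"
    df["mesnp_total"] = df["create"] + df["destroy"] + df["displace"]
    df["n_snps"] = df[["create", "destroy", "displace", "none", "unclassifiable"]].sum(axis=1)
    total = df.sum(axis=0)
    total.name = "Total"
    df = pd.concat([df, total.to_frame().T])
    count_cols = ["create", "destroy", "displace", "none", "unclassifiable",
                  "mesnp_total", "n_snps"]
    df[count_cols] = df[count_cols].astype(int)
    for cls in ("create", "destroy", "displace"):
        df[f"{cls}_frac"] = df[cls] / total_snps
    return df


# Ensembl-style consequence severity ranking (most severe first) binned
# into broad genomic categories. The membership and the category names
# are a default, overridable via the ``mapping`` argument.
DEFAULT_SO_CATEGORIES: dict[str, tuple[str, int]] = {
    term: (category, rank)
    for rank, (term, category) in enumerate(
        [
            ("transcript_ablation", "coding"),
            ("splice_acceptor_variant", "splice_site"),
            ("splice_donor_variant", "splice_site"),
            ("stop_gained", "coding"),
            ("frameshift_variant", "coding"),
            ("stop_lost", "coding"),
            ("start_lost", "coding"),
            ("transcript_amplification", "coding"),
            ("inframe_insertion", "coding"),
            ("inframe_deletion", "coding"),
            ("missense_variant", "coding"),
            ("protein_altering_variant", "coding"),
            ("splice_region_variant", "splice_site"),
            ("incomplete_terminal_codon_variant", "coding"),
            ("start_retained_variant", "coding"),
            ("stop_retained_variant", "coding"),
            ("synonymous_variant", "coding"),
            ("coding_sequence_variant", "coding"),
            ("mature_miRNA_variant", "mature_miRNA"),
            ("5_prime_UTR_variant", "5_prime_UTR"),
            ("3_prime_UTR_variant", "3_prime_UTR"),
            ("non_coding_transcript_exon_variant", "non_coding_RNA"),
            ("intron_variant", "intron"),
            ("NMD_transcript_variant", "NMD_transcript"),
            ("non_coding_transcript_variant", "non_coding_RNA"),
            ("upstream_gene_variant", "proximal_promoter"),
            ("downstream_gene_variant", "downstream"),
            ("TFBS_ablation", "TF_binding_site"),
            ("TFBS_amplification", "TF_binding_site"),
            ("TF_binding_site_variant", "TF_binding_site"),
            ("regulatory_region_ablation", "regulatory_region"),
            ("regulatory_region_amplification", "regulatory_region"),
            ("feature_elongation", "other"),
            ("regulatory_region_variant", "regulatory_region"),
            ("feature_truncation", "other"),
            ("intergenic_variant", "intergenic"),
        ]
    )
}


def categorize_consequence(
    so_terms: list[str],
    mapping: Optional[Mapping[str, tuple[str, int]]] = None,
) -> str:
    """Bin sequence-ontology consequence terms into one genomic category.

    When a variant carries multiple terms the most severe term's category
    wins (lower rank = more severe). Unknown terms fall into ``other``
    with a logged warning; an empty term list is ``unannotated``.
    """
    if mapping is None:
        mapping = DEFAULT_SO_CATEGORIES
    if not so_terms:
        return "unannotated"
    best_category, best_rank = None, None
    for term in so_terms:
        if term not in mapping:
            logger.warning("unknown SO term %r mapped to 'other'", term)
            category, rank = "other", len(mapping) + 1
        else:
            category, rank = mapping[term]
        if best_rank is None or rank < best_rank:
            best_category, best_rank = category, rank
    return best_category
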