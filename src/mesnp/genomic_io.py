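"""Readers/writers for the external formats the toolkit touches.

All coordinate conversion happens here: VCF and the in-memory
:class:`SnpRecord` are 1-based; BED and :class:`GenomicInterval` are
0-based half-open. A SNP at 1-based position ``p`` lies inside the
interval ``[s, e)`` iff ``s <= p - 1 < e``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from cyvcf2 import VCF
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class GenotypeState(Enum):
    MISSING = "missing"
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"


@dataclass(frozen=True)
class GenotypeCall:
    """A single diploid genotype call for one sample.

    Missing calls contribute neither alleles to a frequency numerator nor
    chromosomes to its denominator.
    """

    state: GenotypeState

    @property
    def alt_dose(self) -> Optional[int]:
        """Number of alternate alleles (0, 1, 2), or None when missing."""
        return {
            GenotypeState.MISSING: None,
            GenotypeState.HOM_REF: 0,
            GenotypeState.HET: 1,
            GenotypeState.HOM_ALT: 2,
        }[self.state]

    @property
    def is_called(self) -> bool:
        return self.state is not GenotypeState.MISSING


MISSING = GenotypeCall(GenotypeState.MISSING)
HOM_REF = GenotypeCall(GenotypeState.HOM_REF)
HET = GenotypeCall(GenotypeState.HET)
HOM_ALT = GenotypeCall(GenotypeState.HOM_ALT)


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic single-base substitution (1-based position)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    rsid: Optional[str] = None
    genotypes: Optional[tuple[GenotypeCall, ...]] = None
    af: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(
                f"alleles must be single bases, got {self.ref_allele}>{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical: {self.ref_allele}")


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored 0-based half-open span (CGI, peak, DMR, QTL)."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval must have start < end, got {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos: int) -> bool:
        """Membership of a 1-based position."""
        return self.start <= pos - 1 < self.end


class GenomeSequence:
    """Random-access view onto a FASTA reference.

    Bases are returned uppercase regardless of source-file case
    (soft-masking is ignored). Out-of-range access raises rather than
    returning a silent N.
    """

    def __init__(self, fasta):
        # accepts a pyfaidx.Fasta or any mapping of name -> sequence string
        self._fasta = fasta
        self.chrom_names: list[str] = list(fasta.keys())
        self.lengths: dict[str, int] = {name: len(fasta[name]) for name in self.chrom_names}

    @classmethod
    def from_dict(cls, sequences: dict[str, str]) -> "GenomeSequence":
        """Wrap in-memory sequences (used by the fixture generator/tests)."""
        return cls(sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def base(self, chrom: str, pos: int) -> str:
        """Uppercase base at a 1-based position."""
        if chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 1 <= pos <= self.lengths[chrom]:
            raise IndexError(
                f"position {pos} out of range for {chrom} (length {self.lengths[chrom]})"
            )
        return str(self._fasta[chrom][pos - 1 : pos]).upper()

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Uppercase subsequence over a 0-based half-open span."""
        if chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.lengths[chrom] or start >= end:
            raise IndexError(f"span [{start},{end}) out of range for {chrom}")
        return str(self._fasta[chrom][start:end]).upper()

    def sequence(self, chrom: str) -> str:
        return self.fetch(chrom, 0, self.lengths[chrom])


def load_genome(path: str | Path) -> GenomeSequence:
    """Open a FASTA file for random access (builds/uses a .fai index).

    Raises on an empty file or duplicate sequence names.
    """
    path = Path(path)
    fasta = Fasta(str(path), duplicate_action="stop", sequence_always_upper=False)
    genome = GenomeSequence(fasta)
    if not genome.chrom_names:
        raise ValueError(f"no sequences found in {path}")
    return genome


@dataclass
class VcfReadStats:
    """Side tallies accumulated while streaming a VCF."""

    n_emitted: int = 0
    n_indels_dropped: int = 0
    n_malformed_skipped: int = 0


def read_snps(
    path: str | Path,
    keep_samples: bool = False,
    stats: Optional[VcfReadStats] = None,
) -> Iterator[SnpRecord]:
    """Stream biallelic single-base substitutions from a VCF.

    Multi-allelic sites are split into one record per alternate allele,
    each classified downstream independently. INDEL alleles are dropped
    and counted (pass a :class:`VcfReadStats` to retrieve tallies). With
    ``keep_samples`` the per-sample GT calls are attached in file order.
    """
    if stats is None:
        stats = VcfReadStats()
    vcf = VCF(str(path), gts012=True)
    for variant in vcf:
        ref = variant.REF.upper()
        genotypes: Optional[tuple[GenotypeCall, ...]] = None
        if keep_samples and len(vcf.samples) > 0:
            # gt_types with gts012: 0=hom_ref 1=het 2=hom_alt 3=unknown
            mapping = (HOM_REF, HET, HOM_ALT, MISSING)
            genotypes = tuple(mapping[t] for t in variant.gt_types)
        for alt in variant.ALT:
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or alt in ("*", "."):
                stats.n_indels_dropped += 1
                continue
            if ref == alt or ref not in _VALID_BASES or alt not in _VALID_BASES:
                stats.n_malformed_skipped += 1
                continue
            stats.n_emitted += 1
            yield SnpRecord(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref_allele=ref,
                alt_allele=alt,
                rsid=variant.ID,
                genotypes=genotypes,
                af=_info_af(variant),
            )
    if stats.n_indels_dropped:
        logger.warning("dropped %d INDEL alleles", stats.n_indels_dropped)
    if stats.n_malformed_skipped:
        logger.warning("skipped %d malformed alleles", stats.n_malformed_skipped)


def _info_af(variant) -> Optional[float]:
    af = variant.INFO.get("AF")
    if af is None:
        return None
    if isinstance(af, (tuple, list)):
        af = af[0]
    try:
        return float(af)
    except (TypeError, ValueError):
        return None


@dataclass
class ConsistencyReport:
    """Outcome of checking VCF reference alleles against the genome."""

    n_checked: int = 0
    n_mismatch: int = 0
    n_unknown_chrom: int = 0
    mismatches: list[tuple[str, int, str, str]] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return self.n_mismatch == 0 and self.n_unknown_chrom == 0


def verify_reference_consistency(
    snps: Iterable[SnpRecord], genome: GenomeSequence
) -> ConsistencyReport:
    """Check that each SNP's REF allele matches the genome base at its position.

    Mismatches are listed as (chrom, pos, expected=VCF ref, found=genome
    base); SNPs on chromosomes absent from the genome are counted
    separately, never silently dropped.
    """
    report = ConsistencyReport()
    for snp in snps:
        report.n_checked += 1
        if snp.chrom not in genome:
            report.n_unknown_chrom += 1
            continue
        found = genome.base(snp.chrom, snp.pos)
        if found != snp.ref_allele:
            report.n_mismatch += 1
            report.mismatches.append((snp.chrom, snp.pos, snp.ref_allele, found))
    return report


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 intervals (0-based half-open), preserving input order.

    A 4th column becomes the label. ``start >= end`` is a hard error
    reported with the offending line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            label = fields[3] if len(fields) > 3 else None
            intervals.append(GenomicInterval(chrom, start, end, label))
    return intervals


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3/BED4 (label column only when present)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


DBMESNP_COLUMNS = [
    "Chr", "Position", "Genome", "Ref", "Alt", "AF", "rsID",
    "Consequence", "Gene", "Functionality", "Biotype", "meSNP_class",
]


def write_dbmesnp_table(records, path: str | Path) -> int:
    """Write classified meSNP records as a tab-separated database table.

    The ``Genome`` column holds the trinucleotide context with the variant
    as the middle base. Missing annotation fields are written as ``.``.
    Returns the number of rows written.
    """

    def dot(value) -> str:
        return "." if value in (None, "") else str(value)

    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(DBMESNP_COLUMNS) + "\n")
        for rec in records:
            ctx = rec.context
            trinuc = (ctx.left_base or "") + ctx.center_ref + (ctx.right_base or "")
            row = [
                rec.chrom,
                str(rec.pos),
                trinuc,
                rec.ref_allele,
                rec.alt_allele,
                dot(rec.af),
                dot(rec.rsid),
                dot(rec.consequence),
                dot(rec.gene),
                dot(rec.functionality),
                dot(rec.biotype),
                rec.mesnp_class.value,
            ]
            fh.write("\t".join(row) + "\n")
            n += 1
    return n
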