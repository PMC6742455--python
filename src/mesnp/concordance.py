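"""Group-specific methylation regions and allele-frequency concordance.

Two phenotype groups of samples (e.g. high vs low feed efficiency) each
carry per-sample methylation peak sets. A region is *group-specific
hypermethylated* when a peak is present in at least ``min_present`` of
one group's samples and absent from every sample of the other group.

For meSNPs inside such regions, the alternate-allele frequency is
computed per group over non-missing genotypes; SNPs whose absolute
between-group frequency difference reaches a threshold (0.5 by default)
are tested for *methylation compatibility*: the CpG-forming (MSC) allele
must be at higher frequency in the hypermethylated group, equivalently
the CpG-free (MSD) allele in the hypomethylated group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from mesnp.core import MeSnpClass, MeSnpRecord
from mesnp.genomic_io import GenomicInterval, GenotypeCall


@dataclass
class SampleGroup:
    """A named phenotype group with per-sample methylation peak sets.

    ``peak_sets`` maps sample_id -> list of merged, non-overlapping
    intervals; genotype vectors elsewhere must follow ``sample_ids``
    order.
    """

    name: str
    sample_ids: list[str]
    peak_sets: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid in self.peak_sets:
            if sid not in self.sample_ids:
                raise ValueError(f"peak set for unknown sample {sid!r}")


def _coverage_runs(
    peaks_by_sample: Sequence[list[GenomicInterval]], chrom: str, min_cov: int
) -> list[tuple[int, int]]:
    """Maximal runs where >= min_cov samples have a peak, via event sweep."""
    events: list[tuple[int, int]] = []
    for sample_peaks in peaks_by_sample:
        for iv in sample_peaks:
            if iv.chrom == chrom:
                events.append((iv.start, +1))
                events.append((iv.end, -1))
    if not events:
        return []
    events.sort()
    runs: list[tuple[int, int]] = []
    cov = 0
    run_start: Optional[int] = None
    i = 0
    while i < len(events):
        pos = events[i][0]
        while i < len(events) and events[i][0] == pos:
            cov += events[i][1]
            i += 1
        if cov >= min_cov and run_start is None:
            run_start = pos
        elif cov < min_cov and run_start is not None:
            if pos > run_start:
                runs.append((run_start, pos))
            run_start = None
    return runs


def group_specific_peaks(
    group_a: SampleGroup,
    group_b: SampleGroup,
    min_present: int = 3,
    mode: str = "intersection",
) -> list[GenomicInterval]:
    """Regions hypermethylated specifically in one group.

    A region is emitted labelled with group A's name iff >= ``min_present``
    of A's samples have an overlapping peak there and no sample of B has
    any overlapping peak (>= 1 shared bp); symmetric for B. With the
    default ``mode="intersection"`` the emitted span is where the
    supporting peaks all overlap simultaneously; ``mode="union"`` emits
    the merged union of the supporting samples' overlapping peaks
    (re-checked against the absence rule).
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    for g in (group_a, group_b):
        if min_present > len(g.sample_ids):
            raise ValueError(
                f"min_present={min_present} exceeds group {g.name!r} size {len(g.sample_ids)}"
            )

    out: list[GenomicInterval] = []
    for own, other in ((group_a, group_b), (group_b, group_a)):
        own_peaks = [own.peak_sets.get(s, []) for s in own.sample_ids]
        other_peaks = [iv for s in other.sample_ids for iv in other.peak_sets.get(s, [])]
        other_trees: dict[str, IntervalTree] = {}
        for iv in other_peaks:
            other_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        chroms = sorted({iv.chrom for peaks in own_peaks for iv in peaks})
        for chrom in chroms:
            for start, end in _coverage_runs(own_peaks, chrom, min_present):
                region = (start, end)
                if mode == "union":
                    supporting = [
                        iv
                        for peaks in own_peaks
                        for iv in peaks
                        if iv.chrom == chrom and iv.start < end and iv.end > start
                    ]
                    region = (min(p.start for p in supporting), max(p.end for p in supporting))
                tree = other_trees.get(chrom)
                if tree is not None and tree.overlap(region[0], region[1]):
                    continue
                out.append(GenomicInterval(chrom, region[0], region[1], label=own.name))
    return out


def enumerate_genotype_states(n_samples: int, n_states: int = 4) -> int:
    """Number of genotype-vector combinations for a group of samples.

    With the four diploid states missing, hom-ref, het and hom-alt, a
    group of 4 samples admits 4**4 = 256 combinations.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return n_states ** n_samples


def count_with_min_called(n_samples: int, min_called: int, n_states: int = 4) -> int:
    """Combinations with at least ``min_called`` non-missing genotypes.

    Counted by exhaustive enumeration (state 0 is missing). For 4
    samples with >= 3 called this yields 189 = 3^4 + 4*3^3.
    """
    count = 0
    for combo in itertools.product(range(n_states), repeat=n_samples):
        if sum(1 for s in combo if s != 0) >= min_called:
            count += 1
    return count


@dataclass(frozen=True)
class GroupAFResult:
    """Per-group alternate-allele frequencies and their difference."""

    name_g1: str
    name_g2: str
    af_g1: Optional[float]
    af_g2: Optional[float]
    n_called_g1: int
    n_called_g2: int

    @property
    def callable(self) -> bool:
        return self.af_g1 is not None and self.af_g2 is not None

    @property
    def delta(self) -> Optional[float]:
        if not self.callable:
            return None
        return self.af_g1 - self.af_g2

    @property
    def abs_delta(self) -> Optional[float]:
        d = self.delta
        return None if d is None else abs(d)

    def af_of(self, group: str) -> Optional[float]:
        if group == self.name_g1:
            return self.af_g1
        if group == self.name_g2:
            return self.af_g2
        raise KeyError(f"unknown group {group!r}")


def _group_af(genotypes: Iterable[GenotypeCall]) -> tuple[Optional[float], int]:
    alt = 0
    n_called = 0
    for gt in genotypes:
        dose = gt.alt_dose
        if dose is None:
            continue
        n_called += 1
        alt += dose
    if n_called == 0:
        return None, 0
    return alt / (2 * n_called), n_called


def group_allele_frequencies(
    genotypes_g1: Sequence[GenotypeCall],
    genotypes_g2: Sequence[GenotypeCall],
    name_g1: str = "group1",
    name_g2: str = "group2",
) -> GroupAFResult:
    """Alternate-allele frequency per group over non-missing genotypes.

    AF = (sum of alternate alleles among called samples) / (2 * number of
    called samples). A group with no called genotypes is flagged
    uncallable (AF None).
    """
    af1, n1 = _group_af(genotypes_g1)
    af2, n2 = _group_af(genotypes_g2)
    return GroupAFResult(name_g1, name_g2, af1, af2, n1, n2)


def concordance_filter(
    result: GroupAFResult, min_called: int = 3, min_abs_delta: float = 0.5
) -> tuple[bool, Optional[str]]:
    """Pass iff both groups have enough called genotypes and the absolute
    between-group AF difference reaches the threshold.

    Returns (passed, reason); the reason distinguishes insufficient calls
    from insufficient delta.
    """
    if result.n_called_g1 < min_called or result.n_called_g2 < min_called:
        return False, "insufficient_calls"
    if not result.callable:
        return False, "insufficient_calls"
    if result.abs_delta < min_abs_delta:
        return False, "insufficient_delta"
    return True, None


def methylation_compatibility(
    record: MeSnpRecord, result: GroupAFResult, hyper_group: str
) -> Optional[bool]:
    """Is the allele-frequency pattern compatible with the methylation peak?

    For CREATE the MSC (CpG-forming) allele is the alternate; for DESTROY
    it is the reference, whose frequency is 1 - alt AF. Compatible iff
    the MSC allele frequency is strictly higher in the hypermethylated
    group (ties carry no signal and are incompatible). DISPLACE/NONE
    classes are indeterminate (None).
    """
    if record.mesnp_class not in (MeSnpClass.CREATE, MeSnpClass.DESTROY):
        return None
    if not result.callable:
        raise ValueError("AF result is uncallable; filter first")
    other = result.name_g2 if hyper_group == result.name_g1 else result.name_g1
    af_hyper = result.af_of(hyper_group)
    af_other = result.af_of(other)
    if record.mesnp_class is MeSnpClass.CREATE:
        msc_hyper, msc_other = af_hyper, af_other
    else:
        msc_hyper, msc_other = 1 - af_hyper, 1 - af_other
    return msc_hyper > msc_other


@dataclass
class CandidateMeSnp:
    """A concordance candidate: a meSNP inside a group-specific region."""

    tissue: str
    record: MeSnpRecord
    dmr: GenomicInterval  # label = hypermethylated group
    af_result: GroupAFResult
    compatible: Optional[bool] = None
    region_category: Optional[str] = None
    gene: Optional[str] = None
    qtl_hits: list[str] = field(default_factory=list)

    @property
    def hyper_group(self) -> str:
        if self.dmr.label is None:
            raise ValueError("candidate DMR lacks a hypermethylated-group label")
        return self.dmr.label


def qtl_overlap(
    candidates: list[CandidateMeSnp], qtls: list[GenomicInterval]
) -> list[CandidateMeSnp]:
    """Fill each candidate's QTL hits (same half-open membership rule)."""
    trees: dict[str, IntervalTree] = {}
    for iv in qtls:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.label)
    for cand in candidates:
        tree = trees.get(cand.record.chrom)
        if tree is None:
            cand.qtl_hits = []
            continue
        cand.qtl_hits = sorted(
            {hit.data for hit in tree[cand.record.pos - 1] if hit.data is not None}
        )
    return candidates


def candidate_table(candidates: Iterable[CandidateMeSnp]) -> pd.DataFrame:
    """Tabular report of candidates split by methylation compatibility.

    Rows carry a ``section`` column: "compatible", "incompatible", or
    "indeterminate" (DISPLACE/NONE classes, which have no MSC/MSD
    allele). Empty input yields a header-only frame.
    """
    rows = []
    for cand in candidates:
        rec = cand.record
        if cand.compatible is None:
            section = "indeterminate"
        else:
            section = "compatible" if cand.compatible else "incompatible"
        rows.append(
            {
                "section": section,
                "tissue": cand.tissue,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "rsid": rec.rsid,
                "ref": rec.ref_allele,
                "alt": rec.alt_allele,
                "mesnp_class": rec.mesnp_class.value,
                "hyper_group": cand.hyper_group,
                "group1": cand.af_result.name_g1,
                "af_group1": cand.af_result.af_g1,
                "group2": cand.af_result.name_g2,
                "af_group2": cand.af_result.af_g2,
                "region": cand.region_category,
                "gene": cand.gene,
                "qtl_hits": ",".join(cand.qtl_hits) if cand.qtl_hits else None,
            }
        )
    columns = [
        "section", "tissue", "chrom", "pos", "rsid", "ref", "alt",
        "mesnp_class", "hyper_group", "group1", "af_group1", "group2",
        "af_group2", "region", "gene", "qtl_hits",
    ]
    df = pd.DataFrame(rows, columns=columns)
    order = {"compatible": 0, "incompatible": 1, "indeterminate": 2}
    if not df.empty:
        df = df.sort_values(
            by=["section", "tissue", "chrom", "pos"],
            key=lambda col: col.map(order) if col.name == "section" else col,
            kind="stable",
        ).reset_index(drop=True)
    return df
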