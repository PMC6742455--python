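"""Chi-square enrichment of meSNPs inside genomic feature sets.

The null model places SNPs uniformly at random along each chromosome,
ignoring nucleotide composition: with n meSNPs on a chromosome of length
L and F feature base pairs (after merging overlaps), the expected count
inside features is n*F/L. The observed count is compared to that
expectation with a two-cell Pearson goodness-of-fit statistic on 1 df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2

from mesnp.core import MeSnpRecord
from mesnp.genomic_io import GenomeSequence, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    chrom: str
    observed: int
    expected: float
    total: int
    fold: Optional[float]
    chi_sq: Optional[float]
    p_value: Optional[float]
    significant: Optional[bool]
    testable: bool = True


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per chromosome (overlaps and abutments merged)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: iv.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def expected_count(n_mesnps: int, feature_bp: int, chrom_length: int) -> float:
    """Expected meSNPs in features under uniform placement: n * F / L."""
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    if not 0 <= feature_bp <= chrom_length:
        raise ValueError(
            f"feature bp {feature_bp} outside [0, {chrom_length}]; "
            "merge overlapping features before summing"
        )
    return n_mesnps * feature_bp / chrom_length


def chi_square_enrichment(
    observed: int,
    expected: float,
    total: int,
    alpha: float = 0.01,
    chrom: str = "",
    continuity_correction: bool = False,
) -> EnrichmentResult:
    """Two-cell Pearson goodness-of-fit of an observed count vs expectation.

    X^2 = (O-E)^2/E + ((T-O)-(T-E))^2/(T-E) on 1 df; significant iff the
    upper-tail p-value is below ``alpha``. Degenerate expectations
    (E <= 0 or E >= total) yield an untestable result rather than an
    error.
    """
    if not 0 <= observed <= total:
        raise ValueError(f"observed {observed} outside [0, {total}]")
    if expected <= 0 or expected >= total:
        return EnrichmentResult(
            chrom=chrom, observed=observed, expected=expected, total=total,
            fold=None, chi_sq=None, p_value=None, significant=None, testable=False,
        )
    d1 = abs(observed - expected)
    d2 = abs((total - observed) - (total - expected))
    if continuity_correction:
        d1 = max(d1 - 0.5, 0.0)
        d2 = max(d2 - 0.5, 0.0)
    stat = d1 ** 2 / expected + d2 ** 2 / (total - expected)
    p = float(chi2.sf(stat, df=1))
    return EnrichmentResult(
        chrom=chrom, observed=observed, expected=expected, total=total,
        fold=observed / expected, chi_sq=stat, p_value=p,
        significant=p < alpha, testable=True,
    )


def enrichment_report(
    records: Iterable[MeSnpRecord],
    features: Iterable[GenomicInterval],
    genome: GenomeSequence,
    alpha: float = 0.01,
    pooled: bool = False,
    continuity_correction: bool = False,
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-chromosome enrichment table plus a genome-wide average fold.

    Only meSNPs (CREATE/DESTROY/DISPLACE) are counted. Features are
    merged per chromosome before their lengths are summed. Chromosomes
    with no meSNPs or no feature bp are omitted from the table (logged).
    The average fold is by default the unweighted mean of per-chromosome
    folds; with ``pooled`` it is the genome-wide pooled observed/expected
    ratio instead.
    """
    merged = merge_intervals(features)
    feature_bp: dict[str, int] = {}
    by_chrom_feats: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        feature_bp[iv.chrom] = feature_bp.get(iv.chrom, 0) + iv.length
        by_chrom_feats.setdefault(iv.chrom, []).append(iv)

    n_mesnps: dict[str, int] = {}
    n_inside: dict[str, int] = {}
    for rec in records:
        if not rec.mesnp_class.is_mesnp:
            continue
        n_mesnps[rec.chrom] = n_mesnps.get(rec.chrom, 0) + 1
        offset = rec.pos - 1
        for iv in by_chrom_feats.get(rec.chrom, ()):
            if iv.start <= offset < iv.end:
                n_inside[rec.chrom] = n_inside.get(rec.chrom, 0) + 1
                break

    results: list[EnrichmentResult] = []
    for chrom in genome.chrom_names:
        n = n_mesnps.get(chrom, 0)
        fbp = feature_bp.get(chrom, 0)
        if n == 0 or fbp == 0:
            logger.info("chromosome %s omitted (n_mesnps=%d, feature_bp=%d)", chrom, n, fbp)
            continue
        exp = expected_count(n, fbp, genome.lengths[chrom])
        results.append(
            chi_square_enrichment(
                n_inside.get(chrom, 0), exp, n, alpha=alpha, chrom=chrom,
                continuity_correction=continuity_correction,
            )
        )

    table = pd.DataFrame(
        [
            {
                "chrom": r.chrom, "observed": r.observed, "expected": r.expected,
                "n_mesnps": r.total, "fold": r.fold, "chi_sq": r.chi_sq,
                "p_value": r.p_value, "significant": r.significant,
            }
            for r in results
        ]
    )
    if table.empty:
        return table, None
    if pooled:
        avg = float(table["observed"].sum() / table["expected"].sum())
    else:
        folds = table["fold"].dropna()
        avg = float(np.mean(folds)) if len(folds) else None
    return table, avg
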