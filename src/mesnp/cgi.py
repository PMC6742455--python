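"""CpG-island detection and membership annotation.

Islands are spans satisfying three criteria: minimum length (200 bp
relaxed, 500 bp strict), G+C content >= 0.50, and observed/expected CpG
ratio >= 0.60 using the Gardiner-Garden & Frommer form

    obs/exp = n_CpG * L / (n_C * n_G)

Detection scans a fixed 200-bp window at 1-bp steps, merges qualifying
windows and re-checks merged runs against the criteria. Users wishing to
reproduce a published island annotation exactly should load its interval
file via :func:`mesnp.genomic_io.read_intervals` instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
from intervaltree import IntervalTree

from mesnp.core import MeSnpRecord
from mesnp.genomic_io import GenomeSequence, GenomicInterval

WINDOW = 200


@dataclass(frozen=True)
class CgiCriteria:
    min_length: int
    min_gc: float = 0.50
    min_obs_exp: float = 0.60


RELAXED = CgiCriteria(min_length=200)
STRICT = CgiCriteria(min_length=500)


@dataclass(frozen=True)
class CgiStats:
    length: int
    gc_fraction: float
    n_cpg: int
    obs_exp: float

    def satisfies(self, criteria: CgiCriteria) -> bool:
        return (
            self.length >= criteria.min_length
            and self.gc_fraction >= criteria.min_gc
            and self.obs_exp >= criteria.min_obs_exp
        )


def window_stats(segment: str) -> CgiStats:
    """Length, GC fraction, CpG count and obs/exp ratio of a segment.

    Non-ACGT bases count as neither C nor G; obs/exp is defined as 0 when
    the segment has no C or no G.
    """
    if len(segment) < 1:
        raise ValueError("segment must be non-empty")
    seq = segment.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = seq.count("CG")  # CG cannot self-overlap; plain count suffices
    length = len(seq)
    gc = (n_c + n_g) / length
    obs_exp = (n_cpg * length / (n_c * n_g)) if n_c and n_g else 0.0
    return CgiStats(length=length, gc_fraction=gc, n_cpg=n_cpg, obs_exp=obs_exp)


def _qualifying_window_starts(seq: str, criteria: CgiCriteria) -> np.ndarray:
    """Start offsets of all WINDOW-bp windows passing GC and obs/exp."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cpg = np.zeros(len(arr), dtype=bool)
    if len(arr) >= 2:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]

    def windowed_sum(x: np.ndarray, w: int) -> np.ndarray:
        cs = np.concatenate([[0], np.cumsum(x)])
        return cs[w:] - cs[:-w]

    n = len(arr) - WINDOW + 1
    if n <= 0:
        return np.array([], dtype=np.int64)
    c_w = windowed_sum(is_c, WINDOW)
    g_w = windowed_sum(is_g, WINDOW)
    # only CpGs fully inside the window: starts i .. i+WINDOW-2
    cpg_w = windowed_sum(is_cpg, WINDOW - 1)[: n]
    gc_ok = (c_w + g_w) / WINDOW >= criteria.min_gc
    denom = (c_w * g_w).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(denom > 0, cpg_w * WINDOW / denom, 0.0)
    return np.nonzero(gc_ok & (obs_exp >= criteria.min_obs_exp))[0]


def detect_cgi(genome: GenomeSequence, criteria: CgiCriteria) -> list[GenomicInterval]:
    """Scan every chromosome for CpG islands under the given criteria.

    Qualifying 200-bp windows are merged when they overlap or touch, and
    each merged run is trimmed so that it begins and ends with a CpG
    (windows extend up to a window length past a CpG-rich block, and the
    trim removes that flanking slack). A trimmed run is kept only if it
    is at least ``criteria.min_length`` long and, on recomputation, still
    satisfies all the criteria. Deterministic; returns 0-based half-open
    intervals.
    """
    islands: list[GenomicInterval] = []
    for chrom in genome.chrom_names:
        seq = genome.sequence(chrom)
        starts = _qualifying_window_starts(seq, criteria)
        for run_start, run_end in _merge_runs(starts, WINDOW):
            trimmed = _trim_to_cpg(seq, run_start, run_end)
            if trimmed is None:
                continue
            start, end = trimmed
            if end - start < criteria.min_length:
                continue
            if window_stats(seq[start:end]).satisfies(criteria):
                islands.append(GenomicInterval(chrom, start, end, label="CGI"))
    return islands


def _trim_to_cpg(seq: str, start: int, end: int) -> Optional[tuple[int, int]]:
    """Shrink [start, end) to the first CpG start / last CpG end inside it."""
    first = seq.find("CG", start, end)
    if first == -1:
        return None
    last = seq.rfind("CG", start, end)
    return first, min(last + 2, end)


def _merge_runs(starts: np.ndarray, window: int) -> Iterator[tuple[int, int]]:
    """Merge window spans [s, s+window) whose starts overlap or touch."""
    if len(starts) == 0:
        return
    run_start = int(starts[0])
    prev = run_start
    for s in starts[1:]:
        s = int(s)
        if s <= prev + window:  # windows overlap or are adjacent
            prev = s
        else:
            yield run_start, prev + window
            run_start = prev = s
    yield run_start, prev + window


def build_interval_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def annotate_membership(
    records: Iterable[MeSnpRecord],
    intervals: list[GenomicInterval],
    label: str,
) -> Iterator[MeSnpRecord]:
    """Tag records falling inside any of the intervals with a feature label.

    A record at 1-based position p is inside [s, e) iff s <= p-1 < e.
    Labels accumulate across calls; intervals carrying their own label
    contribute ``label:interval_label`` so individual DMR/QTL identities
    survive.
    """
    trees = build_interval_trees(intervals)
    for rec in records:
        tree = trees.get(rec.chrom)
        if tree is not None:
            hits = tree[rec.pos - 1]
            for hit in hits:
                iv: GenomicInterval = hit.data
                if iv.label and iv.label != label:
                    rec.features.add(f"{label}:{iv.label}")
            if hits:
                rec.features.add(label)
        yield rec
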