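"""Brute-force reference routines used to cross-check the fast paths.

These deliberately avoid the windowed slot algebra: the reference
classifier rebuilds the entire mutated chromosome and diffs the full
sets of CpG start offsets, so agreement with
:func:`mesnp.core.classify_cpg_variant` is a genuine two-route check.
"""

from __future__ import annotations

from mesnp.core import MeSnpClass


def cpg_start_offsets(seq: str) -> set[int]:
    """0-based offsets i where seq[i:i+2] == 'CG'."""
    return {i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"}


def classify_by_sequence_diff(seq: str, pos: int, ref: str, alt: str) -> MeSnpClass:
    """Classify a substitution by diffing full-sequence CpG sets.

    ``pos`` is 1-based; ``seq[pos-1]`` must equal ``ref``. CREATE iff the
    mutated sequence gains >=1 CpG and loses none; DESTROY iff it loses
    >=1 and gains none; DISPLACE iff it loses exactly one and gains
    exactly one at a different offset; NONE iff the sets are equal.
    """
    i = pos - 1
    if seq[i] != ref:
        raise ValueError(f"reference mismatch at {pos}: genome {seq[i]}, ref {ref}")
    before = cpg_start_offsets(seq)
    after = cpg_start_offsets(seq[:i] + alt + seq[i + 1 :])
    gained = after - before
    lost = before - after
    if not gained and not lost:
        return MeSnpClass.NONE
    if gained and not lost:
        return MeSnpClass.CREATE
    if lost and not gained:
        return MeSnpClass.DESTROY
    if len(gained) == 1 and len(lost) == 1:
        return MeSnpClass.DISPLACE
    raise AssertionError("a single substitution cannot move more than one CpG")


def brute_force_islands(seq: str, min_length: int, min_gc: float, min_obs_exp: float):
    """All maximal spans >= min_length whose every covering criterion holds.

    O(L^2); only for tiny fixtures. Returns (start, end) pairs of spans
    that satisfy the criteria and are not contained in a longer
    satisfying span.
    """
    from mesnp.cgi import window_stats

    n = len(seq)
    hits = []
    for start in range(n):
        for end in range(start + min_length, n + 1):
            stats = window_stats(seq[start:end])
            if (
                stats.gc_fraction >= min_gc
                and stats.obs_exp >= min_obs_exp
            ):
                hits.append((start, end))
    maximal = [
        (s, e)
        for s, e in hits
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in hits)
    ]
    return maximal
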