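"""Seeded synthetic fixtures: genome, classified SNPs, cohort with peaks.

The generator emulates the shape of a cattle methylation study: a
multi-chromosome reference with planted CpG islands on a low-GC
background, SNPs of every meSNP class at known positions, and two
phenotype groups of four diploid samples whose per-sample methylation
peak sets contain planted group-specific regions harbouring meSNPs with
planned between-group allele-frequency differences.

All randomness flows through one ``numpy`` generator derived from the
single integer seed; identical (seed, spec) pairs produce byte-identical
outputs. Truth tables record, for every planted object, what a correct
analysis must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from mesnp.cgi import RELAXED, window_stats
from mesnp.genomic_io import GenomicInterval

# trinucleotide recipes: (left, center_ref, right, ref, alt) per class
_RECIPES = {
    "create": ("T", "A", "G", "A", "C"),    # TAG -> TCG
    "destroy": ("T", "C", "G", "C", "T"),   # TCG -> TTG
    "displace": ("C", "G", "G", "G", "C"),  # CGG -> CCG
    "none": ("A", "C", "A", "C", "T"),      # ACA -> ATA
}


@dataclass(frozen=True)
class PlantedIsland:
    chrom: str
    start: int  # 0-based
    length: int
    cpg_density: float = 0.3


@dataclass(frozen=True)
class ConcordancePlan:
    """One planted concordance locus inside a group-specific peak region."""

    mesnp_class: str           # "create" or "destroy"
    hyper_group: str
    af: dict[str, float]       # planned alternate-allele frequency per group
    region_length: int = 600
    present_in: int = 3        # samples of the hyper group carrying the peak


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 50_000
    gc_background: float = 0.35
    planted_islands: tuple[PlantedIsland, ...] = (
        PlantedIsland("chr1", 10_000, 400),
        PlantedIsland("chr1", 30_000, 800),
        PlantedIsland("chr2", 20_000, 600),
    )
    planted_snps: tuple[tuple[str, int], ...] = (
        ("create", 10), ("destroy", 10), ("displace", 5), ("none", 5),
    )
    group_names: tuple[str, str] = ("HFE", "LFE")
    group_size: int = 4
    concordance_plans: tuple[ConcordancePlan, ...] = (
        ConcordancePlan("create", "HFE", {"HFE": 1.0, "LFE": 0.0}),
        ConcordancePlan("destroy", "HFE", {"HFE": 0.0, "LFE": 1.0}),
        ConcordancePlan("create", "LFE", {"LFE": 0.0, "HFE": 1.0}),
        ConcordancePlan("destroy", "LFE", {"LFE": 1.0, "HFE": 0.0}),
    )
    missing_rate: float = 0.0

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


class _Occupancy:
    """Tracks claimed spans per chromosome so plants never collide."""

    def __init__(self) -> None:
        self._spans: dict[str, list[tuple[int, int]]] = {}

    def claim(self, chrom: str, start: int, end: int) -> None:
        if self.overlaps(chrom, start, end):
            raise ValueError(f"planted span {chrom}:{start}-{end} overlaps an earlier plant")
        self._spans.setdefault(chrom, []).append((start, end))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self._spans.get(chrom, []))


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def _island_sequence(rng: np.random.Generator, length: int, cpg_density: float) -> str:
    """A CG-rich block satisfying the relaxed island criteria by construction."""
    pairs = []
    bases = "ACGT"
    # non-CpG pairs drawn GC-rich so GC content stays >= 0.5
    p_base = [0.2, 0.3, 0.3, 0.2]
    n_pairs = (length + 1) // 2
    use_cpg = rng.random(n_pairs) < cpg_density
    for flag in use_cpg:
        if flag:
            pairs.append("CG")
        else:
            b1, b2 = rng.choice(list(bases), size=2, p=p_base)
            if b1 == "C" and b2 == "G":  # keep CpG count at the planned density
                b2 = "C"
            pairs.append(b1 + b2)
    seq = "".join(pairs)[:length]
    stats = window_stats(seq)
    if not (stats.gc_fraction >= RELAXED.min_gc and stats.obs_exp >= RELAXED.min_obs_exp):
        raise ValueError(
            f"island construction failed criteria (gc={stats.gc_fraction:.2f}, "
            f"obs_exp={stats.obs_exp:.2f}); raise cpg_density"
        )
    return seq


def make_genome(
    spec: FixtureSpec, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Background genome with planted CpG islands.

    Returns (sequences, truth island intervals). Overlapping or
    out-of-bounds planted islands are an error.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    occupancy = _Occupancy()
    seqs: dict[str, np.ndarray] = {
        chrom: _random_background(rng, spec.chrom_length, spec.gc_background)
        for chrom in spec.chrom_names
    }
    truth: list[GenomicInterval] = []
    for island in spec.planted_islands:
        if island.chrom not in seqs:
            raise ValueError(f"island on unknown chromosome {island.chrom!r}")
        end = island.start + island.length
        if island.start < 0 or end > spec.chrom_length:
            raise ValueError(f"island {island} outside chromosome bounds")
        occupancy.claim(island.chrom, island.start, end)
        block = _island_sequence(rng, island.length, island.cpg_density)
        seqs[island.chrom][island.start:end] = np.frombuffer(
            block.encode("ascii"), dtype=np.uint8
        )
        truth.append(GenomicInterval(island.chrom, island.start, end, label="island"))
    return {c: a.tobytes().decode("ascii") for c, a in seqs.items()}, truth


def _free_positions(
    spec: FixtureSpec,
    occupied: _Occupancy,
    rng: np.random.Generator,
    n: int,
    margin: int = 5,
) -> list[tuple[str, int]]:
    """Sample n well-separated 1-based positions outside occupied spans."""
    out: list[tuple[str, int]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError("cannot place requested plants; genome too small/crowded")
        chrom = spec.chrom_names[int(rng.integers(spec.n_chroms))]
        pos = int(rng.integers(1 + margin, spec.chrom_length - margin))
        if occupied.overlaps(chrom, pos - 1 - margin, pos + margin):
            continue
        occupied.claim(chrom, pos - 1 - margin, pos + margin)
        out.append((chrom, pos))
    return out


def _plant_snp(
    seqs: dict[str, str], chrom: str, pos: int, mesnp_class: str
) -> tuple[str, str]:
    """Overwrite the trinucleotide at a 1-based position; return (ref, alt)."""
    left, center, right, ref, alt = _RECIPES[mesnp_class]
    s = seqs[chrom]
    i = pos - 1
    seqs[chrom] = s[: i - 1] + left + center + right + s[i + 2 :]
    return ref, alt


def make_snps(
    seqs: dict[str, str],
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
    occupied: Optional[_Occupancy] = None,
) -> pd.DataFrame:
    """Plant SNPs of each requested class, editing the genome in place.

    The genome context is rewritten first so that every planted SNP's
    class, classified against the emitted reference, equals its truth
    label exactly. Returns the truth table (chrom, pos, ref, alt, class),
    sorted by position.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if occupied is None:
        occupied = _Occupancy()
        for island in spec.planted_islands:
            occupied.claim(island.chrom, island.start, island.start + island.length)
    rows = []
    for mesnp_class, count in spec.planted_snps:
        if mesnp_class not in _RECIPES:
            raise ValueError(f"unknown class {mesnp_class!r}")
        for chrom, pos in _free_positions(spec, occupied, rng, count):
            ref, alt = _plant_snp(seqs, chrom, pos, mesnp_class)
            rows.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "class": mesnp_class}
            )
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "class", "rsid"])
    truth = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    truth["rsid"] = [f"sim_{c}_{i}" for i, c in enumerate(truth["class"])]
    return truth


@dataclass
class CohortFixture:
    """Everything make_cohort plants, with per-object truth."""

    sample_ids: dict[str, list[str]]               # group -> sample ids
    peak_sets: dict[str, list[GenomicInterval]]    # sample id -> peaks
    regions: list[GenomicInterval]                 # truth group-specific regions
    loci: pd.DataFrame                             # truth per concordance locus
    genotypes: dict[str, dict[str, list[int]]]     # rsid -> group -> alt doses (-1 missing)


def _allocate_genotypes(
    af: float, n: int, rng: np.random.Generator, missing_rate: float
) -> list[int]:
    """Alt-allele doses summing to round(af*2n), shuffled; -1 marks missing."""
    total_alt = int(round(af * 2 * n))
    doses = [2] * (total_alt // 2) + [1] * (total_alt % 2)
    doses += [0] * (n - len(doses))
    rng.shuffle(doses)
    if missing_rate > 0:
        doses = [-1 if rng.random() < missing_rate else d for d in doses]
    return doses


def make_cohort(
    seqs: dict[str, str],
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
    occupied: Optional[_Occupancy] = None,
) -> CohortFixture:
    """Plant group-specific peak regions, concordance meSNPs and genotypes.

    Each plan yields one region present (as an identical peak) in
    ``present_in`` samples of its hyper group and absent from the other
    group, containing one meSNP of the planned class whose genotypes
    realise the planned per-group alternate-allele frequencies. Decoy
    peaks that must NOT be recovered are also planted: one shared by all
    samples of both groups and one present in too few samples. Truth
    compatibility labels are derived from the realised allele counts by
    direct arithmetic.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if occupied is None:
        occupied = _Occupancy()
    g1, g2 = spec.group_names
    sample_ids = {g: [f"{g}_{i + 1}" for i in range(spec.group_size)] for g in (g1, g2)}
    peak_sets: dict[str, list[GenomicInterval]] = {
        sid: [] for g in (g1, g2) for sid in sample_ids[g]
    }
    regions: list[GenomicInterval] = []
    loci_rows = []
    genotypes: dict[str, dict[str, list[int]]] = {}

    for idx, plan in enumerate(spec.concordance_plans):
        if plan.hyper_group not in (g1, g2):
            raise ValueError(f"unknown hyper group {plan.hyper_group!r}")
        if not 1 <= plan.present_in <= spec.group_size:
            raise ValueError("present_in outside group size")
        for g, af in plan.af.items():
            if not 0 <= af <= 1:
                raise ValueError(f"planned AF {af} outside [0,1]")
        # place the region
        placed = False
        for _ in range(1000):
            chrom = spec.chrom_names[int(rng.integers(spec.n_chroms))]
            start = int(rng.integers(10, spec.chrom_length - plan.region_length - 10))
            if not occupied.overlaps(chrom, start - 5, start + plan.region_length + 5):
                occupied.claim(chrom, start - 5, start + plan.region_length + 5)
                placed = True
                break
        if not placed:
            raise ValueError("cannot place concordance region; genome too crowded")
        end = start + plan.region_length
        region = GenomicInterval(chrom, start, end, label=plan.hyper_group)
        regions.append(region)
        carriers = list(sample_ids[plan.hyper_group])
        rng.shuffle(carriers)
        for sid in carriers[: plan.present_in]:
            peak_sets[sid].append(GenomicInterval(chrom, start, end))

        # plant the meSNP mid-region
        pos = start + plan.region_length // 2  # 1-based == 0-based+1 offset is fine mid-region
        ref, alt = _plant_snp(seqs, chrom, pos, plan.mesnp_class)
        rsid = f"cand_{idx}"
        doses = {
            g: _allocate_genotypes(plan.af[g], spec.group_size, rng, spec.missing_rate)
            for g in (g1, g2)
        }
        genotypes[rsid] = doses

        # realised AFs and truth labels by direct arithmetic
        real_af, n_called = {}, {}
        for g in (g1, g2):
            called = [d for d in doses[g] if d >= 0]
            n_called[g] = len(called)
            real_af[g] = sum(called) / (2 * len(called)) if called else float("nan")
        hypo = g2 if plan.hyper_group == g1 else g1
        delta = real_af[g1] - real_af[g2]
        passes = (
            n_called[g1] >= 3 and n_called[g2] >= 3 and abs(delta) >= 0.5
        )
        if plan.mesnp_class == "create":
            msc_hyper, msc_hypo = real_af[plan.hyper_group], real_af[hypo]
        else:
            msc_hyper, msc_hypo = 1 - real_af[plan.hyper_group], 1 - real_af[hypo]
        loci_rows.append(
            {
                "rsid": rsid, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "class": plan.mesnp_class, "hyper_group": plan.hyper_group,
                f"af_{g1}": real_af[g1], f"af_{g2}": real_af[g2],
                "abs_delta": abs(delta), "passes_filter": passes,
                "compatible": bool(msc_hyper > msc_hypo),
            }
        )

    # decoy peaks: shared everywhere, and present in too few samples
    for _ in range(1000):
        chrom = spec.chrom_names[int(rng.integers(spec.n_chroms))]
        start = int(rng.integers(10, spec.chrom_length - 400))
        if not occupied.overlaps(chrom, start, start + 300):
            occupied.claim(chrom, start, start + 300)
            for sid in peak_sets:
                peak_sets[sid].append(GenomicInterval(chrom, start, start + 300))
            break
    for _ in range(1000):
        chrom = spec.chrom_names[int(rng.integers(spec.n_chroms))]
        start = int(rng.integers(10, spec.chrom_length - 400))
        if not occupied.overlaps(chrom, start, start + 300):
            occupied.claim(chrom, start, start + 300)
            for sid in sample_ids[g1][:2]:  # 2 of 4: below the min-present rule
                peak_sets[sid].append(GenomicInterval(chrom, start, start + 300))
            break

    for sid in peak_sets:
        peak_sets[sid].sort(key=lambda iv: (iv.chrom, iv.start))
    loci = pd.DataFrame(loci_rows)
    return CohortFixture(sample_ids, peak_sets, regions, loci, genotypes)


# ---------------------------------------------------------------------------
# file emission


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _contig_lines(seqs: dict[str, str]) -> str:
    return "".join(f"##contig=<ID={c},length={len(s)}>\n" for c, s in seqs.items())


def write_snp_vcf(truth: pd.DataFrame, seqs: dict[str, str], path: str | Path) -> None:
    """Sites-only VCF for the planted classified SNPs."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER + _contig_lines(seqs))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in truth.itertuples():
            fh.write(f"{row.chrom}\t{row.pos}\t{row.rsid}\t{row.ref}\t{row.alt}\t.\tPASS\t.\n")


_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_cohort_vcf(
    cohort: CohortFixture, loci: pd.DataFrame, seqs: dict[str, str], path: str | Path
) -> list[str]:
    """Genotyped VCF for the concordance loci; returns sample column order."""
    g1, g2 = list(cohort.sample_ids)
    samples = cohort.sample_ids[g1] + cohort.sample_ids[g2]
    ordered = loci.sort_values(["chrom", "pos"])
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER + _contig_lines(seqs))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for row in ordered.itertuples():
            doses = cohort.genotypes[row.rsid]
            gts = [_GT_STRINGS[d] for d in doses[g1]] + [_GT_STRINGS[d] for d in doses[g2]]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.rsid}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
    return samples


def simulate(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit the full fixture set to a directory; returns the file map.

    Files: genome.fa, snps.vcf, cohort.vcf, peaks per sample (BED),
    groups.tsv, truth_islands.bed, truth_snps.tsv, truth_regions.bed,
    truth_loci.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    seqs, islands = make_genome(spec, rng)
    occupied = _Occupancy()
    for island in spec.planted_islands:
        occupied.claim(island.chrom, island.start, island.start + island.length)
    snp_truth = make_snps(seqs, spec, rng, occupied)
    cohort = make_cohort(seqs, spec, rng, occupied)

    files: dict[str, Path] = {}
    files["genome"] = outdir / "genome.fa"
    write_fasta(seqs, files["genome"])
    files["snps_vcf"] = outdir / "snps.vcf"
    write_snp_vcf(snp_truth, seqs, files["snps_vcf"])
    files["cohort_vcf"] = outdir / "cohort.vcf"
    write_cohort_vcf(cohort, cohort.loci, seqs, files["cohort_vcf"])
    files["truth_islands"] = outdir / "truth_islands.bed"
    with open(files["truth_islands"], "w") as fh:
        for iv in islands:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
    files["truth_snps"] = outdir / "truth_snps.tsv"
    snp_truth.to_csv(files["truth_snps"], sep="\t", index=False)
    files["truth_regions"] = outdir / "truth_regions.bed"
    with open(files["truth_regions"], "w") as fh:
        for iv in cohort.regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
    files["truth_loci"] = outdir / "truth_loci.tsv"
    cohort.loci.to_csv(files["truth_loci"], sep="\t", index=False)
    files["groups"] = outdir / "groups.tsv"
    with open(files["groups"], "w") as fh:
        for group, sids in cohort.sample_ids.items():
            for sid in sids:
                fh.write(f"{sid}\t{group}\n")
    for sid, peaks in cohort.peak_sets.items():
        p = outdir / f"peaks_{sid}.bed"
        with open(p, "w") as fh:
            for iv in peaks:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        files[f"peaks_{sid}"] = p
    return files
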