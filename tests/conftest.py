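import numpy as np
import pytest

from mesnp.fixtures import FixtureSpec, simulate
from mesnp.genomic_io import load_genome


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory):
    """A complete simulated fixture set written once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    return simulate(FixtureSpec(seed=11), outdir)


@pytest.fixture(scope="session")
def fixture_genome(fixture_files):
    return load_genome(fixture_files["genome"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


def write_vcf(path, rows, samples=()):
    """rows: (chrom, pos, rsid, ref, alt[, gts]) tuples."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = {r[0] for r in rows}
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c},length=1000000>\n")
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            header += "\tFORMAT\t" + "\t".join(samples)
        fh.write(header + "\n")
        for row in rows:
            chrom, pos, rsid, ref, alt = row[:5]
            line = f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t."
            if samples:
                line += "\tGT\t" + "\t".join(row[5])
            fh.write(line + "\n")
    return path
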