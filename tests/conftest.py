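"""Shared fixtures: tiny hand-written VCF/TSV inputs and simulated datasets."""
import textwrap

import numpy as np
import pytest

from divscan.samples import SampleTable


@pytest.fixture
def mixed_ploidy_table() -> SampleTable:
    """Two diploids in pop A, one haploid + one diploid in pop B."""
    return SampleTable.from_records([
        ("a1", "A", 2), ("a2", "A", 2), ("b1", "B", 1), ("b2", "B", 2),
    ])


@pytest.fixture
def tiny_vcf(tmp_path):
    """Hand-written VCF exercising every record-level filter.

    Samples: a1, a2 diploid (pop A); b1 haploid, b2 diploid (pop B).
    """
    text = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=100000>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta1\ta2\tb1\tb2
        chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t0\t0/0
        chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t0/0\t./.\t1\t0/1
        chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/0\t0/1\t0/0
        chr1\t400\t.\tT\tC,G\t.\tPASS\t.\tGT\t0/1\t0/2\t0\t0/0
        chr1\t500\t.\tA\tAT\t.\tPASS\t.\tGT\t0/1\t0/0\t0\t0/0
        chr1\t600\t.\tG\tC\t.\tlowqual\t.\tGT\t0/1\t0/0\t0\t0/0
        chr1\t700\t.\tA\tT\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1\t1/1
        """)
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def window_grid():
    """Ten 20-kb windows on one 200-kb chromosome."""
    from divscan.windows import make_windows
    return make_windows({"chr1": 200_000}, 20_000)


@pytest.fixture(scope="session")
def sympatric_run():
    """One sympatric-regime simulation run through the window pipeline."""
    import divscan as ds
    from divscan import simulate as sim

    params = sim.sympatric_params(seed=7)
    rng = np.random.default_rng(7)
    sf = sim.simulate_frequencies(params, rng)
    counts = sim.sample_allele_counts(sf, params, rng)
    stats = ds.window_stats(counts, params.windows())
    return params, sf, stats
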