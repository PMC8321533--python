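#!/usr/bin/env python
"""Window statistics (π, d_XY, Hudson F_ST, ZF_ST) for both regimes.

Reads the VCFs written by 01_simulate.py through the mixed-ploidy reader and
writes per-window statistics tables to results/window_stats_<mode>.tsv.
"""
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from _paths import SCRATCH  # noqa: E402

from divscan import (load_sample_table, make_windows, read_chrom_lengths,  # noqa: E402
                     read_sites_table, window_stats)


def main():
    for mode in ("sympatric", "allopatric"):
        d = os.path.join(SCRATCH, mode)
        if not os.path.exists(os.path.join(d, "sim.vcf")):
            sys.exit(f"missing {d}/sim.vcf — run 01_simulate.py first")
        table = load_sample_table(os.path.join(d, "samples.tsv"))
        lengths = read_chrom_lengths(os.path.join(d, "chrom_lengths.tsv"))
        sites = read_sites_table(os.path.join(d, "sim.vcf"), table)
        stats = window_stats(sites, make_windows(lengths))
        out = os.path.join(SCRATCH, mode, "window_stats.tsv")
        stats.to_csv(out, sep="\t", index=False)
        r = sites.report
        fcol = "fst_pop1_pop2"
        print(f"[{mode}] {r.n_kept:,}/{r.n_records:,} sites kept; "
              f"{len(stats)} windows; mean F_ST "
              f"{stats[fcol].mean():.3f}, mean dxy "
              f"{stats['dxy_pop1_pop2'].mean():.5f} -> {out}")


if __name__ == "__main__":
    main()
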