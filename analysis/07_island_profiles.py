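#!/usr/bin/env python
"""Distance profiles of π, ZF_ST and d_XY around island centers.

Averages each statistic in 20-kb steps up to 2 Mb from the called island
centers (both regimes) and reports where each profile returns to the
genome-wide mean. Expected pattern: d_XY stays above the genome mean away
from sympatric-regime centers (gene-flow barriers) but below it around
allopatric-regime centers (ancestral linked selection).
"""
import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from _paths import RESULTS, SCRATCH  # noqa: E402

from divscan import (RegionSet, crossing_distance, profile,  # noqa: E402
                     read_chrom_lengths)

MAX_DIST = 2_000_000


def main():
    for mode in ("sympatric", "allopatric"):
        stats = pd.read_csv(
            os.path.join(SCRATCH, mode, "window_stats.tsv"), sep="\t")
        lengths = read_chrom_lengths(
            os.path.join(SCRATCH, mode, "chrom_lengths.tsv"))
        iods = RegionSet.from_bed(
            os.path.join(RESULTS, f"islands_{mode}.bed"), lengths)
        for stat in ("pi_pop1", "zfst_pop1_pop2", "dxy_pop1_pop2"):
            prof = profile(stats, iods, stat, max_dist=MAX_DIST)
            out = os.path.join(RESULTS, f"profile_{mode}_{stat}.tsv")
            prof.to_csv(out, sep="\t", index=False)
            gm = prof["genome_mean"].iloc[0]
            center = prof.loc[prof["distance_bp"] == 0, "mean_stat"].iloc[0]
            direction = "above" if center > gm else "below"
            d = crossing_distance(prof, direction=direction)
            d_txt = f"{d/1e6:.2f} Mb" if np.isfinite(d) else "never"
            print(f"[{mode}] {stat}: center {center:.4g} vs genome mean "
                  f"{gm:.4g} ({direction}); returns to mean at {d_txt}")


if __name__ == "__main__":
    main()
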