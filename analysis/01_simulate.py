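#!/usr/bin/env python
"""Generate the two synthetic study regimes and the calibration dataset.

Writes mixed-ploidy VCFs (heavy, to scratch/analysis/) and the per-window
generative truth tables (to results/):

* sympatric regime — gene-flow barriers: 300-kb barrier blocks (t_eff = t,
  λ = 0.25) on five 10-Mb chromosomes, background homogenized by g = 0.5;
* allopatric regime — no gene flow anywhere; the same blocks are
  low-recombination (λ = 0.25) background, drifting faster but with reduced
  absolute divergence;
* drift-only regime — one 40-Mb chromosome of homogeneous windows for
  split-time calibration (expected fixation index ≈ 0.34).
"""
import os
import sys

import numpy as np

sys.path.insert(0, os.path.dirname(__file__))
from _paths import SCRATCH  # noqa: E402

from divscan import simulate as sim  # noqa: E402

SEED = 11


def main():
    for mode, maker in [("sympatric", sim.sympatric_params),
                        ("allopatric", sim.allopatric_params),
                        ("driftonly", sim.driftonly_params)]:
        params = maker(seed=SEED)
        rng = np.random.default_rng(SEED)
        sf = sim.simulate_frequencies(params, rng)
        table, geno = sim.sample_genotypes(sf, params, rng)
        outdir = os.path.join(SCRATCH, mode)
        paths = sim.write_outputs(outdir, sf, table, geno, params)
        n_barrier = int((sf.truth["class"] != "background").sum())
        print(f"[{mode}] {len(sf):,} sites, {len(table.samples)} samples "
              f"({sum(p == 1 for p in table.ploidies)} haploid), "
              f"{n_barrier}/{len(sf.truth)} non-background windows "
              f"-> {paths['vcf']}")


if __name__ == "__main__":
    main()
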