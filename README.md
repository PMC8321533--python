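# divscan

Windowed divergence landscapes, islands of divergence, and haplodiploid
divergence-time estimation from mixed-ploidy variant data.

When two diverging populations or young species are compared along the
genome, relative divergence (F_ST) is rarely flat: it concentrates in
contiguous blocks — *islands of divergence* (IoDs) — that can arise from two
very different mechanisms. Barriers to gene flow between hybridizing taxa
locally *elevate* absolute divergence (d_XY), while linked selection in
low-recombination regions of the ancestor *reduces* it. Telling these
apart, and dating the split itself, is the core task this package supports,
with first-class handling of haplodiploid data (haploid males + diploid
females, as in bees and other Hymenoptera).

It is aimed at population geneticists with a multi-sample VCF, a
sample→population/ploidy table, and optionally region BEDs (repeat arrays,
centromere candidates) to test against.

## What it computes

* **Window statistics** (20-kb nonoverlapping windows by default):
  nucleotide diversity π = 2a(n−a)/(n(n−1)) per population, absolute
  divergence d_XY = p₁(1−p₂) + p₂(1−p₁), and Hudson's F_ST as a
  ratio-of-averages over per-site components, standardized to
  ZF_ST = (F_ST − median)/SD; window GC content and stat–stat correlations.
* **Branch statistics**: T = −ln(1 − F_ST) and the population branch
  statistic PBS₁ = (T₁₂ + T₁₀ − T₂₀)/2 against an outgroup.
* **Islands of divergence**: windows with ZF_ST ≥ 2 merged within 60 kb,
  blocks > 100 kb kept, optional 1-Mb second merge; inside/outside Wilcoxon
  contrasts and distance profiles around island centers.
* **Region-overlap permutation tests**: randomize regions per chromosome
  preserving sizes; empirical p, Z-score, fold enrichment.
* **Divergence time**: θ_w = K/(a_n·L), haplodiploid N_e = θ_w/(3µ),
  t = 3·N_e·mean(T) over windows outside islands, percentile bootstrap CI
  (5,000 replicates).
* **Synthetic data**: a generator producing mixed-ploidy VCFs with
  window-structured divergence (gene-flow barrier vs linked-selection
  regimes) and a truth BED, so the whole pipeline runs without any external
  download. See `docs/methods.md` for the model.

## Worked example

Simulate a "sympatric" dataset (five 10-Mb chromosomes, one 300-kb
gene-flow-barrier block each, 50 samples of mixed ploidy) and run the whole
pipeline:

```sh
divscan simulate --mode sympatric --out demo/data --seed 11
cat > demo/cfg.yaml <<EOF
vcf: demo/data/sim.vcf
samples: demo/data/samples.tsv
chrom_lengths: demo/data/chrom_lengths.tsv
truth_bed: demo/data/truth_barrier.bed
outdir: demo/run
pair: [pop1, pop2]
ne: 1000.0
second_merge_gap: 1000000
EOF
divscan run-all --config demo/cfg.yaml --seed 11
```

which prints

```
5 islands; t = 4120 (95% CI 4088-4152); manifest 905a524e8217
```

— the caller found the five simulated barrier blocks, and the split-time
estimate over background windows exceeds the generative background
t_eff = 1000 because injected fixed differences inflate F_ST there (see
`docs/methods.md`). `demo/run/inside_outside.tsv` holds the diagnostic
contrast: d_XY is **+36%** inside islands (rank-sum p ≈ 4×10⁻²⁶) while π
drops by ~98% — the gene-flow-barrier signature. Testing the called islands
against the simulated truth:

```sh
divscan permtest --a demo/run/islands.bed --b demo/data/truth_barrier.bed \
    --chrom-lengths demo/data/chrom_lengths.tsv --seed 11
# observed 5 of 5 islands on truth blocks; null mean 0.33; Z = 8.4;
# p = 0.001; fold enrichment 15.2
```

An `allopatric` simulation (same blocks, no gene flow, linked selection
only) yields islands with d_XY about 40% *below* background — the opposite
signature, produced by the same pipeline.

The `analysis/` directory contains the same workflow as numbered narrative
scripts (`01_simulate.py` … `07_island_profiles.py`), writing summary
tables under `results/` and heavy intermediates under `scratch/`.

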