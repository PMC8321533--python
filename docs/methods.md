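# Methods

`divscan` implements a comparative divergence-landscape analysis for
mixed-ploidy population resequencing data: windowed diversity and divergence
statistics, detection of islands of divergence (IoDs), branch statistics,
region-overlap permutation tests, and haplodiploid divergence-time
estimation, together with a synthetic-data generator that makes every stage
testable at desk scale. This note records the models, the defaults and why,
the numerical choices, and the known limitations.

## Input model and site filtering

The unit of input is a multi-sample VCF of biallelic SNPs plus a sample
table assigning each sample a population and a ploidy (1 or 2). A
haplodiploid dataset mixes haploid males and diploid females, so the number
of sampled chromosomes per population is the sum of ploidies. Record-level
filters: multiallelic records, non-SNPs and FILTER-failed records are
skipped; a heterozygous call in a ploidy-1 sample indicates a genotyping
artifact (typically collapsed paralogy) and drops the whole site. Haploid
genotypes are accepted both haploid-style (`0`, `1`) and as homozygous
diploid calls (`0/0`, `1/1`), since callers emit both dialects. Missing
alleles reduce the population's called count; a site with no calls in one
population of a pair is excluded for that pair only, which maximizes data
use. Every skip reason is counted and the counters must account exactly for
the dropped records (asserted in tests).

VCF coordinates are 1-based; all internal window and interval arithmetic is
0-based half-open, with conversion at the reader boundary only.

## Window statistics

All statistics are computed in nonoverlapping windows (default 20 kb) from
per-site, per-population allele counts (a, n):

* π = 2a(n−a)/(n(n−1)) — unbiased heterozygosity; undefined for n < 2;
* d_XY = p₁(1−p₂) + p₂(1−p₁) with pᵢ = aᵢ/nᵢ;
* Hudson's F_ST with sample-size-corrected numerator
  (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and denominator d_XY,
  combined per window as a ratio of averages (Σnum/Σden). Hudson's
  estimator is the recommended two-population choice: it is nearly unbiased
  at small and unequal sample sizes, and the ratio-of-averages windowing
  avoids the instability of averaging per-site ratios. Weir & Cockerham's
  estimator is not implemented; for the two-population comparisons here the
  two agree closely except under strong sample-size imbalance, which Hudson
  handles better.

Per-base π and d_XY divide by the accessible window span (optionally minus
masked bases) because the VCF carries variant sites only — absent sites are
monomorphic. A "per-genotyped-site" denominator is available; the choice
rescales π/d_XY uniformly and cancels in inside/outside contrasts. Windows
with fewer than `min_snps` (default 10) usable SNPs report NA for all
statistics. Negative window F_ST values are retained, not clamped: clamping
would bias the genome-wide median used for standardization.

ZF_ST = (window F_ST − median F_ST)/SD(F_ST), median and sample SD taken
over all non-NA windows of the comparison. Standardization puts comparisons
with different overall divergence on a common outlier scale. The non-NA
ZF_ST vector has median 0 by construction (to floating round-off).

Window GC content is the G+C fraction over non-N bases. Correlations
between window statistics (Spearman by default, Pearson optional) drop NA
pairs pairwise.

## Branch statistics

Under neutral divergence without gene flow, F_ST relates to the scaled
split time T by F_ST = 1 − e^(−T), so each window yields
T = −ln(1 − F_ST); F_ST = 1 gives an infinite branch and is set NA with a
warning, and slightly negative F_ST maps to a small negative T (retained so
branch sums stay exact). Given two in-group populations and an outgroup,
the population branch statistic PBS₁ = (T₁₂ + T₁₀ − T₂₀)/2 measures the
allele-frequency divergence private to population 1; the two in-group
branches reconstruct the pairwise distance, pbs₁ + pbs₂ = T₁₂, asserted on
every window.

## Islands of divergence

IoDs are called by a threshold/merge/length rule: flag windows with
ZF_ST ≥ 2 (the threshold is inclusive and configurable), merge flagged
windows whose edge-to-edge gap is ≤ 60 kb into blocks, keep blocks strictly
longer than 100 kb, and optionally merge retained IoDs within 1 Mb of each
other (bridging short ZF_ST dips inside one divergent region; applied per
comparison, typically where gene flow is plausible). Island length is the
interval span including bridged gaps. The caller is equivalent to an
interval-union computation and is cross-checked in tests against a
brute-force oracle on random flag patterns; it is idempotent and monotone
(raising the threshold never increases island bp, widening the merge gap
never decreases it).

Inside/outside contrasts classify a window as "IoD" if it overlaps an
island by ≥ 1 bp, compare medians and means of any window statistic between
classes with a two-sided Wilcoxon rank-sum test, and report the percent
change of the mean.

Distance profiles average a statistic in 20-kb steps out to ±5 Mb from each
island center (midpoint rounded down to the window grid). Windows may serve
several nearby islands (simple pooled mean, matching a per-center stepping
procedure); chromosome ends simply truncate the profile. Distances are
signed by default with a pooled-absolute option. Raw bin means are
reported; smoothing (e.g. LOESS) is left to plotting. The crossing distance
is the smallest absolute distance at which the pooled profile returns to
the genome-wide mean.

## Region-overlap permutation tests

The association between two region sets (e.g. called islands vs centromeric
repeat arrays) is tested by randomizing the location of each region
uniformly along its own chromosome while preserving its size — per
chromosome, never across — and comparing the observed overlap with the null
distribution over `n_perm` (default 1,000) permutations. Randomized regions
may mutually overlap (the conventional default; a rejection-sampling
no-overlap mode exists). The statistic is the count of query regions
intersecting the reference by ≥ 1 bp, or total intersected bp. Reported:
one-sided empirical p = (#{null ≥ obs} + 1)/(n_perm + 1) (never 0),
Z-score (obs − null mean)/null SD, and fold enrichment obs/null mean (fold
< 1 flags depletion trends even when one-sided p is large). Calibration is
verified in tests: under independently placed sets the p-values are
Uniform(0,1] by a KS test over 500 replicate datasets. The bp statistic is
used there because the count statistic is lattice-valued at small region
numbers, which makes the empirical p conservative for reasons unrelated to
correctness.

## Divergence-time estimation

The model: two populations of equal effective size N_e split t generations
ago and diverge by drift alone. For haplodiploids an autosome has 3N_e
copies, hence T = t/(3N_e) and t = 3·N_e·mean(T), with T computed per
window from F_ST outside the called islands (barrier regions violate the
free-drift assumption). Windows with NA F_ST or F_ST ≥ 1 are excluded with
counts. N_e comes from Watterson's estimator θ_w = K/(a_n·L) — K
segregating sites, a_n = Σ_{i=1}^{n−1} 1/i, L accessible bases (default:
total assembly length, which reproduces published per-base θ values) — via
3N_e = θ_w/µ. When the two species' N_e estimates differ, the default
policy is their arithmetic mean (per-species and fixed-value options
exist); the model itself assumes a single shared N_e. Confidence intervals
are percentile bootstrap over windows (default 5,000 replicates), scaled by
the same 3N_e. With one generation per year, generations read as years.

Because −ln(1−F) is convex, the window-mean T is never below the T of the
mean F_ST (Jensen's inequality; asserted on every run) — estimates from
window means therefore exceed what a headline mean F_ST would give, and
per-window noise in F_ST inflates mean T by ½·Var(F)/(1−F)². The
calibration experiment (below) sizes window SNP counts so this bias is
negligible against the CI width.

## Synthetic-data generator

The generator emulates the two mechanisms that shape real divergence
landscapes, as window classes on top of a two-population split t
generations ago:

* **barrier** windows — no post-split homogenization (local effective split
  time t_eff = t) and linked-selection-reduced diversity (λ < 1),
  mimicking low-recombination, often pericentromeric, barrier loci under
  hybridization;
* **background** windows — gene flow homogenizes divergence, modeled as an
  effective-time reduction t_eff = t(1−g), λ = 1;
* **lowrec_background** windows — λ < 1 but the same gene flow as
  background: the allopatric linked-selection regime (high relative, low
  absolute divergence).

Drift is approximated by Balding–Nichols beta sampling: daughter
frequencies are drawn around the ancestral frequency with fixation index
F_exp = 1 − e^(−t_eff/(3·N_e·λ)); drawing both daughters at F_exp gives an
expected pairwise Hudson F_ST of F_exp. Ancestral polymorphic sites are
placed at density θ_anc·λ per base with frequencies from a discretized
neutral SFS (grid k/200, weights ∝ 1/k; the exact shape is not critical to
any tested property). Post-split mutations are injected as fixed
differences at rate Poisson(2µ·t_eff·L) per window, making
E[d_XY] ≈ π_anc·λ + 2µ·t_eff analytic. Genotypes are Hardy–Weinberg:
diploids Binomial(2, p), haploids Bernoulli(p) — a haploid can never be
heterozygous. Outputs are a plain-text VCF (round-trip-tested against the
reader), a truth BED/TSV of window classes and expected fixation indices, a
sample table and a params JSON; everything is deterministic given the seed.

What the generator does *not* emulate: linkage disequilibrium and
recombination maps (sites are independent), segregating post-split variants
(all injected divergence is fixed, biasing π slightly low and making F_ST
at divergent sites saturate), selection acting site-by-site, mutation-model
detail (all sites are A→T biallelic), and sequencing/genotyping error.
Passing tests therefore demonstrate the correctness and calibration of the
estimators and the pipeline logic under the generative model, not the
demographic realism of any particular parameter set.

### Preset conditions

| preset | layout | t | N_e | g | λ | θ_anc | µ |
|---|---|---|---|---|---|---|---|
| sympatric | 5 × 10 Mb, one 300-kb barrier block per chromosome | 2000 | 1000 | 0.5 | 0.25 | 0.002 | 3e-7 |
| allopatric | same blocks as lowrec_background | 400 | 1000 | 0 | 0.25 | 0.002 | 3e-7 |
| driftonly | 1 × 40 Mb, all background | 1246.5 (F_exp ≈ 0.34) | 1000 | 0 | 1 | 0.02 | 0 |

Sampling layout is study-like at desk scale: 20 haploids + 5 diploids per
population (30 chromosomes). Design notes on the choices that were
genuinely open:

* µ = 3e-7 satisfies the sympatric elevation condition
  2µtg > π_anc(1−λ) (fixed-difference divergence must outrun the
  λ-reduction of ancestral diversity inside barriers) with about a two-fold
  margin, while keeping drift the dominant term in background F_ST. A side
  effect of all-fixed injection is that absolute F_ST levels run higher
  than in the real system; the directional contrasts the pipeline must
  detect are unaffected.
* The drift-only preset omits mutation injection (µ = 0) because the
  F_ST→T estimator models drift without new mutation; injected fixed
  differences would bias it upward by construction. Its site density
  θ_anc = 0.02 (≈400 SNPs per 20-kb window) matches the SNP density of
  dense real resequencing data and keeps the O(1/S) ratio bias of window
  F_ST an order of magnitude inside the bootstrap CI half-width (a pilot at
  ≈100 SNPs/window showed the bias erodes CI coverage).
* t = 1246.5 in the drift-only preset is the closed-form
  −3N_e·ln(1 − 0.34), i.e. the split time whose expected fixation index is
  0.34.

## Problem sizes and runtimes

The test suite runs the full pipeline on 2,500-window genomes (5 × 10 Mb)
and the split-time calibration on 100 replicates of 2,000 windows with
5,000 bootstrap replicates each; the permutation calibration uses 500
replicate datasets × 200 permutations. These sizes give Monte-Carlo error
comfortably below the tested tolerances while the whole suite completes in
a few minutes on one CPU.

## Known limitations

* Only biallelic SNPs and hard genotype calls are supported; no genotype
  likelihoods, phasing or indels.
* Hudson's is the only F_ST estimator; comparisons against
  Weir & Cockerham require external tooling.
* The divergence-time model ignores migration after the split, population
  growth, and new mutation; its N_e ambiguity (two species, one model
  parameter) is handled by policy, not inference.
* The permutation null randomizes regions independently per chromosome;
  circular-rotation and covariate-matched nulls are not implemented.
* The generator's independence across sites means island *lengths* carry no
  LD signal; only their placement and amplitude are informative in tests.
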