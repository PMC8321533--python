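"""Synthetic mixed-ploidy SNP datasets with window-structured divergence.

The generator emulates two (optionally three) populations that split t
generations ago, with per-window regimes mimicking the two mechanisms that
shape real divergence landscapes:

* ``barrier`` windows resist post-split gene flow (local effective split
  time stays t) and carry reduced diversity (linked-selection factor λ < 1 in
  low-recombination, often pericentromeric, regions) — the islands-of-
  divergence regime under hybridization;
* ``background`` windows are partially homogenized by gene flow, modeled as
  an effective-time reduction t_eff = t(1−g);
* ``lowrec_background`` windows keep λ < 1 but experience the same gene flow
  as background — the allopatric linked-selection regime, where relative
  divergence is high but absolute divergence is *low*.

Drift is approximated by Balding–Nichols beta sampling: each population's
allele frequency is drawn around the ancestral frequency with fixation index
F_exp(window) = 1 − exp(−t_eff/(3·N_e·λ)) (haplodiploid 3N_e scaling).
Ancestral polymorphic sites are placed at density θ_anc·λ per base with
frequencies from a discretized neutral SFS (weights ∝ 1/k). Post-split new
mutations are injected as fixed differences at rate Poisson(2·µ·t_eff·L) per
window, so E[d_XY] ≈ π_anc·λ + 2·µ·t_eff: barrier windows show elevated and
lowrec windows reduced absolute divergence. Sampling is Hardy–Weinberg:
diploids Binomial(2, p), haploids Bernoulli(p).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .samples import SampleTable
from .variants import FilterReport, SiteCountsTable
from .windows import make_windows

__all__ = [
    "SimParams", "SimFreqs", "simulate_frequencies", "sample_allele_counts",
    "sample_genotypes", "write_outputs", "sympatric_params",
    "allopatric_params", "driftonly_params", "block_classes",
]

CLASSES = ("barrier", "background", "lowrec_background")


@dataclass
class SimParams:
    """Generative parameters of the two/three-population window model.

    ``samples`` maps population → (n_haploid, n_diploid) individuals.
    ``window_classes`` is aligned with ``make_windows(chrom_lengths,
    window_width)`` row order. ``branch_scale`` multiplies a population's
    private drift time (for asymmetric-branch experiments); ``outgroup``
    adds a third population split ``t_outgroup`` generations ago.
    """

    chrom_lengths: Dict[str, int]
    t: float
    ne: float
    mu: float
    theta_anc: float
    window_width: int = 20_000
    window_classes: Optional[Sequence[str]] = None
    gene_flow: float = 0.0          # g: homogenization of non-barrier windows
    linked_selection: float = 1.0   # λ: diversity factor in barrier/lowrec
    samples: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {"pop1": (20, 5), "pop2": (20, 5)})
    branch_scale: Optional[Dict[str, float]] = None
    outgroup: Optional[str] = None
    t_outgroup: Optional[float] = None
    sfs_grid_n: int = 100
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0.0 <= self.gene_flow < 1.0):
            raise ValueError("gene_flow must be in [0, 1)")
        if not (0.0 < self.linked_selection <= 1.0):
            raise ValueError("linked_selection must be in (0, 1]")
        if min(self.t, self.ne, self.mu, self.theta_anc) < 0:
            raise ValueError("rates and times must be >= 0")
        if self.outgroup is not None:
            if self.t_outgroup is None or self.t_outgroup < self.t:
                raise ValueError("outgroup needs t_outgroup >= t")
            if self.outgroup not in self.samples:
                raise ValueError("outgroup population missing from samples")

    @property
    def pops(self) -> List[str]:
        return list(self.samples)

    @property
    def ingroup(self) -> List[str]:
        return [p for p in self.samples if p != self.outgroup]

    def windows(self) -> pd.DataFrame:
        return make_windows(self.chrom_lengths, self.window_width)

    def classes(self) -> np.ndarray:
        w = self.windows()
        if self.window_classes is None:
            cls = np.full(len(w), "background", dtype=object)
        else:
            cls = np.asarray(list(self.window_classes), dtype=object)
            if len(cls) != len(w):
                raise ValueError("window_classes length must match the grid")
            bad = set(cls) - set(CLASSES)
            if bad:
                raise ValueError(f"invalid window class labels: {sorted(bad)}")
        return cls

    def to_json(self, path) -> None:
        d = dict(self.__dict__)
        d["window_classes"] = (list(self.window_classes)
                               if self.window_classes is not None else None)
        d["samples"] = {k: list(v) for k, v in self.samples.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


@dataclass
class SimFreqs:
    """Per-site population allele frequencies plus the generative truth."""

    chroms: np.ndarray            # per site
    pos: np.ndarray               # 1-based
    win_row: np.ndarray           # row in `windows`
    freqs: np.ndarray             # (n_sites, n_pops)
    pops: List[str]
    windows: pd.DataFrame
    truth: pd.DataFrame           # per window: class, lam, t_eff, F_exp

    def __len__(self):
        return len(self.pos)


def block_classes(n_windows: int, blocks: Sequence[Tuple[int, int]],
                  label: str = "barrier") -> List[str]:
    """Per-window class labels: ``label`` on [start, start+len) window blocks,
    ``background`` elsewhere. ``blocks`` are (first_window, n_windows) pairs."""
    cls = ["background"] * n_windows
    for first, n in blocks:
        for k in range(first, first + n):
            cls[k] = label
    return cls


def _sfs_grid(grid_n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Discretized neutral SFS: frequencies k/(2N) for k=1..2N−1, weight∝1/k."""
    k = np.arange(1, 2 * grid_n)
    w = 1.0 / k
    return k / (2.0 * grid_n), w / w.sum()


def _unique_positions(rng: np.random.Generator, width: int, s: int
                      ) -> np.ndarray:
    return np.sort(rng.choice(width, size=s, replace=False, shuffle=False))


def simulate_frequencies(params: SimParams,
                         rng: Optional[np.random.Generator] = None
                         ) -> SimFreqs:
    """Draw per-site population allele frequencies under the window model.

    Returns sorted sites (ancestral polymorphisms and injected fixed
    differences interleaved by position) and a per-window truth table with
    the class, λ, effective split time and expected fixation index
    F_exp = 1 − exp(−t_eff/(3·N_e·λ)).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    windows = params.windows()
    cls = params.classes()
    nw = len(windows)
    width_w = (windows["end"] - windows["start"]).to_numpy()

    lam_w = np.where(np.isin(cls, ("barrier", "lowrec_background")),
                     params.linked_selection, 1.0)
    t_eff_w = np.where(cls == "barrier", params.t,
                       params.t * (1.0 - params.gene_flow))
    pops = params.pops
    scale = params.branch_scale or {}
    grid_p, grid_w = _sfs_grid(params.sfs_grid_n)

    # pairwise expected fixation index of the in-group pair (truth bookkeeping)
    with np.errstate(divide="ignore"):
        F_exp_w = 1.0 - np.exp(-t_eff_w / (3.0 * params.ne * lam_w))
    truth = windows.copy()
    truth["class"] = cls
    truth["lam"] = lam_w
    truth["t_eff"] = t_eff_w
    truth["F_exp"] = F_exp_w

    # per-population, per-window fixation index: both daughters drawn with
    # F = F_exp gives an expected pairwise Hudson F_ST of (F1+F2)/2 = F_exp
    def pop_F(pop: str) -> np.ndarray:
        if pop == params.outgroup:
            tt = np.full(nw, float(params.t_outgroup))
        else:
            tt = t_eff_w * float(scale.get(pop, 1.0))
        return 1.0 - np.exp(-tt / (3.0 * params.ne * lam_w))

    F_pop = np.stack([pop_F(p) for p in pops], axis=1)  # (nw, npop)

    # --- ancestral polymorphic sites ------------------------------------
    s_anc = rng.poisson(params.theta_anc * lam_w * width_w)
    win_anc = np.repeat(np.arange(nw), s_anc)
    n_anc = int(s_anc.sum())
    p_anc = grid_p[rng.choice(len(grid_p), size=n_anc, p=grid_w)]
    freqs_anc = np.empty((n_anc, len(pops)))
    for j in range(len(pops)):
        F = F_pop[win_anc, j]
        drift = F > 0
        out = np.array(p_anc, copy=True)
        if drift.any():
            a = p_anc[drift] * (1.0 - F[drift]) / F[drift]
            b = (1.0 - p_anc[drift]) * (1.0 - F[drift]) / F[drift]
            out[drift] = rng.beta(a, b)
        freqs_anc[:, j] = out

    # --- post-split fixed differences -----------------------------------
    ingroup_idx = [pops.index(p) for p in params.ingroup]
    m_pair = rng.poisson(2.0 * params.mu * t_eff_w * width_w)
    win_new = np.repeat(np.arange(nw), m_pair)
    n_new = int(m_pair.sum())
    freqs_new = np.zeros((n_new, len(pops)))
    which = rng.integers(0, 2, size=n_new)
    for k, j in enumerate(ingroup_idx[:2]):
        freqs_new[which == k, j] = 1.0
    if params.outgroup is not None:
        m_out = rng.poisson(2.0 * params.mu * float(params.t_outgroup)
                            * width_w)
        win_out = np.repeat(np.arange(nw), m_out)
        f_out = np.zeros((int(m_out.sum()), len(pops)))
        f_out[:, pops.index(params.outgroup)] = 1.0
        win_new = np.concatenate([win_new, win_out])
        freqs_new = np.vstack([freqs_new, f_out])
        n_new = len(win_new)

    # --- merge, draw distinct positions per window, sort ----------------
    win_all = np.concatenate([win_anc, win_new])
    freqs_all = np.vstack([freqs_anc, freqs_new])
    order = np.argsort(win_all, kind="stable")
    win_all = win_all[order]
    freqs_all = freqs_all[order]

    pos = np.empty(len(win_all), dtype=np.int64)
    starts_w = windows["start"].to_numpy()
    chrom_w = windows["chrom"].to_numpy()
    counts = np.bincount(win_all, minlength=nw)
    off = 0
    for w in np.nonzero(counts)[0]:
        c = counts[w]
        pos[off:off + c] = (starts_w[w]
                            + _unique_positions(rng, int(width_w[w]), int(c))
                            + 1)
        off += c
    return SimFreqs(chroms=chrom_w[win_all].astype(object), pos=pos,
                    win_row=win_all, freqs=freqs_all, pops=list(pops),
                    windows=windows, truth=truth)


def _layout_table(samples: Dict[str, Tuple[int, int]]) -> SampleTable:
    recs = []
    for pop, (n_hap, n_dip) in samples.items():
        recs += [(f"{pop}_h{i}", pop, 1) for i in range(n_hap)]
        recs += [(f"{pop}_d{i}", pop, 2) for i in range(n_dip)]
    return SampleTable.from_records(recs)


def sample_allele_counts(sim: SimFreqs, params: SimParams,
                         rng: np.random.Generator) -> SiteCountsTable:
    """Binomially sample per-population allele counts (no genotype matrix).

    Equivalent under Hardy–Weinberg to summing individual genotypes; the fast
    path for estimator calibration experiments.
    """
    npop = len(sim.pops)
    n_chrom = np.array([params.samples[p][0] + 2 * params.samples[p][1]
                        for p in sim.pops])
    alt = np.empty((len(sim), npop), dtype=np.int64)
    for j in range(npop):
        alt[:, j] = rng.binomial(n_chrom[j], sim.freqs[:, j])
    called = np.broadcast_to(n_chrom, (len(sim), npop)).copy()
    return SiteCountsTable(
        chroms=sim.chroms, pos=sim.pos,
        ref=np.full(len(sim), "A", dtype=object),
        alt_allele=np.full(len(sim), "T", dtype=object),
        pops=list(sim.pops), alt=alt, called=called,
        report=FilterReport(n_records=len(sim), n_kept=len(sim)))


def sample_genotypes(sim: SimFreqs, params: SimParams,
                     rng: np.random.Generator
                     ) -> Tuple[SampleTable, np.ndarray]:
    """Draw a per-sample genotype (alt-dosage) matrix under Hardy–Weinberg.

    Diploids: Binomial(2, p); haploids: Bernoulli(p) — a haploid sample can
    never be heterozygous. Returns the sample table and an
    ``(n_sites, n_samples)`` int8 dosage matrix.
    """
    table = _layout_table(params.samples)
    geno = np.empty((len(sim), len(table.samples)), dtype=np.int8)
    for k, (s, pop, ploidy) in enumerate(
            zip(table.samples, table.populations, table.ploidies)):
        p = sim.freqs[:, sim.pops.index(pop)]
        geno[:, k] = rng.binomial(ploidy, p)
    return table, geno


def write_outputs(outdir, sim: SimFreqs, table: SampleTable,
                  genotypes: np.ndarray, params: SimParams
                  ) -> Dict[str, str]:
    """Write VCF + truth BED/TSV + sample TSV + params JSON into ``outdir``.

    The VCF contains every simulated site (including sites monomorphic in
    the realized sample, as legal all-reference records) so that a round-trip
    through the VCF reader reproduces the sampled allele counts exactly.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "sim.vcf"),
        "truth_windows": os.path.join(outdir, "truth_windows.tsv"),
        "truth_bed": os.path.join(outdir, "truth_barrier.bed"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "chrom_lengths": os.path.join(outdir, "chrom_lengths.tsv"),
        "params": os.path.join(outdir, "params.json"),
    }
    ploidies = table.ploidies
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divscan-simulate\n")
        for c, L in params.chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        hap_gt = ("0", "1")
        dip_gt = ("0/0", "0/1", "1/1")
        for i in range(len(sim)):
            gts = [hap_gt[genotypes[i, k]] if ploidies[k] == 1
                   else dip_gt[genotypes[i, k]]
                   for k in range(len(ploidies))]
            fh.write(f"{sim.chroms[i]}\t{sim.pos[i]}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    sim.truth.to_csv(paths["truth_windows"], sep="\t", index=False)
    barrier = sim.truth[sim.truth["class"] == "barrier"]
    barrier[["chrom", "start", "end"]].to_csv(
        paths["truth_bed"], sep="\t", header=False, index=False)
    table.to_tsv(paths["samples"])
    pd.DataFrame(list(params.chrom_lengths.items())).to_csv(
        paths["chrom_lengths"], sep="\t", header=False, index=False)
    params.to_json(paths["params"])
    return paths


# ---------------------------------------------------------------------------
# preset study conditions
# ---------------------------------------------------------------------------

def _five_chrom_layout() -> Tuple[Dict[str, int], List[Tuple[int, int]], int]:
    """5 × 10-Mb chromosomes (2,500 20-kb windows) with one 300-kb divergent
    block per chromosome at a chromosome-specific offset."""
    chrom_lengths = {f"chr{i}": 10_000_000 for i in range(1, 6)}
    per_chrom = 500
    offsets = [100, 220, 340, 150, 400]
    blocks = [(i * per_chrom + off, 15) for i, off in enumerate(offsets)]
    return chrom_lengths, blocks, 5 * per_chrom


def sympatric_params(seed: Optional[int] = None) -> SimParams:
    """Hybridizing-species regime: barrier windows block gene flow (t_eff = t,
    λ = 0.25) while the background is homogenized (g = 0.5). Islands show
    *elevated* absolute divergence."""
    chrom_lengths, blocks, nw = _five_chrom_layout()
    return SimParams(
        chrom_lengths=chrom_lengths, t=2000.0, ne=1000.0, mu=3e-7,
        theta_anc=0.002, gene_flow=0.5, linked_selection=0.25,
        window_classes=block_classes(nw, blocks, "barrier"), seed=seed)


def allopatric_params(seed: Optional[int] = None) -> SimParams:
    """Isolated-species regime: no gene flow anywhere; low-recombination
    blocks (λ = 0.25) drift faster and are called as islands, but their
    absolute divergence is *reduced* (linked selection in the ancestor)."""
    chrom_lengths, blocks, nw = _five_chrom_layout()
    return SimParams(
        chrom_lengths=chrom_lengths, t=400.0, ne=1000.0, mu=3e-7,
        theta_anc=0.002, gene_flow=0.0, linked_selection=0.25,
        window_classes=block_classes(nw, blocks, "lowrec_background"),
        seed=seed)


def driftonly_params(seed: Optional[int] = None, n_windows: int = 2000,
                     fst: float = 0.34) -> SimParams:
    """Pure-drift calibration regime for the split-time estimator: one
    40-Mb chromosome of homogeneous background windows, no gene flow, no
    linked selection, no post-split mutation (µ = 0), N_e = 1,000 and t set
    so the expected fixation index is ``fst``. θ_anc = 0.02 matches the SNP
    density of dense real resequencing data (≈400 SNPs per 20-kb window) and
    keeps the O(1/S) ratio bias of window F_ST well inside the bootstrap
    CI."""
    t = -3.0 * 1000.0 * float(np.log1p(-fst))
    return SimParams(
        chrom_lengths={"chr1": n_windows * 20_000}, t=t, ne=1000.0, mu=0.0,
        theta_anc=0.02, gene_flow=0.0, linked_selection=1.0, seed=seed)
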