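"""Windowed diversity and divergence statistics.

Per-site estimators (all functions are numpy-vectorized):

* nucleotide diversity  π = 2a(n−a) / (n(n−1))  — the fraction of differing
  pairs among the n sampled chromosomes, unbiased for heterozygosity;
* absolute divergence   d_XY = p1(1−p2) + p2(1−p1) — the probability that one
  chromosome from each population differs;
* Hudson's F_ST as (numerator, denominator) components,
  num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1),  den = d_XY,
  combined per window as a ratio of averages (Σnum/Σden), which is robust to
  low per-site sample sizes.

Window aggregation uses nonoverlapping tiles (default 20 kb). π and d_XY are
divided by the accessible window span (the input VCF holds variant sites only,
so non-variant bases count as monomorphic); F_ST needs no denominator. Window
F_ST landscapes are standardized to ZF_ST = (F_ST − median)/SD so comparisons
with different overall divergence share an outlier threshold.
"""
from __future__ import annotations

import itertools
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .variants import SiteCountsTable

__all__ = [
    "site_pi", "site_dxy", "site_fst_components", "make_windows",
    "window_stats", "zfst", "gc_content", "correlate", "pair_label",
]


# ---------------------------------------------------------------------------
# per-site estimators
# ---------------------------------------------------------------------------

def site_pi(alt_count, called_count):
    """Per-site nucleotide diversity 2a(n−a)/(n(n−1)); NaN where n < 2."""
    a = np.asarray(alt_count, dtype=float)
    n = np.asarray(called_count, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 2.0 * a * (n - a) / (n * (n - 1.0))
    return np.where(n >= 2, out, np.nan)


def site_dxy(p1, p2):
    """Per-site absolute divergence p1(1−p2) + p2(1−p1)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return p1 * (1.0 - p2) + p2 * (1.0 - p1)


def site_fst_components(a1, n1, a2, n2) -> Tuple[np.ndarray, np.ndarray]:
    """Hudson-estimator per-site (numerator, denominator).

    Both are NaN where either population has fewer than 2 called chromosomes;
    sites where the denominator is 0 (both populations monomorphic for the
    same allele) must be excluded by the caller when forming ratios.
    """
    a1 = np.asarray(a1, dtype=float); n1 = np.asarray(n1, dtype=float)
    a2 = np.asarray(a2, dtype=float); n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = a1 / n1
        p2 = a2 / n2
        num = ((p1 - p2) ** 2
               - p1 * (1.0 - p1) / (n1 - 1.0)
               - p2 * (1.0 - p2) / (n2 - 1.0))
    den = site_dxy(p1, p2)
    ok = (n1 >= 2) & (n2 >= 2)
    return np.where(ok, num, np.nan), np.where(ok, den, np.nan)


# ---------------------------------------------------------------------------
# window grid
# ---------------------------------------------------------------------------

def make_windows(chrom_lengths: Dict[str, int], width: int = 20_000
                 ) -> pd.DataFrame:
    """Tile each chromosome with nonoverlapping windows of ``width`` bp.

    The last window of a chromosome is truncated at the chromosome end.
    Coordinates are 0-based half-open.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, int(length), width):
            rows.append((chrom, start, min(start + width, int(length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def pair_label(p1: str, p2: str) -> str:
    return f"{p1}_{p2}"


def _assign_windows(sites: SiteCountsTable, windows: pd.DataFrame) -> np.ndarray:
    """Window row index for each site (−1 if outside every window)."""
    idx = np.full(len(sites), -1, dtype=np.int64)
    pos0 = sites.pos - 1
    for chrom, grp in windows.groupby("chrom", sort=False):
        m = sites.chroms == chrom
        if not m.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        rows = grp.index.to_numpy()[order]
        j = np.searchsorted(starts, pos0[m], side="right") - 1
        ok = (j >= 0) & (pos0[m] < ends[np.maximum(j, 0)])
        vals = np.where(ok, rows[np.maximum(j, 0)], -1)
        idx[m] = vals
    return idx


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------

def window_stats(
    sites: SiteCountsTable,
    windows: pd.DataFrame,
    pops: Optional[Sequence[str]] = None,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    *,
    denominator: str = "span",
    min_snps: int = 10,
    masked_bp: Optional[np.ndarray] = None,
    add_zfst: bool = True,
) -> pd.DataFrame:
    """Aggregate per-site estimators into a per-window statistics table.

    Parameters
    ----------
    denominator:
        ``"span"`` (default): per-base π/d_XY divide by window span minus
        ``masked_bp`` — appropriate for SNP-only VCFs where absent sites are
        monomorphic. ``"sites"``: divide by the number of usable SNPs (then π
        and d_XY are per-variant-site averages).
    min_snps:
        Windows with fewer usable SNPs report NA for every statistic and are
        excluded from the ZF_ST median/SD.

    Returns the window table with columns ``n_snps``, ``pi_<pop>``,
    ``dxy_<p1>_<p2>``, ``fst_<p1>_<p2>`` and (``add_zfst``) ``zfst_<p1>_<p2>``.
    """
    if denominator not in ("span", "sites"):
        raise ValueError("denominator must be 'span' or 'sites'")
    pops = list(pops) if pops is not None else list(sites.pops)
    if pairs is None:
        pairs = list(itertools.combinations(pops, 2))
    windows = windows.reset_index(drop=True)
    nw = len(windows)
    widx = _assign_windows(sites, windows)
    inside = widx >= 0
    w = widx[inside]

    span = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    if masked_bp is not None:
        span = span - np.asarray(masked_bp, dtype=float)
        if np.any(span <= 0):
            raise ValueError("window fully masked: span - masked_bp <= 0")

    out = windows.copy()
    n_snps = np.bincount(w, minlength=nw).astype(int)
    out["n_snps"] = n_snps
    usable = n_snps >= min_snps

    def _wsum(values: np.ndarray) -> np.ndarray:
        v = values[inside]
        ok = np.isfinite(v)
        return np.bincount(w[ok], weights=v[ok], minlength=nw)

    def _wcount(values: np.ndarray) -> np.ndarray:
        v = values[inside]
        return np.bincount(w[np.isfinite(v)], minlength=nw).astype(float)

    for p in pops:
        i = sites.pop_index(p)
        pi = site_pi(sites.alt[:, i], sites.called[:, i])
        denom = span if denominator == "span" else np.maximum(_wcount(pi), 1.0)
        col = _wsum(pi) / denom
        out[f"pi_{p}"] = np.where(usable, col, np.nan)

    for p1, p2 in pairs:
        i, j = sites.pop_index(p1), sites.pop_index(p2)
        n1 = sites.called[:, i].astype(float)
        n2 = sites.called[:, j].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            f1 = sites.alt[:, i] / n1
            f2 = sites.alt[:, j] / n2
        dxy = site_dxy(f1, f2)
        denom = span if denominator == "span" else np.maximum(_wcount(dxy), 1.0)
        lab = pair_label(p1, p2)
        out[f"dxy_{lab}"] = np.where(usable, _wsum(dxy) / denom, np.nan)

        num, den = site_fst_components(
            sites.alt[:, i], sites.called[:, i],
            sites.alt[:, j], sites.called[:, j])
        # a site enters the ratio only when both components are defined and
        # the denominator is nonzero somewhere in the window
        ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
        num = np.where(ok, num, np.nan)
        den = np.where(ok, den, np.nan)
        snum, sden = _wsum(num), _wsum(den)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = snum / sden
        fst = np.where(usable & (sden > 0), fst, np.nan)
        out[f"fst_{lab}"] = fst
        if add_zfst:
            try:
                out[f"zfst_{lab}"] = zfst(fst)
            except ValueError:
                # degenerate landscape (too few windows or zero variance):
                # leave the standardized column undefined
                out[f"zfst_{lab}"] = np.nan
    return out


def zfst(fst: np.ndarray) -> np.ndarray:
    """Standardize window F_ST: (F_ST − median)/SD over non-NA windows.

    The sample standard deviation (ddof=1) of all non-NA window values is
    used; NA windows stay NA. Raises on fewer than 2 non-NA windows or a
    degenerate (zero-variance) landscape.
    """
    fst = np.asarray(fst, dtype=float)
    ok = np.isfinite(fst)
    if ok.sum() < 2:
        raise ValueError("ZF_ST needs at least 2 non-NA window F_ST values")
    med = np.median(fst[ok])
    sd = np.std(fst[ok], ddof=1)
    if sd == 0:
        raise ValueError("degenerate landscape: SD of window F_ST is 0")
    out = np.full_like(fst, np.nan)
    out[ok] = (fst[ok] - med) / sd
    return out


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def gc_content(fasta_path, windows: pd.DataFrame) -> np.ndarray:
    """Fraction G+C over non-N bases per window; NaN where all bases are N."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    out = np.full(len(windows), np.nan)
    for k, (chrom, start, end) in enumerate(
            windows[["chrom", "start", "end"]].itertuples(index=False)):
        if chrom not in fa:
            raise KeyError(f"chromosome {chrom!r} absent from FASTA")
        seq = str(fa[chrom][int(start):int(end)]).upper()
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        if gc + at > 0:
            out[k] = gc / (gc + at)
    return out


def correlate(x, y, method: str = "spearman") -> Tuple[float, float]:
    """Correlation between two window statistics with pairwise NA dropping.

    Returns ``(coefficient, p_value)``; NaN with a warning for constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired non-NA observations")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: correlation undefined")
        return float("nan"), float("nan")
    if method == "spearman":
        r, p = _sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = _sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
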