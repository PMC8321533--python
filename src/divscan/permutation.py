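"""Permutation tests for overlap between genomic region sets.

The null model randomizes the location of each region uniformly along its own
chromosome while preserving its size (randomized regions may mutually
overlap). Significance of the observed overlap against ``n_perm`` randomized
placements is the one-sided empirical p-value

    p = (#{null >= observed} + 1) / (n_perm + 1),

never exactly zero; the Z-score (observed − null mean)/null SD measures the
strength of the association, and observed/null-mean gives fold enrichment.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .regions import RegionSet

__all__ = ["PermutationResult", "randomize_regions", "overlap_stat",
           "perm_test"]


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a region-overlap permutation test."""

    observed: float
    null_mean: float
    null_sd: float
    z_score: float
    p_empirical: float
    fold_enrichment: float
    n_perm: int
    mode: str
    randomized: str
    seed: Optional[int] = None

    def to_dict(self) -> Dict[str, object]:
        return dict(self.__dict__)


def _require_lengths(rs: RegionSet) -> Dict[str, int]:
    if rs.chrom_lengths is None:
        raise ValueError("randomization requires chromosome lengths")
    return rs.chrom_lengths


def _max_starts(rs: RegionSet) -> np.ndarray:
    lengths = _require_lengths(rs)
    L = np.asarray([lengths[c] for c in rs.chroms], dtype=np.int64)
    max_start = L - rs.lengths
    if np.any(max_start < 0):
        raise ValueError("region longer than its chromosome")
    return max_start


def randomize_regions(regions: RegionSet, rng: np.random.Generator,
                      no_overlap: bool = False,
                      max_tries: int = 1000) -> RegionSet:
    """Place each region uniformly on its own chromosome, sizes preserved.

    ``start ~ Uniform{0 .. L − len}`` independently per region; randomized
    regions may overlap one another unless ``no_overlap`` (rejection sampling
    per chromosome, raises after ``max_tries`` failures).
    """
    max_start = _max_starts(regions)
    if not no_overlap:
        starts = rng.integers(0, max_start + 1)
        return RegionSet(regions.chroms, starts, starts + regions.lengths,
                         regions.chrom_lengths)
    starts = np.empty(len(regions), dtype=np.int64)
    for c in set(regions.chroms.tolist()):
        m = regions.chroms == c
        sizes = regions.lengths[m]
        hi = max_start[m]
        for _ in range(max_tries):
            s = rng.integers(0, hi + 1)
            e = s + sizes
            order = np.argsort(s)
            if np.all(s[order][1:] >= e[order][:-1]):
                starts[m] = s
                break
        else:
            raise RuntimeError(f"no non-overlapping placement found on {c!r}")
    return RegionSet(regions.chroms, starts, starts + regions.lengths,
                     regions.chrom_lengths)


def _overlap_arrays(q_starts: np.ndarray, q_ends: np.ndarray,
                    ref: Tuple[np.ndarray, np.ndarray, np.ndarray],
                    mode: str) -> float:
    """Overlap of query intervals against one chromosome's merged reference.

    ``ref`` is (starts, ends, cumulative coverage) of sorted non-overlapping
    intervals. Count mode: number of query intervals intersecting >= 1
    reference interval. bp mode: summed intersection bp per query interval
    (overlapping queries each count their own intersection).
    """
    rs, re, cum = ref
    if len(rs) == 0 or len(q_starts) == 0:
        return 0.0
    if mode == "n_query_overlapping":
        idx = np.searchsorted(rs, q_ends, side="left")
        hit = (idx > 0) & (re[np.maximum(idx - 1, 0)] > q_starts)
        return float(hit.sum())
    # coverage function C(x) = covered bp of the reference union in [0, x)
    def C(x):
        i = np.searchsorted(rs, x, side="right") - 1
        i0 = np.maximum(i, 0)
        partial = np.clip(x - rs[i0], 0, re[i0] - rs[i0])
        return np.where(i >= 0, cum[i0] + partial, 0)
    return float(np.sum(C(q_ends) - C(q_starts)))


def overlap_stat(query: RegionSet, reference: RegionSet,
                 mode: str = "n_query_overlapping") -> float:
    """Overlap statistic between two region sets.

    ``n_query_overlapping`` (default): count of query regions intersecting at
    least one reference region by >= 1 bp. ``bp_overlap``: total intersected
    basepairs. Invariant to interval order in either set.
    """
    if mode not in ("n_query_overlapping", "bp_overlap"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    ref = reference.merge()._by_chrom()
    total = 0.0
    for c in set(query.chroms.tolist()):
        if c not in ref:
            continue
        m = query.chroms == c
        total += _overlap_arrays(query.starts[m], query.ends[m], ref[c], mode)
    return total


def perm_test(a: RegionSet, b: RegionSet, n_perm: int = 1000,
              mode: str = "n_query_overlapping", randomize: str = "A",
              seed: Optional[int] = None,
              rng: Optional[np.random.Generator] = None) -> PermutationResult:
    """Permutation test of the overlap of region set ``a`` with ``b``.

    ``randomize="A"`` randomizes only the query set (``b`` fixed);
    ``"both"`` randomizes both sets each permutation, as when neither set's
    position is privileged. One-sided (enrichment) p; fold enrichments below
    1 indicate observed overlap under the null mean.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if randomize not in ("A", "both"):
        raise ValueError("randomize must be 'A' or 'both'")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = overlap_stat(a, b, mode)

    # fast path: pre-group chromosomes, draw starts vectorized per permutation
    a_max = _max_starts(a)
    a_chrom_masks = {c: a.chroms == c for c in set(a.chroms.tolist())}
    if randomize == "A":
        b_ref = b.merge()._by_chrom()
    else:
        b_max = _max_starts(b)

    null = np.empty(n_perm)
    for k in range(n_perm):
        a_starts = rng.integers(0, a_max + 1)
        if randomize == "both":
            b_starts = rng.integers(0, b_max + 1)
            b_rand = RegionSet(b.chroms, b_starts, b_starts + b.lengths,
                               b.chrom_lengths)
            b_ref = b_rand.merge()._by_chrom()
        tot = 0.0
        for c, m in a_chrom_masks.items():
            if c not in b_ref:
                continue
            tot += _overlap_arrays(a_starts[m], a_starts[m] + a.lengths[m],
                                   b_ref[c], mode)
        null[k] = tot

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    p = (float(np.sum(null >= observed)) + 1.0) / (n_perm + 1.0)
    fold = observed / null_mean if null_mean > 0 else float("nan")
    return PermutationResult(observed, null_mean, null_sd, z, p, fold,
                             n_perm, mode, randomize, seed)
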