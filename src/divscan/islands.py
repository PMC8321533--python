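"""Island-of-divergence (IoD) detection from standardized window F_ST.

An IoD is a contiguous block of extreme relative divergence. The caller
follows a threshold/merge/length rule: flag windows with ZF_ST at or above a
threshold (default 2 SD above the median), merge flagged windows whose
edge-to-edge gap is at most ``merge_gap`` (default 60 kb) into blocks, keep
blocks strictly longer than ``min_length`` (default 100 kb), and optionally
merge retained islands within ``second_merge_gap`` (default off; 1 Mb where
used) to bridge short dips in ZF_ST inside one divergent region. Block length
is the interval span including bridged gaps.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .regions import RegionSet

__all__ = ["IslandCallParams", "call_divergent_windows", "merge_and_filter",
           "compare_inside_outside", "island_summary"]


@dataclass(frozen=True)
class IslandCallParams:
    """Threshold/merge/length parameters of the IoD caller (bp units)."""

    z_threshold: float = 2.0
    merge_gap: int = 60_000
    min_length: int = 100_000
    second_merge_gap: Optional[int] = None

    def __post_init__(self):
        if self.z_threshold < 0 or self.merge_gap < 0 or self.min_length < 0:
            raise ValueError("island-call parameters must be >= 0")
        if self.second_merge_gap is not None and self.second_merge_gap < 0:
            raise ValueError("second_merge_gap must be >= 0")


def call_divergent_windows(df: pd.DataFrame, z_col: str,
                           z_threshold: float = 2.0) -> np.ndarray:
    """Boolean flag per window: ZF_ST at or above the threshold.

    The threshold is inclusive (a window exactly at 2 SD is flagged);
    NA windows are never flagged.
    """
    z = df[z_col].to_numpy(dtype=float)
    return np.isfinite(z) & (z >= z_threshold)


def merge_and_filter(df: pd.DataFrame, flags: np.ndarray,
                     params: IslandCallParams,
                     chrom_lengths: Optional[Dict[str, int]] = None
                     ) -> RegionSet:
    """Merge flagged windows into islands and apply the length filter.

    ``df`` must carry sorted, per-chromosome ``chrom``/``start``/``end``
    window coordinates. Windows whose gap (start of next minus end of
    previous block) is at most ``merge_gap`` join one block; blocks strictly
    longer than ``min_length`` are islands; islands within
    ``second_merge_gap`` of each other (if configured) are merged, bridging
    the gap into one interval. Merging never crosses chromosomes.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(df):
        raise ValueError("flags length must match window table")
    sub = df.loc[flags, ["chrom", "start", "end"]]
    for _, grp in sub.groupby("chrom", sort=False):
        if not grp["start"].is_monotonic_increasing:
            raise ValueError("windows must be sorted by start per chromosome")
    if len(sub) == 0:
        return RegionSet([], [], [], chrom_lengths)
    blocks = RegionSet(sub["chrom"], sub["start"], sub["end"],
                       chrom_lengths).merge(gap=params.merge_gap)
    islands = blocks.filter_length(params.min_length, strict=True)
    if params.second_merge_gap is not None and len(islands) > 0:
        islands = islands.merge(gap=params.second_merge_gap)
    return islands


def compare_inside_outside(df: pd.DataFrame, islands: RegionSet,
                           stat_cols: Sequence[str]) -> pd.DataFrame:
    """Contrast window statistics inside vs outside islands.

    Windows overlapping an island by at least 1 bp are "IoD", the rest
    "background". For each statistic the result row holds counts, medians and
    means per class, the percent change of the mean inside relative to
    outside, and a two-sided Wilcoxon rank-sum p-value. Degenerate classes
    (no windows, or all windows on one side) yield NA.
    """
    inside = islands.overlaps(df["chrom"], df["start"], df["end"]) \
        if len(islands) else np.zeros(len(df), dtype=bool)
    rows = []
    for col in stat_cols:
        v = df[col].to_numpy(dtype=float)
        vin = v[inside & np.isfinite(v)]
        vout = v[~inside & np.isfinite(v)]
        if len(vin) == 0 or len(vout) == 0:
            rows.append((col, len(vin), len(vout), np.nan, np.nan, np.nan,
                         np.nan, np.nan, np.nan))
            continue
        mean_in, mean_out = vin.mean(), vout.mean()
        pct = 100.0 * (mean_in - mean_out) / mean_out if mean_out != 0 else np.nan
        p = _sps.mannwhitneyu(vin, vout, alternative="two-sided").pvalue
        rows.append((col, len(vin), len(vout), float(np.median(vin)),
                     float(np.median(vout)), mean_in, mean_out, pct, float(p)))
    return pd.DataFrame(rows, columns=[
        "statistic", "n_in", "n_out", "median_in", "median_out",
        "mean_in", "mean_out", "pct_change", "p_ranksum"])


def island_summary(islands: RegionSet,
                   genome_bp: Optional[int] = None) -> pd.DataFrame:
    """One-row summary: count, mean length, total bp, percent of genome."""
    n = len(islands)
    total = int(islands.lengths.sum())
    if genome_bp is None and islands.chrom_lengths is not None:
        genome_bp = sum(islands.chrom_lengths.values())
    return pd.DataFrame([{
        "n_islands": n,
        "mean_length": total / n if n else np.nan,
        "total_bp": total,
        "pct_genome": 100.0 * total / genome_bp if genome_bp else np.nan,
    }])
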