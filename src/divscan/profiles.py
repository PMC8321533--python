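"""Average window statistics as a function of distance from island centers.

For each island of divergence, the window at its center (midpoint rounded
down to the window grid) anchors distance 0, and the windows at center ±
k·step (default 20-kb steps out to 5 Mb) contribute to the bin at signed
distance k·step. Bins are averaged over all islands; windows falling off a
chromosome end are simply absent (the bin's n reflects clipping). A window
may serve several nearby islands' profiles (simple pooled mean).
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .regions import RegionSet

__all__ = ["profile", "crossing_distance"]


def profile(windows: pd.DataFrame, islands: RegionSet, stat_col: str,
            max_dist: int = 5_000_000, step: int = 20_000,
            signed: bool = True) -> pd.DataFrame:
    """Distance profile of ``stat_col`` around island centers.

    ``windows`` must tile chromosomes with nonoverlapping width-``step``
    windows (the grid the statistics were computed on). Returns a table with
    ``distance_bp`` (signed, −max_dist..max_dist, or absolute if
    ``signed=False``), ``mean_stat``, ``n`` (windows contributing) and the
    genome-wide mean of the statistic as a reference column.

    Raises on an empty island set.
    """
    if len(islands) == 0:
        raise ValueError("profile requires a non-empty island set")
    k_max = int(max_dist) // int(step)
    nbins = 2 * k_max + 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)

    vals_by_chrom = {}
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        first = int(grp["start"].iloc[0])
        widths = (grp["end"] - grp["start"]).to_numpy()
        if first != 0 or np.any(np.diff(grp["start"].to_numpy()) != step) \
                or np.any(widths[:-1] != step):
            raise ValueError("windows must tile each chromosome in "
                             f"uniform {step}-bp steps")
        vals_by_chrom[chrom] = grp[stat_col].to_numpy(dtype=float)

    for chrom, start, end in zip(islands.chroms, islands.starts, islands.ends):
        if chrom not in vals_by_chrom:
            continue
        vals = vals_by_chrom[chrom]
        center = int((start + end) // 2) // step  # window-grid index
        lo = max(center - k_max, 0)
        hi = min(center + k_max, len(vals) - 1)
        segment = vals[lo:hi + 1]
        bins = np.arange(lo - center + k_max, hi - center + k_max + 1)
        ok = np.isfinite(segment)
        np.add.at(sums, bins[ok], segment[ok])
        np.add.at(counts, bins[ok], 1)

    dist = (np.arange(nbins) - k_max) * step
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    all_vals = np.concatenate(list(vals_by_chrom.values()))
    genome_mean = float(np.nanmean(all_vals))
    out = pd.DataFrame({"distance_bp": dist, "mean_stat": means, "n": counts,
                        "genome_mean": genome_mean})
    if not signed:
        out["distance_bp"] = np.abs(out["distance_bp"])
        out = (out.groupby("distance_bp", as_index=False)
                  .apply(_pool_bins, include_groups=False)
                  .reset_index(drop=True))
        out["genome_mean"] = genome_mean
    return out


def _pool_bins(g: pd.DataFrame) -> pd.Series:
    n = g["n"].sum()
    mean = np.nansum(g["mean_stat"] * g["n"]) / n if n > 0 else np.nan
    return pd.Series({"mean_stat": mean, "n": n})


def crossing_distance(profile_df: pd.DataFrame, genome_mean: Optional[float]
                      = None, direction: str = "above") -> float:
    """Distance at which the profile first returns to the genome-wide mean.

    ``direction="above"``: the profile starts above the mean near the center;
    report the smallest absolute distance whose bin mean is at or below the
    mean (``"below"`` is the mirror case). Bins without data are skipped.
    NaN if the profile never crosses.
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    if genome_mean is None:
        genome_mean = float(profile_df["genome_mean"].iloc[0])
    df = profile_df.copy()
    df["absdist"] = df["distance_bp"].abs()
    pooled = (df[df["n"] > 0]
              .groupby("absdist")
              .apply(lambda g: np.average(g["mean_stat"], weights=g["n"]),
                     include_groups=False)
              .sort_index())
    for d, v in pooled.items():
        crossed = v <= genome_mean if direction == "above" else v >= genome_mean
        if crossed:
            return float(d)
    return float("nan")
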