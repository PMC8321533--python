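"""Genomic interval sets with chromosome-length context.

All coordinates are 0-based half-open, BED-style. A :class:`RegionSet` is the
exchange format between the island caller, the permutation tests, the
divergence-time estimator (which excludes islands) and the distance profiles.
Interval arithmetic is implemented on numpy arrays because the permutation
machinery evaluates overlap statistics ~10^5 times per test.
"""
from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["RegionSet", "read_chrom_lengths"]


class RegionSet:
    """An immutable set of genomic intervals (chrom, start, end).

    Parameters
    ----------
    chroms, starts, ends:
        Parallel arrays. Coordinates are 0-based half-open.
    chrom_lengths:
        Optional ``{chrom: length}`` map. Required for randomization and for
        percent-of-genome summaries; intervals must fit their chromosome.
    """

    def __init__(
        self,
        chroms: Iterable[str],
        starts: Iterable[int],
        ends: Iterable[int],
        chrom_lengths: Optional[Mapping[str, int]] = None,
    ):
        self.chroms = np.asarray(list(chroms), dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms, starts, ends must have equal length")
        if np.any(self.starts < 0):
            raise ValueError("negative interval start")
        if np.any(self.ends <= self.starts):
            raise ValueError("intervals must have end > start")
        self.chrom_lengths: Optional[Dict[str, int]] = (
            dict(chrom_lengths) if chrom_lengths is not None else None
        )
        if self.chrom_lengths is not None:
            for c, e in zip(self.chroms, self.ends):
                if c not in self.chrom_lengths:
                    raise ValueError(f"interval on unknown chromosome {c!r}")
                if e > self.chrom_lengths[c]:
                    raise ValueError(
                        f"interval end {e} exceeds length of chromosome {c!r}"
                    )

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.starts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegionSet(n={len(self)}, bp={self.total_bp})"

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_bp(self) -> int:
        """Total covered basepairs (union; overlaps counted once)."""
        return int(self.merge().lengths.sum())

    def sort(self) -> "RegionSet":
        order = np.lexsort((self.starts, _as_str(self.chroms)))
        return RegionSet(
            self.chroms[order], self.starts[order], self.ends[order],
            self.chrom_lengths,
        )

    # -- set operations ----------------------------------------------------
    def merge(self, gap: int = 0) -> "RegionSet":
        """Union intervals, joining any pair closer than ``gap`` bp.

        Two intervals are joined when ``next.start - prev.end <= gap``
        (edge-to-edge distance); ``gap=0`` unions overlapping or book-ended
        intervals. Never joins across chromosomes.
        """
        if len(self) == 0:
            return RegionSet([], [], [], self.chrom_lengths)
        s = self.sort()
        out_c, out_s, out_e = [], [], []
        cur_c, cur_s, cur_e = s.chroms[0], s.starts[0], s.ends[0]
        for c, st, en in zip(s.chroms[1:], s.starts[1:], s.ends[1:]):
            if c == cur_c and st - cur_e <= gap:
                cur_e = max(cur_e, en)
            else:
                out_c.append(cur_c); out_s.append(cur_s); out_e.append(cur_e)
                cur_c, cur_s, cur_e = c, st, en
        out_c.append(cur_c); out_s.append(cur_s); out_e.append(cur_e)
        return RegionSet(out_c, out_s, out_e, self.chrom_lengths)

    def filter_length(self, min_length: int, strict: bool = True) -> "RegionSet":
        """Keep intervals longer than (``strict``) or at least ``min_length``."""
        keep = self.lengths > min_length if strict else self.lengths >= min_length
        return RegionSet(
            self.chroms[keep], self.starts[keep], self.ends[keep],
            self.chrom_lengths,
        )

    def overlaps(self, chroms, starts, ends) -> np.ndarray:
        """Boolean array: does each query interval intersect this set (≥1 bp)?"""
        merged = self.merge()
        by_chrom = merged._by_chrom()
        chroms = np.asarray(list(chroms), dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(starts), dtype=bool)
        for c, (rs, re, _cum) in by_chrom.items():
            m = chroms == c
            if not m.any():
                continue
            idx = np.searchsorted(rs, ends[m], side="left")
            hit = (idx > 0) & (re[np.maximum(idx - 1, 0)] > starts[m])
            out[m] = hit
        return out

    def _by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, cumulative-coverage) of sorted merged
        intervals. Callers must pass a merged set; cached per instance."""
        cached = getattr(self, "_by_chrom_cache", None)
        if cached is not None:
            return cached
        d: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for c in pd.unique(self.chroms):
            m = self.chroms == c
            s, e = self.starts[m], self.ends[m]
            order = np.argsort(s)
            s, e = s[order], e[order]
            cum = np.concatenate([[0], np.cumsum(e - s)])
            d[str(c)] = (s, e, cum)
        self._by_chrom_cache = d
        return d

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_bed(cls, path, chrom_lengths: Optional[Mapping[str, int]] = None
                 ) -> "RegionSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={0: str})
        return cls(df["chrom"], df["start"], df["end"], chrom_lengths)

    def to_bed(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       chrom_lengths: Optional[Mapping[str, int]] = None
                       ) -> "RegionSet":
        return cls(df["chrom"], df["start"], df["end"], chrom_lengths)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        )


def _as_str(arr: np.ndarray) -> np.ndarray:
    return np.asarray([str(x) for x in arr])


def read_chrom_lengths(path) -> Dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))
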