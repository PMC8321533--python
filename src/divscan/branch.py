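"""Branch statistics: F_ST → divergence-time units, and the PBS.

Under neutral divergence of two populations from a common ancestor,
F_ST relates to the scaled split time T by F_ST = 1 − e^(−T), so
T = −ln(1 − F_ST). Given three populations (two in-group, one outgroup) the
population branch statistic

    PBS_1 = (T_12 + T_10 − T_20) / 2

is the length of the branch private to population 1, i.e. its
allele-frequency divergence since the common ancestor with population 2.
"""
from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .windows import pair_label

__all__ = ["fst_to_T", "pbs", "add_branch_stats"]


def fst_to_T(fst):
    """T = −ln(1 − F_ST); NaN (with warning) at F_ST ≥ 1.

    Slightly negative window F_ST maps to a small negative T and is retained
    so that PBS sums stay exact.
    """
    fst = np.asarray(fst, dtype=float)
    at_one = np.isfinite(fst) & (fst >= 1.0)
    if np.any(at_one):
        warnings.warn(f"{int(at_one.sum())} window(s) with F_ST >= 1: "
                      "infinite branch, set to NA")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.log1p(-fst)
    return np.where(at_one, np.nan, out)


def pbs(t_12, t_10, t_20):
    """Branch length of the focal population: (T_12 + T_10 − T_20)/2.

    ``t_12`` is the in-group distance, ``t_10`` focal-vs-outgroup and
    ``t_20`` the other in-group population vs outgroup. Any NaN input yields
    NaN. Swapping the in-group roles swaps ``t_10``/``t_20``.
    """
    t_12 = np.asarray(t_12, dtype=float)
    t_10 = np.asarray(t_10, dtype=float)
    t_20 = np.asarray(t_20, dtype=float)
    return (t_12 + t_10 - t_20) / 2.0


def add_branch_stats(df: pd.DataFrame, pop1: str, pop2: str, outgroup: str,
                     prefix: str = "fst") -> pd.DataFrame:
    """Append T and PBS columns for an (in-group pair, outgroup) trio.

    Expects pairwise F_ST columns named ``{prefix}_{a}_{b}`` for the three
    pairs (either orientation). Adds ``T_<pair>`` for each pair and
    ``pbs_<pop>`` for both in-group populations; pbs_1 + pbs_2 equals T_12
    wherever all terms are defined.
    """
    def _col(a: str, b: str) -> str:
        for lab in (pair_label(a, b), pair_label(b, a)):
            if f"{prefix}_{lab}" in df.columns:
                return f"{prefix}_{lab}"
        raise KeyError(f"no {prefix} column for pair ({a}, {b})")

    out = df.copy()
    c12, c10, c20 = _col(pop1, pop2), _col(pop1, outgroup), _col(pop2, outgroup)
    t12 = fst_to_T(out[c12].to_numpy())
    t10 = fst_to_T(out[c10].to_numpy())
    t20 = fst_to_T(out[c20].to_numpy())
    out[f"T_{pair_label(pop1, pop2)}"] = t12
    out[f"T_{pair_label(pop1, outgroup)}"] = t10
    out[f"T_{pair_label(pop2, outgroup)}"] = t20
    out[f"pbs_{pop1}"] = pbs(t12, t10, t20)
    out[f"pbs_{pop2}"] = pbs(t12, t20, t10)
    return out
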