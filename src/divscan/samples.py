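"""Sample metadata: population assignment and per-sample ploidy.

Haplodiploid datasets mix haploid males and diploid females, so the number of
sampled chromosomes per population is the sum of ploidies, not twice the
number of individuals.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import pandas as pd

__all__ = ["SampleTable", "load_sample_table"]


@dataclass(frozen=True)
class SampleTable:
    """Sample → population and sample → ploidy assignments.

    Invariants: sample ids unique, every population non-empty, ploidy in {1, 2}.
    """

    samples: Tuple[str, ...]
    populations: Tuple[str, ...]
    ploidies: Tuple[int, ...]

    def __post_init__(self):
        if not (len(self.samples) == len(self.populations) == len(self.ploidies)):
            raise ValueError("parallel fields must have equal length")
        if len(set(self.samples)) != len(self.samples):
            dupes = {s for s in self.samples if list(self.samples).count(s) > 1}
            raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
        for s, p, k in zip(self.samples, self.populations, self.ploidies):
            if k not in (1, 2):
                raise ValueError(f"sample {s!r}: ploidy must be 1 or 2, got {k}")
            if not p:
                raise ValueError(f"sample {s!r}: empty population label")
        if len(self.samples) == 0:
            raise ValueError("sample table is empty")

    @property
    def pop_names(self) -> List[str]:
        seen: Dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def samples_of(self, pop: str) -> List[str]:
        return [s for s, p in zip(self.samples, self.populations) if p == pop]

    def ploidy_of(self, sample: str) -> int:
        return self.ploidies[self.samples.index(sample)]

    def n_chromosomes(self, pop: str) -> int:
        """Sampled chromosomes in ``pop`` = Σ ploidy over its samples."""
        return sum(k for p, k in zip(self.populations, self.ploidies) if p == pop)

    @classmethod
    def from_records(cls, records) -> "SampleTable":
        s, p, k = zip(*records)
        return cls(tuple(s), tuple(p), tuple(int(x) for x in k))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": self.samples, "population": self.populations,
             "ploidy": self.ploidies}
        ).to_csv(path, sep="\t", index=False)


def load_sample_table(path) -> SampleTable:
    """Read a TSV with header columns ``sample``, ``population``, ``ploidy``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    missing = {"sample", "population", "ploidy"} - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    return SampleTable(
        tuple(df["sample"]),
        tuple(df["population"].fillna("")),
        tuple(int(x) for x in df["ploidy"]),
    )
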