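"""Read multi-sample VCFs into per-site, per-population allele counts.

Mixed ploidy is honored: a ploidy-1 sample contributes one chromosome whether
its genotype is written haploid-style (``0``, ``1``) or as a homozygous
diploid call (``0/0``, ``1/1``); a heterozygous call in a ploidy-1 sample is a
genotyping artifact (typically collapsed paralogs) and causes the whole site
to be dropped. Only biallelic SNPs passing the VCF FILTER column are retained;
every skip reason is counted in a :class:`FilterReport`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .samples import SampleTable

__all__ = ["SiteCounts", "SiteCountsTable", "FilterReport", "read_sites",
           "read_sites_table"]


@dataclass(frozen=True)
class SiteCounts:
    """Per-population alternate-allele and called-chromosome counts at one SNP.

    ``pos`` is the 1-based VCF coordinate. For each population,
    ``0 <= alt <= called <= Σ ploidy`` and the reference count is
    ``called - alt``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_counts: Dict[str, int]
    called_counts: Dict[str, int]

    def freq(self, pop: str) -> float:
        n = self.called_counts[pop]
        return self.alt_counts[pop] / n if n > 0 else float("nan")


@dataclass
class FilterReport:
    """Counters for every record-level filter applied while reading."""

    n_records: int = 0
    n_kept: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0
    n_filter_failed: int = 0
    n_haploid_het: int = 0
    n_unparseable: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_records - self.n_kept

    def consistent(self) -> bool:
        """Dropped records are fully accounted for by the per-filter counters."""
        return self.n_dropped == (
            self.n_multiallelic + self.n_non_snp + self.n_filter_failed
            + self.n_haploid_het + self.n_unparseable
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [(f.name, getattr(self, f.name)) for f in fields(self)],
            columns=["filter", "count"],
        ).to_csv(path, sep="\t", index=False)


_BASES = {"A", "C", "G", "T"}


def _genotype_alleles(entry) -> List[int]:
    """cyvcf2 genotype entry → list of allele indices (−1 = missing).

    cyvcf2 encodes a genotype as ``[allele, ..., phased_flag]``; haploid calls
    carry one allele, diploid calls two.
    """
    return [int(a) for a in entry[:-1]]


def read_sites(
    vcf_path,
    samples: SampleTable,
    *,
    drop_haploid_hets: bool = True,
    report: Optional[FilterReport] = None,
) -> Iterator[SiteCounts]:
    """Stream retained biallelic SNPs as :class:`SiteCounts`.

    Multiallelic records, non-SNPs, FILTER-failed records and (by default)
    sites with a heterozygous call in any haploid sample are skipped with
    counters logged in ``report``. Missing alleles reduce the population's
    called count.

    Raises
    ------
    ValueError
        If a sample in ``samples`` is absent from the VCF header.
    """
    vcf = VCF(str(vcf_path))
    header_samples = list(vcf.samples)
    absent = [s for s in samples.samples if s not in header_samples]
    if absent:
        raise ValueError(f"samples not in VCF header: {absent}")
    col = {s: header_samples.index(s) for s in samples.samples}
    pops = samples.pop_names
    pop_members: List[Tuple[str, List[Tuple[int, int]]]] = [
        (p, [(col[s], samples.ploidy_of(s)) for s in samples.samples_of(p)])
        for p in pops
    ]

    for v in vcf:
        if report is not None:
            report.n_records += 1
        if v.FILTER is not None:  # None ⇔ PASS or '.'
            if report is not None:
                report.n_filter_failed += 1
            continue
        if len(v.ALT) != 1:
            if report is not None:
                report.n_multiallelic += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or \
                v.REF.upper() not in _BASES or v.ALT[0].upper() not in _BASES:
            if report is not None:
                report.n_non_snp += 1
            continue

        genos = v.genotypes
        alt_counts: Dict[str, int] = {}
        called_counts: Dict[str, int] = {}
        haploid_het = False
        bad = False
        for pop, members in pop_members:
            alt = called = 0
            for idx, ploidy in members:
                try:
                    alleles = _genotype_alleles(genos[idx])
                except (TypeError, IndexError):
                    bad = True
                    break
                present = [a for a in alleles if a >= 0]
                if any(a > 1 for a in present):
                    bad = True
                    break
                if ploidy == 1:
                    if len(present) == 2 and present[0] != present[1]:
                        haploid_het = True
                        if drop_haploid_hets:
                            break
                        continue  # filter off: treat the call as missing
                    # haploid-style or homozygous-diploid call: 1 chromosome
                    if present:
                        called += 1
                        alt += int(present[0] == 1)
                else:
                    called += len(present)
                    alt += sum(present)
            if (haploid_het and drop_haploid_hets) or bad:
                break
            alt_counts[pop] = alt
            called_counts[pop] = called
        if bad:
            if report is not None:
                report.n_unparseable += 1
            continue
        if haploid_het and drop_haploid_hets:
            if report is not None:
                report.n_haploid_het += 1
            continue
        if report is not None:
            report.n_kept += 1
        yield SiteCounts(v.CHROM, v.POS, v.REF.upper(), v.ALT[0].upper(),
                         alt_counts, called_counts)


@dataclass
class SiteCountsTable:
    """Columnar per-site counts: the input of all windowed estimators.

    ``alt`` and ``called`` are ``(n_sites, n_pops)`` integer arrays aligned
    with ``pops``; ``pos`` is 1-based.
    """

    chroms: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt_allele: np.ndarray
    pops: List[str]
    alt: np.ndarray
    called: np.ndarray
    report: FilterReport = field(default_factory=FilterReport)

    def __len__(self) -> int:
        return len(self.pos)

    def pop_index(self, pop: str) -> int:
        return self.pops.index(pop)

    @classmethod
    def from_sites(cls, sites: Iterator[SiteCounts], pops: List[str],
                   report: Optional[FilterReport] = None) -> "SiteCountsTable":
        chroms, pos, ref, alt_a, alts, calleds = [], [], [], [], [], []
        for s in sites:
            chroms.append(s.chrom)
            pos.append(s.pos)
            ref.append(s.ref)
            alt_a.append(s.alt)
            alts.append([s.alt_counts[p] for p in pops])
            calleds.append([s.called_counts[p] for p in pops])
        n = len(pos)
        return cls(
            np.asarray(chroms, dtype=object),
            np.asarray(pos, dtype=np.int64),
            np.asarray(ref, dtype=object),
            np.asarray(alt_a, dtype=object),
            list(pops),
            np.asarray(alts, dtype=np.int64).reshape(n, len(pops)),
            np.asarray(calleds, dtype=np.int64).reshape(n, len(pops)),
            report or FilterReport(),
        )


def read_sites_table(vcf_path, samples: SampleTable, *,
                     drop_haploid_hets: bool = True) -> SiteCountsTable:
    """Materialize :func:`read_sites` into a :class:`SiteCountsTable`."""
    report = FilterReport()
    it = read_sites(vcf_path, samples, drop_haploid_hets=drop_haploid_hets,
                    report=report)
    return SiteCountsTable.from_sites(it, samples.pop_names, report)
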