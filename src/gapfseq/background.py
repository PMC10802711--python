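"""Library QC over control inverted repeats, and blocklist curation.

Quality control exploits known germline inverted repeats: a well-enriched
palindrome library amplifies them (high unfiltered coverage, the
*amplification score*) while the MAPQ uniqueness filter removes their
multi-mapping reads (low filtered coverage, the *depletion score*).

Blocklist curation removes 1-kb bins recurrently enriched in *both* tumor
and normal libraries — GC-rich or repetitive regions that survive the
single-strand nuclease for technical rather than biological reasons — so
that high-coverage-bin ranking reflects tumor-specific palindromes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import BinCoverage, BinSet


@dataclass(frozen=True)
class ControlRegion:
    chrom: str
    start: int
    end: int
    label: str


def read_control_regions(path) -> list[ControlRegion]:
    """Read control inverted-repeat regions from a 4-column BED file."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "label"], usecols=range(4),
    )
    regions = [
        ControlRegion(str(r.chrom), int(r.start), int(r.end), str(r.label))
        for r in df.itertuples()
    ]
    if not regions:
        raise ValueError(f"no control regions read from {path}")
    return regions


def _region_mean_cpm(cov: BinCoverage, region: ControlRegion) -> float:
    """Mean cpm over the bins overlapping one control region."""
    bins = cov.bins
    if not bins.has_chrom(region.chrom):
        raise ValueError(f"control region {region.label}: chromosome {region.chrom} not in BinSet")
    w = bins.bin_width
    first = region.start // w
    last = min((region.end - 1) // w, bins.n_bins_chrom(region.chrom) - 1)
    if last < first:
        raise ValueError(f"control region {region.label} overlaps no bin")
    off = bins.offset(region.chrom)
    wanted = np.arange(off + first, off + last + 1)
    mask = np.isin(cov.bin_indices, wanted)
    if not mask.any():
        raise ValueError(f"control region {region.label} overlaps no retained bin")
    return float(cov.cpm[mask].mean())


def amplification_score(unfiltered: BinCoverage, regions: list[ControlRegion]) -> float:
    """Mean over control regions of each region's mean unfiltered cpm.

    ``unfiltered`` should be coverage computed with ``mapq_min=0`` so that
    multi-mapping reads at the repeats are retained.
    """
    if not regions:
        raise ValueError("control region list is empty")
    return float(np.mean([_region_mean_cpm(unfiltered, r) for r in regions]))


def depletion_score(filtered: BinCoverage, regions: list[ControlRegion]) -> float:
    """Same two-level averaging on MAPQ-filtered coverage (``mapq_min=40``)."""
    if not regions:
        raise ValueError("control region list is empty")
    return float(np.mean([_region_mean_cpm(filtered, r) for r in regions]))


@dataclass(frozen=True)
class QCReport:
    """Pass/fail verdict from the two control-repeat scores.

    A library passes iff amplification_score > amp_min (enrichment worked)
    AND depletion_score < dep_max (the uniqueness filter removes the
    repeats). Both inequalities are strict.
    """

    amplification_score: float
    depletion_score: float
    amp_min: float = 1.0
    dep_max: float = 0.075
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "passed",
            bool(self.amplification_score > self.amp_min and self.depletion_score < self.dep_max),
        )


def qc_evaluate(
    amplification: float, depletion: float, amp_min: float = 1.0, dep_max: float = 0.075
) -> QCReport:
    if not (np.isfinite(amplification) and np.isfinite(depletion)):
        raise ValueError("QC scores must be finite")
    return QCReport(amplification, depletion, amp_min, dep_max)


@dataclass(frozen=True)
class BlockList:
    """Curated background bins, identified by (chrom, start)."""

    bins: frozenset
    provenance: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.bins)

    def sorted_bins(self, binset: BinSet) -> list[tuple[str, int]]:
        order = {name: i for i, name in enumerate(binset.chrom_names)}
        return sorted(self.bins, key=lambda b: (order.get(b[0], len(order)), b[1]))

    def mask(self, binset: BinSet) -> np.ndarray:
        """Boolean array over the BinSet: True where the bin is blocklisted."""
        m = np.zeros(binset.n_bins, dtype=bool)
        for chrom, start in self.bins:
            m[binset.bin_id(chrom, start)] = True
        return m

    def write_bed(self, path, binset: BinSet, sidecar: bool = True) -> None:
        rows = self.sorted_bins(binset)
        with open(path, "w") as fh:
            for chrom, start in rows:
                end = min(start + binset.bin_width, binset.chrom_length(chrom))
                fh.write(f"{chrom}\t{start}\t{end}\n")
        if sidecar:
            with open(str(path) + ".json", "w") as fh:
                json.dump(self.provenance, fh, indent=2, sort_keys=True)

    @classmethod
    def read_bed(cls, path) -> "BlockList":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"],
                         usecols=range(3), comment="#")
        return cls(frozenset(zip(df["chrom"].astype(str), df["start"].astype(int))),
                   {"source": str(path)})


def identify_background_bins(
    coverages: list[BinCoverage],
    labels: list[str],
    enrich_cutoff: float = 5.0,
    min_fraction: float = 0.75,
) -> BlockList:
    """Find bins recurrently enriched in both tumor and normal samples.

    A bin enters the blocklist iff its cpm exceeds ``enrich_cutoff`` in at
    least ``min_fraction`` of tumor samples AND at least ``min_fraction`` of
    normal samples. The 5-cpm default is the cohort's own low/high coverage
    divide; both parameters are recorded in the provenance.
    """
    if len(coverages) != len(labels):
        raise ValueError("one label per coverage required")
    tumors = [c for c, l in zip(coverages, labels) if l == "tumor"]
    normals = [c for c, l in zip(coverages, labels) if l == "normal"]
    if not tumors or not normals:
        raise ValueError("cohort must contain at least one tumor and one normal sample")
    binset = tumors[0].bins
    for c in coverages:
        if c.bins is not binset and c.bins != binset:
            raise ValueError("all coverages must share one BinSet")
        if c.n_bins != binset.n_bins:
            raise ValueError("blocklist identification requires full (unfiltered) coverage")

    def enriched_fraction(group: list[BinCoverage]) -> np.ndarray:
        hits = np.zeros(binset.n_bins, dtype=np.int64)
        for c in group:
            hits += (c.cpm > enrich_cutoff).astype(np.int64)
        return hits / len(group)

    both = (enriched_fraction(tumors) >= min_fraction) & (
        enriched_fraction(normals) >= min_fraction
    )
    idx = np.flatnonzero(both)
    chroms = binset.chrom_of_bins(idx)
    starts = binset.starts_of_bins(idx)
    return BlockList(
        frozenset(zip(chroms.tolist(), (int(s) for s in starts))),
        provenance={
            "enrich_cutoff_cpm": enrich_cutoff,
            "min_fraction": min_fraction,
            "n_tumor": len(tumors),
            "n_normal": len(normals),
            "n_bins_total": binset.n_bins,
            "n_bins_blocklisted": int(both.sum()),
        },
    )


def apply_blocklist(cov: BinCoverage, blocklist: BlockList) -> BinCoverage:
    """Restrict a coverage track to bins outside the blocklist.

    Idempotent: re-applying the same blocklist removes nothing further.
    Retained values are unchanged; retained bin count on full coverage is
    total bins minus blocklist size.
    """
    drop = set()
    for chrom, start in blocklist.bins:
        drop.add(cov.bins.bin_id(chrom, start))  # raises if bin absent from BinSet
    keep = ~np.isin(cov.bin_indices, np.fromiter(drop, dtype=np.int64, count=len(drop))) \
        if drop else np.ones(cov.n_bins, dtype=bool)
    return BinCoverage(
        sample_id=cov.sample_id,
        mapq_min=cov.mapq_min,
        raw=cov.raw[keep],
        cpm=cov.cpm[keep],
        total_mapped_reads=cov.total_mapped_reads,
        bins=cov.bins,
        bin_indices=cov.bin_indices[keep],
    )
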