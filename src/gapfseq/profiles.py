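"""High-coverage-bin (HCB) ranking and chromosomal/cytoband profiles.

After blocklist curation, the retained bins of a MAPQ-filtered coverage
track are sorted by cpm in descending order and the top K (default 1000)
are the sample's HCBs. The per-chromosome distribution of those HCBs —
the GAPF profile — is the decision statistic downstream: tumors cluster
HCBs on one or a few chromosomes while normals disperse them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CANONICAL_CHROMS, BinCoverage


@dataclass(frozen=True)
class HCBSet:
    """The K highest-cpm retained bins of one sample, cpm-descending."""

    k: int
    chrom: np.ndarray
    start: np.ndarray
    cpm: np.ndarray
    sample_id: str = ""

    def __len__(self) -> int:
        return len(self.start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start, "cpm": self.cpm})


def top_k_hcbs(cov: BinCoverage, k: int = 1000) -> HCBSet:
    """Select the K highest-cpm bins under a deterministic tie rule.

    Ties at equal cpm break toward the earlier chromosome in BinSet order,
    then the smaller start — the selection is bit-exact across runs.
    """
    if k <= 0:
        raise ValueError(f"K must be positive, got {k}")
    # lexsort: last key is primary
    order = np.lexsort((cov.bin_indices, -cov.cpm))
    take = order[: min(k, cov.n_bins)]
    idx = cov.bin_indices[take]
    return HCBSet(
        k=k,
        chrom=cov.bins.chrom_of_bins(idx),
        start=cov.bins.starts_of_bins(idx).astype(np.int64),
        cpm=cov.cpm[take],
        sample_id=cov.sample_id,
    )


@dataclass(frozen=True)
class HCBProfile:
    """Per-chromosome counts of one sample's top-K HCBs (sums to K)."""

    sample_id: str
    counts: pd.Series  # indexed by chromosome name, ordered
    k: int

    def score(self) -> int:
        """Maximum per-chromosome HCB count — the threshold-model statistic."""
        if len(self.counts) == 0:
            raise ValueError("empty profile")
        return int(self.counts.max())


def chromosome_profile(
    hcbs: HCBSet,
    chromosome_set: tuple[str, ...] = CANONICAL_CHROMS,
    on_excluded: str = "error",
) -> HCBProfile:
    """Tally HCBs per chromosome over an ordered chromosome set.

    HCBs on chromosomes outside the set either raise (``on_excluded='error'``)
    or are dropped with a warning (``'drop'``), in which case the profile sum
    falls short of ``len(hcbs)`` by the number dropped.
    """
    counts = pd.Series(0, index=pd.Index(chromosome_set, name="chrom"), dtype=np.int64)
    vals, n = np.unique(hcbs.chrom, return_counts=True)
    excluded = [v for v in vals if v not in counts.index]
    if excluded:
        if on_excluded == "error":
            raise ValueError(f"HCBs on chromosomes outside the profile set: {excluded}")
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d HCBs on excluded chromosomes %s",
            int(sum(c for v, c in zip(vals, n) if v in excluded)),
            excluded,
        )
    for v, c in zip(vals, n):
        if v in counts.index:
            counts[v] = int(c)
    return HCBProfile(sample_id=hcbs.sample_id, counts=counts, k=hcbs.k)


def profiles_to_frame(profiles: list[HCBProfile]) -> pd.DataFrame:
    """Samples x chromosomes table of HCB counts (one row per sample)."""
    df = pd.DataFrame({p.sample_id: p.counts for p in profiles}).T
    df.index.name = "sample_id"
    return df


def read_cytobands(path, chromosome_set: tuple[str, ...] = CANONICAL_CHROMS) -> pd.DataFrame:
    """Read a UCSC cytoBand.txt (5 columns, 0-based half-open).

    Bands on unlocalized/unplaced sequences (names containing '_') and on
    chromosomes outside ``chromosome_set`` are dropped.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "stain"], comment="#",
    )
    df = df[~df["chrom"].str.contains("_")]
    df = df[df["chrom"].isin(chromosome_set)].reset_index(drop=True)
    return df


def _check_non_overlapping(bands: pd.DataFrame) -> None:
    for chrom, grp in bands.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping cytobands on {chrom}")


def cytoband_counts(hcbs: HCBSet, bands: pd.DataFrame) -> pd.Series:
    """Count top-K HCBs per cytoband; assignment is by bin start.

    Returns a Series indexed by (chrom, band name). HCBs on chromosomes with
    no bands are ignored (they are outside the retained band universe).
    """
    _check_non_overlapping(bands)
    idx = pd.MultiIndex.from_frame(bands[["chrom", "name"]])
    counts = pd.Series(0, index=idx, dtype=np.int64)
    for chrom, grp in bands.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        sel = hcbs.chrom == chrom
        if not sel.any():
            continue
        pos = hcbs.start[sel]
        band_i = np.searchsorted(g["start"].to_numpy(), pos, side="right") - 1
        valid = (band_i >= 0) & (pos < g["end"].to_numpy()[np.clip(band_i, 0, None)])
        for bi, c in zip(*np.unique(band_i[valid], return_counts=True)):
            counts[(chrom, g["name"].iloc[int(bi)])] += int(c)
    return counts


def cytoband_coverage(cov: BinCoverage, bands: pd.DataFrame) -> pd.Series:
    """Length-normalized per-band coverage: (sum of bin cpm in band) / band bp."""
    _check_non_overlapping(bands)
    if (bands["end"] <= bands["start"]).any():
        raise ValueError("zero- or negative-length cytoband")
    chrom = cov.bins.chrom_of_bins(cov.bin_indices)
    start = cov.bins.starts_of_bins(cov.bin_indices)
    values = []
    for row in bands.itertuples():
        sel = (chrom == row.chrom) & (start >= row.start) & (start < row.end)
        values.append(float(cov.cpm[sel].sum()) / (row.end - row.start))
    return pd.Series(values, index=pd.MultiIndex.from_frame(bands[["chrom", "name"]]))


@dataclass(frozen=True)
class DecayFit:
    """Log-linear exponential fit y = a * exp(b * x)."""

    a: float
    b: float
    r_squared: float
    degenerate: bool = False


def fit_exponential_decay(x, y) -> DecayFit:
    """Fit an exponential trend to (dilution, peak coverage) points.

    Ordinary least squares of ln(y) on x; ``a = exp(intercept)``,
    ``b = slope``; R^2 is the squared correlation of the log-space fit.
    Two-point inputs fit exactly and are flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need >= 2 (x, y) points of equal length")
    if (y <= 0).any():
        raise ValueError("y must be strictly positive for a log-linear fit")
    res = stats.linregress(x, np.log(y))
    return DecayFit(
        a=float(np.exp(res.intercept)),
        b=float(res.slope),
        r_squared=float(res.rvalue**2),
        degenerate=len(x) == 2,
    )
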