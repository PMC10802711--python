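"""Genome binning and binned read-coverage computation.

The analysis unit throughout the package is the fixed-width genomic bin
(default 1 kb). Aligned reads are counted into bins with a mapping-quality
uniqueness filter and normalized to counts-per-million mapped reads (cpm),
so that coverage is comparable across libraries of different depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# SAM flag bits used to exclude non-primary records from counting
FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

CANONICAL_CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")


@dataclass(frozen=True)
class BinSet:
    """An ordered partition of a genome into fixed-width half-open bins.

    Bins are 0-based, tiled from position 0 on each chromosome; the last bin
    of a chromosome may be shorter than ``bin_width``. Global bin ordering is
    chromosome order as given, then start ascending.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_width: int
    _n_bins_per_chrom: np.ndarray = field(init=False, repr=False, compare=False)
    _offsets: np.ndarray = field(init=False, repr=False, compare=False)
    _chrom_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n_per = np.array(
            [-(-length // self.bin_width) for _, length in self.chromosomes],
            dtype=np.int64,
        )
        offsets = np.concatenate([[0], np.cumsum(n_per)])
        object.__setattr__(self, "_n_bins_per_chrom", n_per)
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(
            self, "_chrom_index", {name: i for i, (name, _) in enumerate(self.chromosomes)}
        )

    @property
    def n_bins(self) -> int:
        return int(self._offsets[-1])

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        return self.chromosomes[self._chrom_index[chrom]][1]

    def n_bins_chrom(self, chrom: str) -> int:
        return int(self._n_bins_per_chrom[self._chrom_index[chrom]])

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._chrom_index

    def offset(self, chrom: str) -> int:
        """Global index of the first bin of ``chrom``."""
        return int(self._offsets[self._chrom_index[chrom]])

    def bin_id(self, chrom: str, start: int) -> int:
        """Global index of the bin starting at ``start`` on ``chrom``.

        ``start`` must be an exact bin start within the chromosome.
        """
        ci = self._chrom_index.get(chrom)
        if ci is None:
            raise KeyError(f"chromosome {chrom!r} not in BinSet")
        if start < 0 or start % self.bin_width != 0 or start >= self.chromosomes[ci][1]:
            raise ValueError(f"{chrom}:{start} is not a bin start in this BinSet")
        return int(self._offsets[ci]) + start // self.bin_width

    def bin_location(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of the bin with global index ``index``."""
        ci = int(np.searchsorted(self._offsets, index, side="right")) - 1
        if ci < 0 or index >= self.n_bins:
            raise IndexError(index)
        name, length = self.chromosomes[ci]
        start = (index - int(self._offsets[ci])) * self.bin_width
        return name, start, min(start + self.bin_width, length)

    def iter_bins(self) -> Iterator[tuple[str, int, int, int]]:
        idx = 0
        for name, length in self.chromosomes:
            for start in range(0, length, self.bin_width):
                yield name, start, min(start + self.bin_width, length), idx
                idx += 1

    def to_frame(self) -> pd.DataFrame:
        chroms: list[str] = []
        starts: list[np.ndarray] = []
        for name, length in self.chromosomes:
            s = np.arange(0, length, self.bin_width, dtype=np.int64)
            chroms.extend([name] * len(s))
            starts.append(s)
        start = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
        end = start + self.bin_width
        # clip last bin of each chromosome
        lengths = np.repeat(
            [length for _, length in self.chromosomes], self._n_bins_per_chrom
        )
        end = np.minimum(end, lengths)
        return pd.DataFrame(
            {"chrom": chroms, "start": start, "end": end, "bin_index": np.arange(len(start))}
        )

    def chrom_of_bins(self, indices: np.ndarray) -> np.ndarray:
        """Chromosome name for each global bin index (vectorized)."""
        ci = np.searchsorted(self._offsets, indices, side="right") - 1
        names = np.array(self.chrom_names, dtype=object)
        return names[ci]

    def starts_of_bins(self, indices: np.ndarray) -> np.ndarray:
        ci = np.searchsorted(self._offsets, indices, side="right") - 1
        return (np.asarray(indices) - self._offsets[ci]) * self.bin_width


def build_bins(chrom_sizes: Mapping[str, int], bin_width: int = 1000) -> BinSet:
    """Partition a genome into non-overlapping fixed-width bins.

    Parameters
    ----------
    chrom_sizes
        Ordered mapping of chromosome name to length in bp.
    bin_width
        Bin width in bp (default 1000).
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if not chrom_sizes:
        raise ValueError("chromosome list is empty")
    for name, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
    return BinSet(tuple(chrom_sizes.items()), bin_width)


def read_chrom_sizes(path, canonical_only: bool = False) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split("\t")[:2]
            if canonical_only and name not in CANONICAL_CHROMS:
                continue
            sizes[name] = int(length)
    if not sizes:
        raise ValueError(f"no chromosomes read from {path}")
    return sizes


@dataclass
class BinCoverage:
    """Per-bin raw read counts and per-million-normalized coverage.

    ``bin_indices`` maps each stored value to its global bin in ``bins``;
    for freshly counted coverage it is the identity, after blocklist
    application it is the retained subset.
    """

    sample_id: str
    mapq_min: int
    raw: np.ndarray
    cpm: np.ndarray
    total_mapped_reads: int
    bins: BinSet
    bin_indices: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        self.cpm = np.asarray(self.cpm, dtype=float)
        if self.bin_indices is None:
            self.bin_indices = np.arange(self.bins.n_bins, dtype=np.int64)
        else:
            self.bin_indices = np.asarray(self.bin_indices, dtype=np.int64)
        if not (len(self.raw) == len(self.cpm) == len(self.bin_indices)):
            raise ValueError("raw, cpm and bin_indices must have equal length")

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        raw: np.ndarray,
        total_mapped_reads: int,
        bins: BinSet,
        mapq_min: int,
    ) -> "BinCoverage":
        cpm = normalize_per_million(raw, total_mapped_reads)
        return cls(sample_id, mapq_min, np.asarray(raw), cpm, total_mapped_reads, bins)

    @property
    def n_bins(self) -> int:
        return len(self.raw)

    def to_frame(self) -> pd.DataFrame:
        chrom = self.bins.chrom_of_bins(self.bin_indices)
        start = self.bins.starts_of_bins(self.bin_indices)
        lengths = np.array([self.bins.chrom_length(c) for c in chrom], dtype=np.int64)
        end = np.minimum(start + self.bins.bin_width, lengths)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "raw_count": self.raw,
                "cpm": self.cpm,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def normalize_per_million(raw: np.ndarray, total_mapped_reads: int) -> np.ndarray:
    """cpm[i] = raw[i] / (total_mapped_reads / 1e6)."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return np.asarray(raw, dtype=float) / (total_mapped_reads / 1e6)


def count_reads_in_bins(
    alignments: Iterable[tuple] | pd.DataFrame,
    bins: BinSet,
    mapq_min: int = 40,
    stats: dict | None = None,
) -> np.ndarray:
    """Count aligned reads into genome bins.

    A read with MAPQ >= ``mapq_min`` contributes +1 to every bin it overlaps
    by at least one bp (``bedtools coverage -counts`` semantics). Unmapped,
    secondary and supplementary records contribute nothing; mates are counted
    independently. Reads on chromosomes absent from the BinSet are skipped
    and logged, not fatal.

    Parameters
    ----------
    alignments
        Iterable of ``(chrom, start, end, mapq, flags)`` records, or a
        DataFrame with columns chrom/start/end/mapq (flags optional).
    stats
        Optional dict filled with counters: n_records, n_counted,
        n_filtered_mapq, n_filtered_flags, n_skipped_chrom.
    """
    counts = np.zeros(bins.n_bins, dtype=np.int64)
    n_records = n_counted = n_mapq = n_flags = n_skip = 0
    w = bins.bin_width

    if isinstance(alignments, pd.DataFrame):
        flags = (
            alignments["flags"].to_numpy()
            if "flags" in alignments.columns
            else np.zeros(len(alignments), dtype=np.int64)
        )
        records = zip(
            alignments["chrom"].to_numpy(),
            alignments["start"].to_numpy(),
            alignments["end"].to_numpy(),
            alignments["mapq"].to_numpy(),
            flags,
        )
    else:
        records = iter(alignments)

    exclude = FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY
    for chrom, start, end, mapq, flg in records:
        n_records += 1
        if flg & exclude:
            n_flags += 1
            continue
        if mapq < mapq_min:
            n_mapq += 1
            continue
        if not bins.has_chrom(chrom):
            n_skip += 1
            continue
        off = bins.offset(chrom)
        nchrom = bins.n_bins_chrom(chrom)
        first = max(int(start) // w, 0)
        last = min((int(end) - 1) // w, nchrom - 1)
        if last < first:
            continue
        counts[off + first : off + last + 1] += 1
        n_counted += 1

    if n_skip:
        logger.warning("%d reads on chromosomes absent from BinSet were skipped", n_skip)
    if stats is not None:
        stats.update(
            n_records=n_records,
            n_counted=n_counted,
            n_filtered_mapq=n_mapq,
            n_filtered_flags=n_flags,
            n_skipped_chrom=n_skip,
        )
    return counts


def count_bam(path, bins: BinSet, mapq_min: int = 40, stats: dict | None = None) -> np.ndarray:
    """Count reads from a coordinate-sorted BAM/SAM file into bins."""
    import pysam

    def gen():
        with pysam.AlignmentFile(str(path), check_sq=False) as bam:
            for rec in bam:
                if rec.is_unmapped:
                    yield ("*", 0, 0, 0, FLAG_UNMAPPED)
                    continue
                yield (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end if rec.reference_end is not None else rec.reference_start + 1,
                    rec.mapping_quality,
                    rec.flag,
                )

    return count_reads_in_bins(gen(), bins, mapq_min=mapq_min, stats=stats)


def read_bed_alignments(path) -> pd.DataFrame:
    """Read a 6+-column BED-like alignment table (chrom, start, end, name, MAPQ, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "mapq", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "mapq": np.int64},
    )
    return df


@dataclass(frozen=True)
class CoverageHistogram:
    """Counts of bins whose cpm falls in each half-open coverage range."""

    range_edges: tuple[float, ...]
    counts_per_range: tuple[int, ...]


def coverage_histogram(cpm: np.ndarray, range_edges: Sequence[float]) -> CoverageHistogram:
    """Histogram bin-level cpm values into half-open ranges [e_i, e_{i+1})."""
    edges = np.asarray(range_edges, dtype=float)
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("range_edges must be strictly ascending with >= 2 values")
    cpm = np.asarray(cpm, dtype=float)
    # np.histogram closes the last interval on the right; shrink it back to
    # half-open by counting values equal to the top edge separately.
    counts, _ = np.histogram(cpm, bins=edges)
    if np.isfinite(edges[-1]):
        counts[-1] -= int(np.count_nonzero(cpm == edges[-1]))
    return CoverageHistogram(tuple(edges), tuple(int(c) for c in counts))
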