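"""Same-orientation (FF/RR) read-pair scanning and insert-size partitioning.

A fold-back inversion junction reflects one end of a DNA fragment onto the
opposite strand of the reference, so junction-spanning pairs map with both
mates in the same orientation (forward-forward or reverse-reverse) instead
of the concordant forward-reverse. Clusters of such pairs mark candidate
palindromic junctions / amplicon breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class MateRecord:
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mapq: int


@dataclass(frozen=True)
class OrientedPair:
    chrom: str
    pos1: int  # leftmost coordinate of each mate, pos1 <= pos2
    pos2: int
    orientation: str  # FR | RF | FF | RR | other
    insert_size: int  # outer distance, >= 0
    mapq1: int
    mapq2: int
    name: str = ""


def classify_pair_orientation(mate_a: MateRecord, mate_b: MateRecord) -> str:
    """Orientation class of a mate pair from strand flags alone.

    FF if both forward, RR if both reverse; otherwise FR when the leftmost
    mate is forward, RF when it is reverse. Inter-chromosomal pairs are
    'other'. Symmetric in mate order.
    """
    if mate_a.chrom != mate_b.chrom:
        return "other"
    left, right = sorted((mate_a, mate_b), key=lambda m: (m.start, m.strand))
    if left.strand == "+" and right.strand == "+":
        return "FF"
    if left.strand == "-" and right.strand == "-":
        return "RR"
    return "FR" if left.strand == "+" else "RF"


def make_pair(mate_a: MateRecord, mate_b: MateRecord, name: str = "") -> OrientedPair:
    orientation = classify_pair_orientation(mate_a, mate_b)
    left, right = sorted((mate_a, mate_b), key=lambda m: m.start)
    insert = max(right.end - left.start, 0)
    return OrientedPair(
        chrom=mate_a.chrom if orientation != "other" else "*",
        pos1=left.start,
        pos2=right.start,
        orientation=orientation,
        insert_size=insert,
        mapq1=left.mapq,
        mapq2=right.mapq,
        name=name,
    )


def pairs_from_records(records: pd.DataFrame) -> list[OrientedPair]:
    """Pair alignment records by read name.

    Expects columns chrom/start/end/name/mapq/strand; names with exactly two
    records form a pair, others are ignored.
    """
    pairs = []
    for name, grp in records.groupby("name", sort=True):
        if len(grp) != 2:
            continue
        a, b = (
            MateRecord(str(r.chrom), int(r.start), int(r.end), str(r.strand), int(r.mapq))
            for r in grp.itertuples()
        )
        pairs.append(make_pair(a, b, name=str(name)))
    return pairs


@dataclass(frozen=True)
class PairCluster:
    chrom: str
    start: int
    end: int
    orientation: str
    support: int


def find_same_orientation_clusters(
    pairs: Iterable[OrientedPair],
    region: tuple[str, int, int] | None = None,
    min_mapq: int = 40,
    min_support: int = 3,
    merge_distance: int = 1000,
    known_chroms: set[str] | None = None,
) -> list[PairCluster]:
    """Cluster FF/RR pairs whose mate positions co-locate.

    Pairs (both mates passing ``min_mapq``) are merged greedily, in
    coordinate order and separately per orientation class, whenever both
    mate positions fall within ``merge_distance`` of the cluster's previous
    pair. Clusters with support below ``min_support`` are discarded. When a
    ``region`` restriction is given its chromosome must belong to
    ``known_chroms`` (if supplied).
    """
    kept = [
        p
        for p in pairs
        if p.orientation in ("FF", "RR") and p.mapq1 >= min_mapq and p.mapq2 >= min_mapq
    ]
    if region is not None:
        chrom, start, end = region
        if known_chroms is not None and chrom not in known_chroms:
            raise ValueError(f"region chromosome {chrom!r} is not a known chromosome")
        kept = [p for p in kept if p.chrom == chrom and start <= p.pos1 and p.pos2 < end]
    clusters: list[PairCluster] = []
    for orientation in ("FF", "RR"):
        group = sorted(
            (p for p in kept if p.orientation == orientation),
            key=lambda p: (p.chrom, p.pos1, p.pos2),
        )
        current: list[OrientedPair] = []
        for p in group:
            if current and (
                p.chrom == current[-1].chrom
                and abs(p.pos1 - current[-1].pos1) <= merge_distance
                and abs(p.pos2 - current[-1].pos2) <= merge_distance
            ):
                current.append(p)
            else:
                if len(current) >= min_support:
                    clusters.append(_close_cluster(current, orientation))
                current = [p]
        if len(current) >= min_support:
            clusters.append(_close_cluster(current, orientation))
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


def _close_cluster(members: Sequence[OrientedPair], orientation: str) -> PairCluster:
    return PairCluster(
        chrom=members[0].chrom,
        start=min(p.pos1 for p in members),
        end=max(p.pos2 for p in members),
        orientation=orientation,
        support=len(members),
    )


@dataclass(frozen=True)
class InsertSizePartition:
    short: list
    long: list
    n_unpaired: int


def partition_by_insert_size(
    pairs: Iterable[OrientedPair | None], cutoff: int = 200, long_inclusive: bool = True
) -> InsertSizePartition:
    """Split pairs into short (< cutoff) and long (>= cutoff) insert streams.

    With ``long_inclusive`` (default) an insert exactly at the cutoff goes
    to the long stream. Unpaired entries (None) are routed to neither stream
    and counted; |short| + |long| + unpaired equals the input size.
    """
    short: list = []
    long_: list = []
    n_unpaired = 0
    for p in pairs:
        if p is None:
            n_unpaired += 1
        elif (p.insert_size < cutoff) if long_inclusive else (p.insert_size <= cutoff):
            short.append(p)
        else:
            long_.append(p)
    return InsertSizePartition(short=short, long=long_, n_unpaired=n_unpaired)
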