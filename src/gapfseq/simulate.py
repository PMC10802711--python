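"""Synthetic GAPF-seq cohorts, dilution series and junction read pairs.

The generator reproduces the statistical structure palindrome-enrichment
sequencing assumes, on a toy genome small enough that full pipeline runs
finish in seconds:

* a heavy mass of near-zero bins (background mean 0.31 cpm, overdispersed
  negative-binomial counts);
* shared artifact bins enriched in both tumor and normal libraries
  (~2.4% of bins, the blocklist's prey);
* dispersed high-coverage bins in normals, spread in proportion to
  chromosome length;
* chromosome-clustered high-coverage bins in tumors (planted clusters of
  100-300 bins at 20-65.5 cpm on one chromosome per sample);
* dilution series whose planted peak coverage scales linearly with tumor
  fraction (base peak 65.5 cpm);
* paired alignments with FF/RR pairs flanking a planted fold-back junction.

Every output is a deterministic function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import BinCoverage, BinSet, build_bins

TOY_GENOME: dict[str, int] = {
    name: 5_000_000 for name in [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
}


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial counts with mean/dispersion parameterization.

    ``dispersion`` is the NB size parameter r: variance = mean + mean^2 / r.
    """
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int64)


@dataclass(frozen=True)
class TumorClusterSpec:
    """A planted palindromic amplicon: C contiguous enriched bins on one chromosome.

    ``chrom=None`` draws the chromosome per tumor sample (chr1-22).
    Scalar ``n_bins`` / ``cpm`` fix the value; 2-tuples draw uniformly.
    """

    chrom: str | None = None
    n_bins: int | tuple[int, int] = (100, 300)
    cpm: float | tuple[float, float] = (20.0, 65.5)


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic tumor/normal GAPF cohort.

    Defaults emulate the study conditions: 39 tumor/normal pairs, 1-kb
    bins, background mean 0.31 cpm, ~2.4% shared artifact bins, dispersed
    high bins in every sample and one strong cluster per tumor.
    """

    n_tumor: int = 39
    n_normal: int = 39
    genome: Mapping[str, int] = field(default_factory=lambda: dict(TOY_GENOME))
    bin_width: int = 1000
    total_mapped_reads: int = 10_000_000
    background_rate: float = 0.31  # mean cpm of non-enriched bins
    background_dispersion: float = 1.0
    n_artifact_bins: int = 2800
    artifact_cpm: float = 50.0
    artifact_dispersion: float = 10.0
    n_dispersed_hcbs: int = 1200  # per-sample high bins, spread with chromosome length
    dispersed_cpm: float = 12.0
    dispersed_dispersion: float = 5.0
    tumor_cluster: TumorClusterSpec = field(default_factory=TumorClusterSpec)
    enriched_dispersion: float = 10.0


@dataclass
class SimulatedCohort:
    bins: BinSet
    coverages: list[BinCoverage]
    labels: list[str]
    truth: dict

    def feature_table(self) -> pd.DataFrame:
        """Truth-independent convenience view of sample ids and labels."""
        return pd.DataFrame(
            {"sample_id": [c.sample_id for c in self.coverages], "label": self.labels}
        )

    def write(self, out_dir) -> None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cov in self.coverages:
            cov.write_tsv(out / f"{cov.sample_id}.coverage.tsv")
        self.feature_table().to_csv(out / "labels.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)


def _cpm_to_raw_mean(cpm: float, total_mapped_reads: int) -> float:
    return cpm * total_mapped_reads / 1e6


def _draw(rng: np.random.Generator, value, integer: bool = False):
    if isinstance(value, tuple):
        lo, hi = value
        return int(rng.integers(lo, hi + 1)) if integer else float(rng.uniform(lo, hi))
    return int(value) if integer else float(value)


def simulate_cohort(spec: CohortSpec, seed: int) -> SimulatedCohort:
    """Draw a labelled tumor/normal cohort of binned coverage tracks.

    Tumor samples carry the planted cluster; both classes carry the shared
    artifact bins (identical positions cohort-wide) and per-sample dispersed
    high bins. The truth record lists every planted bin.
    """
    bins = build_bins(spec.genome, spec.bin_width)
    rng = np.random.default_rng(seed)
    n_bins = bins.n_bins

    artifact_idx = np.sort(rng.choice(n_bins, size=spec.n_artifact_bins, replace=False))

    chrom_names = list(bins.chrom_names)
    cluster_chrom_pool = [c for c in chrom_names if c not in ("chrX", "chrY")]

    coverages: list[BinCoverage] = []
    labels: list[str] = []
    truth_samples = {}
    sample_defs = [("tumor", i) for i in range(spec.n_tumor)] + [
        ("normal", i) for i in range(spec.n_normal)
    ]
    for label, i in sample_defs:
        sid = f"{label[0].upper()}{i + 1:03d}"
        raw = _nb_counts(
            rng,
            _cpm_to_raw_mean(spec.background_rate, spec.total_mapped_reads),
            spec.background_dispersion,
            n_bins,
        )
        # shared artifacts, identical positions in every sample
        raw[artifact_idx] = _nb_counts(
            rng,
            _cpm_to_raw_mean(spec.artifact_cpm, spec.total_mapped_reads),
            spec.artifact_dispersion,
            len(artifact_idx),
        )
        # dispersed high bins: uniform over bins == proportional to chromosome length
        dispersed_idx = rng.choice(n_bins, size=spec.n_dispersed_hcbs, replace=False)
        raw[dispersed_idx] = _nb_counts(
            rng,
            _cpm_to_raw_mean(spec.dispersed_cpm, spec.total_mapped_reads),
            spec.dispersed_dispersion,
            len(dispersed_idx),
        )
        sample_truth: dict = {
            "label": label,
            "dispersed_bins": [int(b) for b in np.sort(dispersed_idx)],
        }
        if label == "tumor":
            cl = spec.tumor_cluster
            chrom = cl.chrom if cl.chrom is not None else cluster_chrom_pool[
                int(rng.integers(len(cluster_chrom_pool)))
            ]
            c_bins = _draw(rng, cl.n_bins, integer=True)
            c_cpm = _draw(rng, cl.cpm)
            n_chrom = bins.n_bins_chrom(chrom)
            if c_bins > n_chrom:
                raise ValueError(
                    f"cluster of {c_bins} bins exceeds {chrom}'s {n_chrom} bins"
                )
            start_bin = int(rng.integers(0, n_chrom - c_bins + 1))
            idx = bins.offset(chrom) + start_bin + np.arange(c_bins)
            raw[idx] = _nb_counts(
                rng,
                _cpm_to_raw_mean(c_cpm, spec.total_mapped_reads),
                spec.enriched_dispersion,
                c_bins,
            )
            sample_truth["cluster"] = {
                "chrom": chrom,
                "start_bin": start_bin,
                "n_bins": int(c_bins),
                "cpm": float(c_cpm),
            }
        coverages.append(
            BinCoverage.from_counts(sid, raw, spec.total_mapped_reads, bins, mapq_min=40)
        )
        labels.append(label)
        truth_samples[sid] = sample_truth

    truth = {
        "seed": seed,
        "artifact_bins": [int(b) for b in artifact_idx],
        "samples": truth_samples,
    }
    return SimulatedCohort(bins=bins, coverages=coverages, labels=labels, truth=truth)


# ---------------------------------------------------------------------------
# Dilution series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DilutionSpec:
    """A tumor-into-normal in vitro dilution series.

    The planted peak's expected cpm scales linearly with tumor fraction
    before noise; the background does not change.
    """

    fractions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.1)
    base_peak_cpm: float = 65.5
    background_rate: float = 0.31
    background_dispersion: float = 1.0
    peak_dispersion: float = 20.0
    genome: Mapping[str, int] = field(default_factory=lambda: dict(TOY_GENOME))
    bin_width: int = 1000
    total_mapped_reads: int = 10_000_000
    n_peak_bins: int = 3  # contiguous bins of the planted palindromic junction
    peak_chrom: str = "chr1"
    peak_start_bin: int = 2000
    noise: bool = True


def simulate_dilution_series(
    spec: DilutionSpec, seed: int
) -> tuple[list[tuple[float, BinCoverage]], dict]:
    """Coverage tracks for each tumor fraction, plus the planted-peak truth."""
    if any(f <= 0 or f > 1 for f in spec.fractions):
        raise ValueError("tumor fractions must lie in (0, 1]; use a normal sample for 0")
    bins = build_bins(spec.genome, spec.bin_width)
    rng = np.random.default_rng(seed)
    peak_idx = bins.offset(spec.peak_chrom) + spec.peak_start_bin + np.arange(spec.n_peak_bins)
    series = []
    for f in spec.fractions:
        peak_mean = _cpm_to_raw_mean(f * spec.base_peak_cpm, spec.total_mapped_reads)
        bg_mean = _cpm_to_raw_mean(spec.background_rate, spec.total_mapped_reads)
        if spec.noise:
            raw = _nb_counts(rng, bg_mean, spec.background_dispersion, bins.n_bins)
            raw[peak_idx] = _nb_counts(rng, peak_mean, spec.peak_dispersion, len(peak_idx))
        else:
            raw = np.full(bins.n_bins, int(round(bg_mean)), dtype=np.int64)
            raw[peak_idx] = int(round(peak_mean))
        series.append(
            (
                f,
                BinCoverage.from_counts(
                    f"dilution_{f:g}", raw, spec.total_mapped_reads, bins, mapq_min=40
                ),
            )
        )
    truth = {
        "peak_bins": [int(i) for i in peak_idx],
        "peak_chrom": spec.peak_chrom,
        "base_peak_cpm": spec.base_peak_cpm,
    }
    return series, truth


# ---------------------------------------------------------------------------
# Fold-back junction read pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionSpec:
    """A planted fold-back junction emitting same-orientation read pairs.

    Junction-spanning fragments have their far end reflected across the
    junction, so both mates map on the same strand: FF when the fragment
    approaches from the left arm, RR from the right.
    """

    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    junction_pos: int = 500_000
    arm_length: int = 5_000
    read_length: int = 100
    n_pairs: int = 200
    fraction_spanning: float = 0.1
    mapq: int = 60
    insert_mean: float = 300.0
    insert_sd: float = 30.0


def simulate_junction_alignments(
    spec: JunctionSpec, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Emit paired alignment records around a planted fold-back junction.

    Returns a BED-like table (chrom, start, end, name, mapq, strand), two
    rows per pair, plus a truth record naming the spanning pairs.
    """
    if spec.read_length >= spec.arm_length:
        raise ValueError("read length must be smaller than the arm length")
    if not (0 <= spec.fraction_spanning <= 1):
        raise ValueError("fraction_spanning must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p, rl = spec.junction_pos, spec.read_length
    rows = []
    spanning_names = []
    n_span = int(round(spec.n_pairs * spec.fraction_spanning))
    for i in range(spec.n_pairs):
        name = f"pair{i:05d}"
        insert = int(max(rng.normal(spec.insert_mean, spec.insert_sd), 2 * rl + 10))
        if i < n_span:
            # spanning: far end reflected across the junction -> FF (left) / RR (right)
            u = int(rng.integers(rl, insert - rl + 1))
            side = rng.integers(2)
            if side == 0:  # fragment enters from the left arm
                m1 = (p - u, "+")
                m2 = (p + u - insert, "+")
            else:
                m1 = (p + u - rl, "-")
                m2 = (p + insert - u - rl, "-")
            spanning_names.append(name)
        else:
            lo = max(p - spec.arm_length, 0)
            hi = min(p + spec.arm_length, spec.chrom_length) - insert
            s = int(rng.integers(lo, max(hi, lo + 1)))
            m1 = (s, "+")
            m2 = (s + insert - rl, "-")
        for mate, (start, strand) in enumerate((m1, m2), start=1):
            rows.append(
                {
                    "chrom": spec.chrom,
                    "start": int(start),
                    "end": int(start) + rl,
                    "name": name,
                    "mapq": spec.mapq,
                    "strand": strand,
                }
            )
    records = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable").reset_index(
        drop=True
    )
    truth = {
        "junction_pos": p,
        "spanning_pairs": spanning_names,
        "n_spanning": len(spanning_names),
        "spec": asdict(spec),
    }
    return records, truth


def simulate_control_library(
    bins: BinSet,
    control_regions: Sequence,
    n_background_reads: int = 5_000,
    reads_per_region: int = 400,
    multimap_fraction: float = 0.9,
    read_length: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Alignments emulating a QC run over control inverted repeats.

    Control-repeat reads are mostly multi-mapping (MAPQ 0) so that the
    uniqueness filter depletes them; background reads map uniquely (MAPQ 60).
    """
    rng = np.random.default_rng(seed)
    rows = []
    total_bp = sum(length for _, length in bins.chromosomes)
    for i in range(n_background_reads):
        # position uniform over the concatenated genome
        gpos = int(rng.integers(0, total_bp - read_length))
        for name, length in bins.chromosomes:
            if gpos < length:
                chrom, start = name, min(gpos, length - read_length)
                break
            gpos -= length
        rows.append((chrom, start, start + read_length, f"bg{i:06d}", 60, "+"))
    for region in control_regions:
        for j in range(reads_per_region):
            start = int(rng.integers(region.start, max(region.end - read_length, region.start + 1)))
            mapq = 0 if rng.random() < multimap_fraction else 60
            rows.append(
                (region.chrom, start, start + read_length, f"{region.label}_{j:04d}", mapq, "+")
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "mapq", "strand"])


# ---------------------------------------------------------------------------
# Alignment record writers (BED / SAM dialects)
# ---------------------------------------------------------------------------

def write_bed_alignments(records: pd.DataFrame, path) -> None:
    records[["chrom", "start", "end", "name", "mapq", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_sam(records: pd.DataFrame, chrom_sizes: Mapping[str, int], path) -> None:
    """Write paired BED-like records as SAM (mates matched by name)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in chrom_sizes.items()],
    }
    refids = {name: i for i, name in enumerate(chrom_sizes)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, grp in records.groupby("name", sort=True):
            mates = list(grp.itertuples())
            for k, rec in enumerate(mates):
                a = pysam.AlignedSegment()
                a.query_name = str(name)
                a.reference_id = refids[rec.chrom]
                a.reference_start = int(rec.start)
                a.mapping_quality = int(rec.mapq)
                length = int(rec.end - rec.start)
                a.cigarstring = f"{length}M"
                a.query_sequence = "N" * length
                flag = 0
                if len(mates) == 2:
                    other = mates[1 - k]
                    flag |= 0x1 | (0x40 if k == 0 else 0x80)
                    if rec.strand == "-":
                        flag |= 0x10
                    if other.strand == "-":
                        flag |= 0x20
                    a.next_reference_id = refids[other.chrom]
                    a.next_reference_start = int(other.start)
                elif rec.strand == "-":
                    flag |= 0x10
                a.flag = flag
                out.write(a)
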