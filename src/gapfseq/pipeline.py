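"""End-to-end pipeline: coverage -> QC -> blocklist -> profiles -> calls.

The runner consumes per-sample aligned-read tables (BED-like TSV or
BAM/SAM) or precomputed per-bin coverage TSVs, executes every analysis
stage in order and writes a machine-readable JSON run report whose stage
counts reconcile with each other. Re-running an identical configuration on
identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import background, classify, coverage, profiles

logger = logging.getLogger(__name__)


@dataclass
class SampleSpec:
    sample_id: str
    path: str
    label: str  # tumor | normal
    format: str = "bed"  # bed | bam | coverage


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    samples: list[SampleSpec]
    chrom_sizes: str
    out_dir: str
    bin_width: int = 1000
    mapq_min: int = 40
    k: int = 1000
    threshold: int | None = None
    blocklist: str | None = None
    build_blocklist: bool = False
    enrich_cutoff: float = 5.0
    min_fraction: float = 0.75
    control_regions: str | None = None
    folds: int = 3
    seeds: tuple[int, ...] = (22, 32, 42)
    canonical_only: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleSpec(**s) for s in raw.pop("samples")]
        seeds = tuple(raw.pop("seeds", (22, 32, 42)))
        return cls(samples=samples, seeds=seeds, **raw)

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("no samples configured")
        for p in [self.chrom_sizes, self.blocklist, self.control_regions] + [
            s.path for s in self.samples
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.bin_width <= 0 or self.k <= 0 or self.folds < 2:
            raise ValueError("bin_width and K must be positive; folds >= 2")
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")


def _load_sample_coverage(spec: SampleSpec, bins, mapq_min: int, stats: dict):
    if spec.format == "coverage":
        df = pd.read_csv(spec.path, sep="\t")
        raw = df["raw_count"].to_numpy(dtype=np.int64)
        if len(raw) != bins.n_bins:
            raise ValueError(
                f"{spec.sample_id}: coverage table has {len(raw)} bins, BinSet has {bins.n_bins}"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(raw > 0, df["cpm"].to_numpy() / raw, np.nan)
        total = int(round(1e6 / np.nanmedian(scale))) if np.isfinite(scale).any() else 1
        stats.update(n_records=len(raw), n_counted=len(raw))
        return coverage.BinCoverage(
            spec.sample_id, mapq_min, raw, df["cpm"].to_numpy(), total, bins
        )
    if spec.format == "bam":
        raw = coverage.count_bam(spec.path, bins, mapq_min=mapq_min, stats=stats)
    else:
        aln = coverage.read_bed_alignments(spec.path)
        raw = coverage.count_reads_in_bins(aln, bins, mapq_min=mapq_min, stats=stats)
    total = max(stats.get("n_counted", 0) + stats.get("n_skipped_chrom", 0), 1)
    return coverage.BinCoverage.from_counts(spec.sample_id, raw, total, bins, mapq_min)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sizes = coverage.read_chrom_sizes(config.chrom_sizes, canonical_only=config.canonical_only)
    bins = coverage.build_bins(sizes, config.bin_width)
    report: dict = {"stages": {}, "samples": {}}
    report["stages"]["bins"] = {"n_bins": bins.n_bins, "bin_width": config.bin_width}

    covs, labels = [], []
    qc_flags: dict[str, bool] = {}
    ctrl = (
        background.read_control_regions(config.control_regions)
        if config.control_regions
        else None
    )
    for spec in config.samples:
        stats: dict = {}
        cov = _load_sample_coverage(spec, bins, config.mapq_min, stats)
        covs.append(cov)
        labels.append(spec.label)
        sample_rep = {"label": spec.label, "counting": stats}
        if ctrl is not None and spec.format in ("bed", "bam"):
            unf_stats: dict = {}
            unfiltered = _load_sample_coverage(
                SampleSpec(spec.sample_id, spec.path, spec.label, spec.format),
                bins, 0, unf_stats,
            )
            qc = background.qc_evaluate(
                background.amplification_score(unfiltered, ctrl),
                background.depletion_score(cov, ctrl),
            )
            qc_flags[spec.sample_id] = qc.passed
            sample_rep["qc"] = {
                "amplification_score": qc.amplification_score,
                "depletion_score": qc.depletion_score,
                "pass": qc.passed,
            }
            if not qc.passed:
                logger.warning("sample %s failed QC; flagged qc_fail downstream", spec.sample_id)
        report["samples"][spec.sample_id] = sample_rep

    if config.blocklist:
        blocklist = background.BlockList.read_bed(config.blocklist)
    elif config.build_blocklist:
        blocklist = background.identify_background_bins(
            covs, labels, enrich_cutoff=config.enrich_cutoff, min_fraction=config.min_fraction
        )
        blocklist.write_bed(out / "blocklist.bed", bins)
    else:
        blocklist = background.BlockList(frozenset())
    filtered = [background.apply_blocklist(c, blocklist) for c in covs]
    report["stages"]["blocklist"] = {
        "n_blocklisted": len(blocklist),
        "n_retained": filtered[0].n_bins if filtered else 0,
        "n_total": bins.n_bins,
    }
    assert report["stages"]["blocklist"]["n_retained"] == bins.n_bins - len(blocklist)

    profs = [
        profiles.chromosome_profile(profiles.top_k_hcbs(c, config.k), bins.chrom_names)
        for c in filtered
    ]
    table = profiles.profiles_to_frame(profs)
    table.to_csv(out / "profiles.tsv", sep="\t")
    for p in profs:
        if int(p.counts.sum()) != min(config.k, filtered[0].n_bins):
            raise AssertionError(f"profile of {p.sample_id} does not sum to K")
    report["stages"]["profiles"] = {"k": config.k, "n_samples": len(profs)}

    X = table.to_numpy()
    y = np.array([1 if l == "tumor" else 0 for l in labels])
    scores = classify.sample_scores(X)
    calls_rows = []
    if len(np.unique(y)) == 2:
        roc = classify.roc_from_scores(scores, y)
        roc.points.to_csv(out / "roc.tsv", sep="\t", index=False)
        threshold = config.threshold if config.threshold is not None else roc.optimal_threshold
        cv = classify.cross_validate_threshold(X, y, folds=config.folds, seeds=config.seeds)
        with open(out / "cv_report.json", "w") as fh:
            json.dump(cv.to_dict(), fh, indent=2)
        report["stages"]["classification"] = {
            "auc": roc.auc,
            "youden_threshold": roc.optimal_threshold,
            "youden_j": roc.youden_j,
            "threshold_used": int(threshold),
            "cv_mean_auc": cv.mean_auc,
            "cv_sd_auc": cv.sd_auc,
        }
    else:
        threshold = config.threshold if config.threshold is not None else 0
        report["stages"]["classification"] = {"note": "single-class cohort; ROC skipped"}
    pos = classify.classify_threshold(scores, int(threshold))
    for sid, lab, s, call in zip(table.index, labels, scores, pos):
        calls_rows.append(
            {
                "sample_id": sid,
                "label": lab,
                "score": int(s),
                "threshold": int(threshold),
                "call": "GAPF-positive" if call else "GAPF-negative",
                "qc_fail": not qc_flags.get(sid, True),
            }
        )
    calls = pd.DataFrame(calls_rows)
    calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    report["stages"]["calls"] = {
        "n_calls": len(calls),
        "n_positive": int(pos.sum()),
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
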