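"""Point-based library quality scoring.

Each sequencing library accumulates penalty points; a score of 0 is a
perfect library and libraries scoring over 15 are discarded, along with
their mate library (input/pulldown pair).  Fixed 5-point criteria use the
printed thresholds; 3 points are awarded per auxiliary metric outside the
cohort median +/- 1.5x IQR; 1 point per listed metric deviating by more
than 2 SD from previously observed ("prior") ranges.

Two quantities without a published definition are defined here:
``uniformity`` is the fraction of non-blacklist 10 kb bins whose fragment
coverage lies within [0.2x, 5x] of the genome-wide mean, and the sequence
diversity score is the fraction of fragments with a unique start position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delfi import make_bins
from .hmc import genic_intergenic_ratio, region_counts, region_rpkm, spikein_folds
from .io import LibraryFragments, RegionSet, SpikeInCounts

__all__ = [
    "QCMetrics",
    "QCResult",
    "CohortDistributions",
    "compute_qc_metrics",
    "compute_cohort_distributions",
    "score_library",
    "score_sample",
]

PASS_THRESHOLD = 15  # "over 15" is strict: total == 15 still passes

# prior-deviation (1-point) checks per library type
PRIOR_CHECKS = {
    "pulldown": ("genic_intergenic_rpkm_ratio", "duplication_rate", "mean_coverage"),
    "input": ("sequence_diversity",),
}


@dataclass
class QCMetrics:
    library_type: str
    dedup_read_count: float
    genic_intergenic_rpkm_ratio: float
    spike_ratio: float | None
    mito_rpkm: float
    pct_reads_in_peaks: float
    median_insert_size: float
    uniformity: float
    sequence_diversity: float
    mean_coverage: float
    duplication_rate: float | None = None
    aux: dict = field(default_factory=dict)  # the configurable auxiliary metric set


@dataclass
class QCResult:
    library_type: str
    points: dict  # criterion -> points awarded
    total: int
    passed: bool
    reasons: list

    def __post_init__(self) -> None:
        assert self.total == sum(self.points.values())


@dataclass
class CohortDistributions:
    """Cohort-level context: per-metric (median, IQR) for the auxiliary 3-point
    rule and optional prior (mean, SD) ranges for the 1-point rule, keyed by
    library type."""

    aux_stats: dict = field(default_factory=dict)  # lib_type -> {metric: (median, iqr)}
    prior_ranges: dict = field(default_factory=dict)  # lib_type -> {metric: (mean, sd)}


def compute_qc_metrics(
    input_lib: LibraryFragments,
    pulldown_lib: LibraryFragments,
    spike_pull: SpikeInCounts,
    spike_in: SpikeInCounts,
    regions: dict[str, RegionSet],
) -> dict[str, QCMetrics]:
    """QC metrics for both libraries of one sample.

    ``regions`` must carry genic/intergenic/peak RegionSets (blacklist
    optional) sharing one genome.  The spike-in criterion compares summed
    hmC-positive folds against the larger negative-control fold; the ratio
    is a per-sample quantity attached to both libraries.
    """
    genome = regions["genic"].genome
    folds = spikein_folds(
        spike_pull, spike_in, pulldown_lib.total_mapped_reads, input_lib.total_mapped_reads
    )
    neg = np.nanmax([folds["mC6"], folds["C0"]])
    spike_ratio = float((folds["hmC1"] + folds["hmC3"] + folds["hmC6"]) / neg) if neg > 0 else float("inf")

    bins = make_bins(genome, regions.get("blacklist"), bin_bp=10_000)
    out = {}
    for lib in (input_lib, pulldown_lib):
        gi = genic_intergenic_ratio(lib, regions["genic"], regions["intergenic"])
        peak_frac = (
            region_counts(lib, regions["peak"]).sum() / lib.n_fragments if lib.n_fragments else 0.0
        )
        mito_rpkm = 0.0
        if "chrM" in genome:
            mito = RegionSet(
                "bin",
                pd.DataFrame(
                    [("chrM", 0, genome["chrM"], None)], columns=["chrom", "start", "end", "name"]
                ),
                genome,
            )
            mito_rpkm = float(region_rpkm(lib, mito).iloc[0])
        bin_counts = region_counts(lib, bins)
        mean_count = bin_counts.mean() if len(bin_counts) else 0.0
        uniformity = (
            float(((bin_counts >= 0.2 * mean_count) & (bin_counts <= 5.0 * mean_count)).mean())
            if mean_count > 0
            else 0.0
        )
        starts = lib.df["start"].to_numpy()
        diversity = float(len(np.unique(starts)) / len(starts)) if len(starts) else 0.0
        metrics = QCMetrics(
            library_type=lib.library_type,
            dedup_read_count=float(lib.total_mapped_reads),
            genic_intergenic_rpkm_ratio=float(gi),
            spike_ratio=spike_ratio,
            mito_rpkm=mito_rpkm,
            pct_reads_in_peaks=100.0 * float(peak_frac),
            median_insert_size=float(np.median(lib.lengths)) if lib.n_fragments else 0.0,
            uniformity=uniformity,
            sequence_diversity=diversity,
            mean_coverage=float(lib.lengths.sum() / sum(genome.values())),
        )
        # default auxiliary set: the scalar metrics plus per-chromosome shares
        metrics.aux = {
            "genic_intergenic_rpkm_ratio": metrics.genic_intergenic_rpkm_ratio,
            "pct_reads_in_peaks": metrics.pct_reads_in_peaks,
            "median_insert_size": metrics.median_insert_size,
            "uniformity": metrics.uniformity,
            "sequence_diversity": metrics.sequence_diversity,
            "mean_coverage": metrics.mean_coverage,
        }
        chroms = lib.df["chrom"].to_numpy()
        for chrom in genome:
            metrics.aux[f"share_{chrom}"] = float((chroms == chrom).mean()) if len(chroms) else 0.0
        out[lib.library_type] = metrics
    return out


def compute_cohort_distributions(cohort_metrics: list[QCMetrics]) -> CohortDistributions:
    """Median and IQR of every auxiliary metric, per library type."""
    dist = CohortDistributions()
    for lib_type in ("input", "pulldown"):
        values: dict[str, list] = {}
        for m in cohort_metrics:
            if m.library_type != lib_type:
                continue
            for k, v in m.aux.items():
                if np.isfinite(v):
                    values.setdefault(k, []).append(v)
        dist.aux_stats[lib_type] = {
            k: (float(np.median(v)), float(np.subtract(*np.percentile(v, [75, 25]))))
            for k, v in values.items()
        }
    return dist


_FIXED_CRITERIA = (
    # (name, library restriction, points, test returning True on violation)
    ("dedup_reads_lt_10M", None, 5, lambda m: m.dedup_read_count < 10e6),
    ("genic_intergenic_lt_1", "pulldown", 5, lambda m: m.genic_intergenic_rpkm_ratio < 1.0),
    ("spike_ratio_lt_1", None, 5, lambda m: m.spike_ratio < 1.0),
    ("mito_rpkm_gt_1000", None, 5, lambda m: m.mito_rpkm > 1000.0),
    ("reads_in_peaks_lt_10pct", None, 5, lambda m: m.pct_reads_in_peaks < 10.0),
    ("median_insert_gt_200", None, 5, lambda m: m.median_insert_size > 200.0),
    ("uniformity_lt_0.8", "input", 5, lambda m: m.uniformity < 0.8),
)


def score_library(
    metrics: QCMetrics, cohort: CohortDistributions | None = None
) -> QCResult:
    """Score one library; pass iff the total is at most 15 points."""
    points: dict[str, int] = {}
    reasons: list[str] = []
    for name, restrict, pts, violated in _FIXED_CRITERIA:
        if restrict is not None and metrics.library_type != restrict:
            continue
        try:
            bad = bool(violated(metrics))
        except TypeError:  # metric missing -> worst case
            bad = True
            reasons.append(f"{name}: metric missing, scored worst case")
        points[name] = pts if bad else 0
        if bad:
            reasons.append(name)
    if cohort is not None:
        for metric, (med, iqr) in cohort.aux_stats.get(metrics.library_type, {}).items():
            value = metrics.aux.get(metric)
            name = f"iqr:{metric}"
            if value is None or not np.isfinite(value):
                points[name] = 3
                reasons.append(f"{name}: metric missing, scored worst case")
                continue
            bad = abs(value - med) > 1.5 * iqr
            points[name] = 3 if bad else 0
            if bad:
                reasons.append(name)
        for metric in PRIOR_CHECKS[metrics.library_type]:
            ranges = cohort.prior_ranges.get(metrics.library_type, {})
            if metric not in ranges:
                continue
            mean, sd = ranges[metric]
            value = getattr(metrics, metric, None)
            name = f"prior:{metric}"
            if value is None or not np.isfinite(value):
                points[name] = 1
                reasons.append(f"{name}: metric missing, scored worst case")
                continue
            bad = abs(value - mean) > 2.0 * sd
            points[name] = 1 if bad else 0
            if bad:
                reasons.append(name)
    total = int(sum(points.values()))
    return QCResult(metrics.library_type, points, total, passed=total <= PASS_THRESHOLD, reasons=reasons)


def score_sample(input_result: QCResult, pulldown_result: QCResult) -> bool:
    """A sample survives only if both of its libraries pass (mate-pair rule)."""
    return input_result.passed and pulldown_result.passed
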