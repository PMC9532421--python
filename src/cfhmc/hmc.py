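"""5hmC quantification features.

Per-region RPKM of pulldown and input libraries, the log2 pulldown/input
enrichment with a pseudocount of 1, spike-in enrichment folds, and the
quantile-normalization + z-scoring used to prepare the feature matrix for
modelling.  Fragments are assigned to regions by midpoint membership and
each fragment counts as 2 reads (proper pair) in the RPKM numerator.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import LibraryFragments, RegionSet, SpikeInCounts, SPIKE_SPECIES

__all__ = [
    "region_counts",
    "region_rpkm",
    "hmc_enrichment",
    "genic_intergenic_ratio",
    "spikein_folds",
    "quantile_normalize",
    "apply_quantile",
    "zscore_fit",
    "zscore_apply",
    "NormalizationState",
    "enrichment_features",
]


def region_counts(lib: LibraryFragments, regions: RegionSet) -> np.ndarray:
    """Number of fragments whose midpoint lies inside each region.

    Regions within a label are non-overlapping and sorted, so midpoint
    membership reduces to a per-chromosome searchsorted.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    if not len(regions) or not lib.n_fragments:
        return counts
    rdf = regions.df
    mids = lib.midpoints
    frag_chrom = lib.df["chrom"].to_numpy()
    offset = 0
    for chrom, sub in rdf.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        m = np.sort(mids[frag_chrom == chrom])
        if len(m):
            # fragments with midpoint in [start, end) per region
            counts[offset : offset + len(sub)] = np.searchsorted(m, ends, side="left") - np.searchsorted(
                m, starts, side="left"
            )
        offset += len(sub)
    return counts


def region_rpkm(lib: LibraryFragments, regions: RegionSet) -> pd.Series:
    """Reads per kilobase of region per million mapped reads.

    ``reads = 2 * midpoint-assigned fragments``; the denominator is the
    library's total mapped read count.
    """
    reads = 2.0 * region_counts(lib, regions)
    kb = regions.lengths / 1_000.0
    per_million = lib.total_mapped_reads / 1e6
    values = reads / kb / per_million if len(regions) else np.array([])
    return pd.Series(values, index=regions.region_ids(), name=f"{lib.sample_id}:{lib.library_type}")


def hmc_enrichment(rpkm_pulldown: pd.Series, rpkm_input: pd.Series, pseudocount: float = 1.0) -> pd.Series:
    """log2((RPKM_pulldown + pc) / (RPKM_input + pc)) per region."""
    if not rpkm_pulldown.index.equals(rpkm_input.index):
        raise ValueError("pulldown and input RPKM vectors index different regions")
    return pd.Series(
        np.log2((rpkm_pulldown.to_numpy() + pseudocount) / (rpkm_input.to_numpy() + pseudocount)),
        index=rpkm_pulldown.index,
        name=rpkm_pulldown.name,
    )


def genic_intergenic_ratio(lib: LibraryFragments, genic: RegionSet, intergenic: RegionSet) -> float:
    """Mean genic RPKM over mean intergenic RPKM (+inf when intergenic is 0)."""
    genic_mean = float(region_rpkm(lib, genic).mean())
    inter_mean = float(region_rpkm(lib, intergenic).mean())
    if inter_mean == 0.0:
        return float("inf")
    return genic_mean / inter_mean


def spikein_folds(
    spike_pull: SpikeInCounts,
    spike_in: SpikeInCounts,
    total_pull: int,
    total_in: int,
) -> pd.Series:
    """Per-species enrichment fold: (pull_s/total_pull) / (in_s/total_in).

    Species with zero input counts are reported as NA.
    """
    pull = spike_pull.as_array() / float(total_pull)
    inp = spike_in.as_array() / float(total_in)
    with np.errstate(divide="ignore", invalid="ignore"):
        folds = np.where(inp > 0, pull / inp, np.nan)
    return pd.Series(folds, index=list(SPIKE_SPECIES), name="fold")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationState:
    """Frozen training-set normalization: reference quantiles + z-scaling.

    Validation samples are mapped onto the training reference; no statistic
    is ever re-estimated outside the training set.
    """

    reference: np.ndarray  # mean order statistics over training samples
    feature_names: list
    mean: np.ndarray | None = None  # post-quantile per-feature mean
    sd: np.ndarray | None = None
    dropped: list = field(default_factory=list)  # zero-SD features

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "reference": np.round(self.reference, 12).tolist(),
                "features": list(self.feature_names),
                "mean": None if self.mean is None else np.round(self.mean, 12).tolist(),
                "sd": None if self.sd is None else np.round(self.sd, 12).tolist(),
                "dropped": list(self.dropped),
            },
            sort_keys=True,
        )
        return hashlib.md5(payload.encode()).hexdigest()

    def to_dict(self) -> dict:
        return {
            "reference": self.reference.tolist(),
            "feature_names": list(self.feature_names),
            "mean": None if self.mean is None else self.mean.tolist(),
            "sd": None if self.sd is None else self.sd.tolist(),
            "dropped": list(self.dropped),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationState":
        return cls(
            reference=np.asarray(d["reference"], dtype=float),
            feature_names=list(d["feature_names"]),
            mean=None if d["mean"] is None else np.asarray(d["mean"], dtype=float),
            sd=None if d["sd"] is None else np.asarray(d["sd"], dtype=float),
            dropped=list(d["dropped"]),
        )

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Quantile-map then z-score a matrix with the frozen training state."""
        qn = apply_quantile(matrix, self)
        return zscore_apply(qn, self)


def _quantile_map(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    # average ranks -> interpolate into the reference order statistics, so
    # ties receive the mean of their reference positions (limma convention)
    ranks = stats.rankdata(values, method="average")
    p = len(reference)
    return np.interp(ranks, np.arange(1, p + 1), reference)


def quantile_normalize(matrix: pd.DataFrame):
    """Quantile-normalize samples (rows) to their mean order statistics.

    Returns the normalized matrix and a :class:`NormalizationState` whose
    reference quantiles are frozen for later application to unseen samples.
    """
    if len(matrix) < 2:
        raise ValueError("quantile normalization needs >= 2 samples to fit")
    X = matrix.to_numpy(dtype=float)
    reference = np.sort(X, axis=1).mean(axis=0)
    out = np.vstack([_quantile_map(row, reference) for row in X])
    state = NormalizationState(reference=reference, feature_names=list(matrix.columns))
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), state


def apply_quantile(matrix: pd.DataFrame, state: NormalizationState) -> pd.DataFrame:
    if list(matrix.columns) != list(state.feature_names):
        raise ValueError("feature mismatch between matrix and normalization state")
    X = matrix.to_numpy(dtype=float)
    out = np.vstack([_quantile_map(row, state.reference) for row in X])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def zscore_fit(matrix: pd.DataFrame, state: NormalizationState) -> pd.DataFrame:
    """Fit per-feature mean/SD on training data; zero-SD features are dropped."""
    mean = matrix.mean(axis=0).to_numpy()
    sd = matrix.std(axis=0, ddof=0).to_numpy()
    dropped = [c for c, s in zip(matrix.columns, sd) if s == 0.0]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance features")
    state.mean, state.sd, state.dropped = mean, sd, dropped
    return zscore_apply(matrix, state)


def zscore_apply(matrix: pd.DataFrame, state: NormalizationState) -> pd.DataFrame:
    if state.mean is None:
        raise ValueError("z-score state not fitted")
    keep = [c for c in matrix.columns if c not in set(state.dropped)]
    keep_idx = [i for i, c in enumerate(state.feature_names) if c not in set(state.dropped)]
    X = matrix[keep].to_numpy(dtype=float)
    return pd.DataFrame(
        (X - state.mean[keep_idx]) / state.sd[keep_idx], index=matrix.index, columns=keep
    )


def enrichment_features(
    pull: LibraryFragments, inp: LibraryFragments, enhancers: RegionSet, pseudocount: float = 1.0
) -> pd.Series:
    """Convenience: one sample's enhancer log2-enrichment feature row."""
    return hmc_enrichment(
        region_rpkm(pull, enhancers), region_rpkm(inp, enhancers), pseudocount=pseudocount
    ).rename(pull.sample_id)
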