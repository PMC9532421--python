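"""Nucleosome Presence Score (NPS) features.

For each base i of a region, a 121 bp window centered on i is scored as
``n_span / n_within``: fragments fully spanning the window over fragments
with at least one endpoint inside it.  High values indicate nucleosome
protection and the statistic is independent of read depth.  The per-base
score is pooled over +/-5 neighboring positions (ratio of sums; NA when the
pooled denominator is 0), NA runs are linearly bridged (edges extended with
the nearest defined value), the profile is smoothed with a degree-2
Savitzky-Golay filter (151 bp window), nucleosomes are called at smoothed
maxima in a 151 bp sliding window (maxima within 76 bp merged to their
midpoint), and features are the minimum smoothed NPS in a +/-50 bp
neighborhood of the midpoint between adjacent nucleosomes <= 300 bp apart.

Only fragments of 120-250 bp (single-nucleosome configurations) contribute.
All coordinates are 0-based half-open; window membership conventions are
fixed here and mirrored by the test oracles: a fragment [s, e) spans the
window of position i iff ``s <= i-60 and e >= i+61``, and has an endpoint
inside it iff ``s`` or ``e-1`` lies in ``[i-60, i+60]``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d
from scipy.signal import savgol_filter

from .io import GenomicInterval, LibraryFragments, RegionSet

__all__ = [
    "NPSConfig",
    "NPSWindowCounts",
    "NPSProfile",
    "size_filter",
    "window_counts",
    "pooled_nps",
    "impute_profile",
    "smooth_profile",
    "call_nucleosomes",
    "nps_features",
    "compute_nps_profile",
    "region_mean_coverage",
    "select_nps_regions",
    "call_coverage_peaks",
    "build_nucleosome_map",
    "sample_nps_features",
    "map_schema_hash",
]


@dataclass(frozen=True)
class NPSConfig:
    window: int = 121  # sliding window (bp), odd
    pool_radius: int = 5  # +/- positions pooled
    size_min: int = 120  # fragment size filter (bp)
    size_max: int = 250
    sg_degree: int = 2  # Savitzky-Golay polynomial degree
    sg_window: int = 151  # Savitzky-Golay window (bp), odd
    call_window: int = 151  # local-max window for nucleosome calling, odd
    merge_distance: int = 76  # maxima closer than this merge to one nucleosome
    pair_gap: int = 300  # max distance between paired nucleosomes
    feature_radius: int = 50  # +/- bp around the pair midpoint
    na_threshold: float = 0.9  # region undefined above this NA fraction
    n_regions: int = 200  # deepest-coverage regions retained

    def __post_init__(self) -> None:
        for name in ("window", "sg_window", "call_window"):
            if getattr(self, name) % 2 == 0:
                raise ValueError(f"{name} must be odd")
        if not (0 < self.merge_distance < self.call_window):
            raise ValueError("need 0 < merge_distance < call_window")


@dataclass
class NPSWindowCounts:
    region: GenomicInterval
    n_span: np.ndarray
    n_within: np.ndarray


@dataclass
class NPSProfile:
    region: GenomicInterval
    pooled: np.ndarray  # per-base pooled NPS (NaN where undefined)
    na_mask: np.ndarray
    imputed: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    undefined: bool = False


def size_filter(df: pd.DataFrame, config: NPSConfig) -> pd.DataFrame:
    lengths = df["end"] - df["start"]
    return df[(lengths >= config.size_min) & (lengths <= config.size_max)]


def _fragment_frame(fragments) -> pd.DataFrame:
    return fragments.df if isinstance(fragments, LibraryFragments) else fragments


def window_counts(fragments, region: GenomicInterval, config: NPSConfig = NPSConfig()) -> NPSWindowCounts:
    """Per-position spanning/endpoint counts over the region.

    Linear-time via difference arrays: each fragment contributes +1 to the
    contiguous run of positions whose window it spans, and to the run(s) of
    positions whose window contains one of its endpoints.
    """
    L = len(region)
    if L < config.window:
        raise ValueError("region shorter than the NPS window")
    df = _fragment_frame(fragments)
    df = size_filter(df[df["chrom"] == region.chrom], config)
    half = (config.window - 1) // 2
    rs = region.start
    span = np.zeros(L + 1, dtype=np.int64)
    within = np.zeros(L + 1, dtype=np.int64)
    if len(df):
        s = df["start"].to_numpy(dtype=np.int64)
        e = df["end"].to_numpy(dtype=np.int64)
        # spanning: i in [s + half, e - half - 1]
        lo = np.clip(s + half - rs, 0, L)
        hi = np.clip(e - half - rs, 0, L)  # exclusive
        ok = hi > lo
        np.add.at(span, lo[ok], 1)
        np.add.at(span, hi[ok], -1)
        # endpoint inside: endpoints s and e-1, each covering i in [p-half, p+half];
        # a fragment counts once even if both endpoints fall in the same window
        p1, p2 = s, e - 1
        joined = (p2 - p1) <= config.window  # unions into one run
        for lo_p, hi_p, mask in (
            (p1, np.where(joined, p2, p1), np.ones(len(s), dtype=bool)),
            (p2, p2, ~joined),
        ):
            lo = np.clip(lo_p - half - rs, 0, L)
            hi = np.clip(hi_p + half + 1 - rs, 0, L)
            ok = mask & (hi > lo)
            np.add.at(within, lo[ok], 1)
            np.add.at(within, hi[ok], -1)
    return NPSWindowCounts(region, np.cumsum(span[:L]), np.cumsum(within[:L]))


def pooled_nps(counts: NPSWindowCounts, config: NPSConfig = NPSConfig()) -> NPSProfile:
    """Ratio-of-sums pooling over +/-pool_radius positions; NA when the
    pooled denominator is zero.  Sums near the region edges use the
    available positions."""
    kernel = np.ones(2 * config.pool_radius + 1)
    num = np.convolve(counts.n_span, kernel, mode="same")
    den = np.convolve(counts.n_within, kernel, mode="same")
    na = den == 0
    values = np.full(len(num), np.nan)
    values[~na] = num[~na] / den[~na]
    undefined = float(na.mean()) > config.na_threshold
    return NPSProfile(counts.region, values, na, undefined=undefined)


def impute_profile(profile: NPSProfile) -> NPSProfile:
    """Linearly bridge interior NA runs; extend edges with the nearest value."""
    if profile.na_mask.all():
        profile.undefined = True
        return profile
    idx = np.arange(len(profile.pooled))
    valid = ~profile.na_mask
    profile.imputed = np.interp(idx, idx[valid], profile.pooled[valid])
    return profile


def smooth_profile(profile: NPSProfile, config: NPSConfig = NPSConfig()) -> NPSProfile:
    """Degree-2 Savitzky-Golay smoothing; edges use a polynomial fit over the
    truncated terminal window (scipy 'interp' mode)."""
    if profile.imputed is None:
        raise ValueError("profile must be imputed before smoothing")
    if len(profile.imputed) < config.sg_window:
        profile.undefined = True
        return profile
    profile.smoothed = savgol_filter(
        profile.imputed, window_length=config.sg_window, polyorder=config.sg_degree, mode="interp"
    )
    return profile


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def call_nucleosomes(profile: NPSProfile, config: NPSConfig = NPSConfig()) -> np.ndarray:
    """Nucleosome centers (absolute bp) from smoothed local maxima.

    A position is a candidate iff it attains the maximum of the 151 bp
    window around it (ties all qualify).  Left-to-right chains of candidates
    with consecutive spacing <= 76 bp collapse to the rounded midpoint of
    the chain extremes; resulting centers are pairwise > 76 bp apart.
    """
    if profile.smoothed is None or profile.undefined:
        raise ValueError("profile has no smoothed values")
    vals = profile.smoothed
    half = (config.call_window - 1) // 2
    rollmax = maximum_filter1d(vals, size=config.call_window, mode="constant", cval=-np.inf)
    cand = np.nonzero(vals >= rollmax)[0]
    if len(cand) == 0:
        return np.array([], dtype=np.int64)
    if len(cand) == len(vals):
        warnings.warn("flat NPS profile: entire region collapses to a single nucleosome")
    centers = []
    chain_start = prev = cand[0]
    for i in cand[1:]:
        if i - prev <= config.merge_distance:
            prev = i
        else:
            centers.append(_round_half_up((chain_start + prev) / 2))
            chain_start = prev = i
    centers.append(_round_half_up((chain_start + prev) / 2))
    return np.asarray(centers, dtype=np.int64) + profile.region.start


def nps_features(
    profile: NPSProfile, nucleosomes: np.ndarray, config: NPSConfig = NPSConfig()
) -> pd.Series:
    """Minimum smoothed NPS around midpoints of adjacent nucleosome pairs.

    Pairs more than ``pair_gap`` bp apart yield no feature.  Feature ids
    encode the region and pair index.
    """
    region = profile.region
    region_id = f"{region.chrom}:{region.start}-{region.end}"
    values, names = [], []
    vals = profile.smoothed
    pair_idx = 0
    for c1, c2 in zip(nucleosomes[:-1], nucleosomes[1:]):
        if c2 - c1 > config.pair_gap:
            continue
        m = _round_half_up((c1 + c2) / 2)
        lo = max(region.start, m - config.feature_radius)
        hi = min(region.end, m + config.feature_radius + 1)
        names.append(f"{region_id}|p{pair_idx}")
        pair_idx += 1
        if vals is None or profile.undefined:
            values.append(np.nan)
        else:
            values.append(float(np.min(vals[lo - region.start : hi - region.start])))
    return pd.Series(values, index=names, dtype=float)


def compute_nps_profile(fragments, region: GenomicInterval, config: NPSConfig = NPSConfig()) -> NPSProfile:
    """Full per-region chain: window counts -> pooling -> imputation -> smoothing."""
    profile = pooled_nps(window_counts(fragments, region, config), config)
    if profile.undefined:
        return profile
    profile = impute_profile(profile)
    if not profile.undefined:
        profile = smooth_profile(profile, config)
    return profile


# ---------------------------------------------------------------------------
# region selection (development samples) and the fixed nucleosome map
# ---------------------------------------------------------------------------


def region_mean_coverage(lib: LibraryFragments, regions: RegionSet) -> np.ndarray:
    """Mean per-base fragment coverage of each region."""
    out = np.zeros(len(regions))
    if not len(regions):
        return out
    genome = regions.genome
    rdf = regions.df
    offset_map = {}
    offset = 0
    for chrom, sub in rdf.groupby("chrom", sort=False):
        offset_map[chrom] = (offset, sub)
        offset += len(sub)
    for chrom, (off, sub) in offset_map.items():
        frag = lib.df[lib.df["chrom"] == chrom]
        if not len(frag):
            continue
        L = genome[chrom]
        diff = np.zeros(L + 1, dtype=np.int64)
        np.add.at(diff, np.clip(frag["start"].to_numpy(), 0, L), 1)
        np.add.at(diff, np.clip(frag["end"].to_numpy(), 0, L), -1)
        cum_cov = np.concatenate([[0], np.cumsum(np.cumsum(diff[:L]))])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        out[off : off + len(sub)] = (cum_cov[ends] - cum_cov[starts]) / (ends - starts)
    return out


def select_nps_regions(
    coverage: pd.DataFrame, candidates: RegionSet, k: int = 200
) -> RegionSet:
    """Top-k candidate regions by across-sample median mean coverage.

    ``coverage`` holds one row per candidate region (in candidate order) and
    one column per development sample.  Ties at rank k break by (chrom,
    start) order; fewer than k candidates returns them all with a warning.
    """
    if len(coverage) != len(candidates):
        raise ValueError("coverage rows must match candidate regions")
    med = coverage.median(axis=1).to_numpy()
    if len(candidates) <= k:
        if len(candidates) < k:
            warnings.warn(f"only {len(candidates)} candidate regions for k={k}")
        return candidates
    order = np.argsort(-med, kind="stable")[:k]  # stable: ties keep (chrom,start) order
    mask = np.zeros(len(candidates), dtype=bool)
    mask[order] = True
    return candidates.subset(mask)


def call_coverage_peaks(
    libs: list[LibraryFragments],
    genome: dict[str, int],
    threshold: float,
    merge_gap: int = 100,
    min_length: int = 200,
) -> RegionSet:
    """Internal substitute peak caller: maximal runs of pooled coverage >=
    threshold, merged when closer than ``merge_gap`` bp."""
    rows = []
    for chrom, L in genome.items():
        diff = np.zeros(L + 1, dtype=np.int64)
        any_frag = False
        for lib in libs:
            frag = lib.df[lib.df["chrom"] == chrom]
            if len(frag):
                any_frag = True
                np.add.at(diff, np.clip(frag["start"].to_numpy(), 0, L), 1)
                np.add.at(diff, np.clip(frag["end"].to_numpy(), 0, L), -1)
        if not any_frag:
            continue
        cov = np.cumsum(diff[:L])
        above = cov >= threshold
        padded = np.concatenate([[False], above, [False]])
        changes = np.flatnonzero(np.diff(padded.astype(np.int8)))
        run_starts, run_ends = changes[::2], changes[1::2]
        merged = []
        for s, e in zip(run_starts, run_ends):
            if merged and s - merged[-1][1] < merge_gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        for s, e in merged:
            if e - s >= min_length:
                rows.append((chrom, int(s), int(e), None))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return RegionSet("peak", df, genome)


def build_nucleosome_map(
    pooled_fragments, regions: RegionSet, config: NPSConfig = NPSConfig()
) -> dict[str, np.ndarray]:
    """Fixed nucleosome centers per region from pooled development fragments.

    The map is frozen once (from samples excluded from all later training)
    so feature identity is constant across the cohort.
    """
    nmap = {}
    for region in regions:
        region_id = f"{region.chrom}:{region.start}-{region.end}"
        profile = compute_nps_profile(pooled_fragments, region, config)
        if profile.undefined or profile.smoothed is None:
            nmap[region_id] = np.array([], dtype=np.int64)
        else:
            nmap[region_id] = call_nucleosomes(profile, config)
    return nmap


def sample_nps_features(
    fragments, regions: RegionSet, nucleosome_map: dict, config: NPSConfig = NPSConfig()
) -> pd.Series:
    """One sample's NPS feature row against a fixed nucleosome map.

    Regions undefined for the sample contribute NA values (imputed later by
    training-set feature medians).
    """
    parts = []
    for region in regions:
        region_id = f"{region.chrom}:{region.start}-{region.end}"
        centers = nucleosome_map.get(region_id, np.array([], dtype=np.int64))
        if len(centers) < 2:
            continue
        profile = compute_nps_profile(fragments, region, config)
        parts.append(nps_features(profile, centers, config))
    return pd.concat(parts) if parts else pd.Series(dtype=float)


def map_schema_hash(nucleosome_map: dict) -> str:
    payload = json.dumps({k: np.asarray(v).tolist() for k, v in sorted(nucleosome_map.items())})
    return hashlib.md5(payload.encode()).hexdigest()
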