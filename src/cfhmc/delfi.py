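"""Region-based cfDNA fragmentomics features (DELFI-like).

The genome is tiled into 100 kb bins (bins touching blacklisted regions or
assembly gaps are dropped whole, nonstandard chromosomes excluded), fragments
are size-filtered to 100-220 nt and classified as short (100-150 nt) or long
(151-220 nt) by midpoint bin, and the four per-bin metrics (short count, long
count, short/long ratio, total) are averaged into non-overlapping 5 Mb tiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import LibraryFragments, RegionSet
from .hmc import region_counts

__all__ = ["make_bins", "bin_fragment_profile", "aggregate_5mb", "delfi_features"]

SIZE_MIN, SIZE_MAX = 100, 220
SHORT_MAX = 150  # short: [100, 150]; long: [151, 220]

METRICS = ("n_short", "n_long", "n_total", "short_long_ratio")


def make_bins(
    genome: dict[str, int],
    blacklist: RegionSet | None = None,
    gaps: RegionSet | None = None,
    bin_bp: int = 100_000,
    chroms: list[str] | None = None,
) -> RegionSet:
    """Tile standard chromosomes into fixed-size bins, dropping masked ones.

    Only full-length bins are kept; a bin overlapping the blacklist or a gap
    by any amount is removed entirely.
    """
    if bin_bp <= 0:
        raise ValueError("bin size must be positive")
    if chroms is None:
        chroms = list(genome)
    rows = []
    for chrom in chroms:
        length = genome[chrom]
        for s in range(0, length - bin_bp + 1, bin_bp):
            rows.append((chrom, s, s + bin_bp, None))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    mask = np.ones(len(df), dtype=bool)
    for rs in (blacklist, gaps):
        if rs is None or not len(rs):
            continue
        for row in rs.df.itertuples(index=False):
            hit = (df["chrom"] == row.chrom) & (df["start"] < row.end) & (df["end"] > row.start)
            mask &= ~hit.to_numpy()
    return RegionSet("bin", df[mask], genome, merge=False)


def bin_fragment_profile(lib: LibraryFragments, bins: RegionSet) -> pd.DataFrame:
    """Per-bin short/long/total counts and short:long ratio for one sample.

    Fragments outside [100, 220] nt are discarded before counting; each
    retained fragment is assigned to the bin containing its midpoint.  The
    ratio is NA in bins with no long fragments.
    """
    lengths = lib.lengths
    keep = (lengths >= SIZE_MIN) & (lengths <= SIZE_MAX)
    short = keep & (lengths <= SHORT_MAX)

    def _counts(mask):
        sub = LibraryFragments(lib.sample_id, lib.library_type, lib.df[mask], max(1, lib.total_mapped_reads))
        return region_counts(sub, bins) if mask.any() else np.zeros(len(bins), dtype=np.int64)

    n_short = _counts(short)
    n_long = _counts(keep & ~short)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_long > 0, n_short / np.maximum(n_long, 1), np.nan)
    out = pd.DataFrame(
        {
            "chrom": bins.df["chrom"].to_numpy(),
            "start": bins.df["start"].to_numpy(),
            "end": bins.df["end"].to_numpy(),
            "n_short": n_short,
            "n_long": n_long,
            "n_total": n_short + n_long,
            "short_long_ratio": ratio,
        }
    )
    out.attrs["sample_id"] = lib.sample_id
    return out


def aggregate_5mb(profile: pd.DataFrame, agg_bp: int = 5_000_000) -> pd.Series:
    """Average the per-100kb metrics into non-overlapping ``agg_bp`` tiles.

    Each metric is the mean over surviving bins in the tile (NA ratios are
    skipped); tiles with no surviving bins yield NA features.  Feature names
    encode the tile coordinates and metric.
    """
    prof = profile.copy()
    prof["tile_start"] = (prof["start"] // agg_bp) * agg_bp
    grouped = prof.groupby(["chrom", "tile_start"], sort=True)
    values, names = [], []
    for (chrom, ts), sub in grouped:
        for metric in METRICS:
            names.append(f"{chrom}:{ts}-{ts + agg_bp}|{metric}")
            col = sub[metric]
            values.append(float(col.mean()) if col.notna().any() else np.nan)
    return pd.Series(values, index=names, name=profile.attrs.get("sample_id"))


def delfi_features(lib: LibraryFragments, bins: RegionSet, agg_bp: int = 5_000_000) -> pd.Series:
    """One sample's aggregated fragmentomics feature row."""
    return aggregate_5mb(bin_fragment_profile(lib, bins), agg_bp=agg_bp)
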