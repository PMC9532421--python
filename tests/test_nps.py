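import numpy as np
import pandas as pd
import pytest

from cfhmc.io import GenomicInterval
from cfhmc.nps import (
    NPSConfig,
    NPSProfile,
    call_nucleosomes,
    compute_nps_profile,
    impute_profile,
    nps_features,
    pooled_nps,
    select_nps_regions,
    smooth_profile,
    window_counts,
)

from conftest import make_regions, random_fragments_near

CFG = NPSConfig()


# ---------------------------------------------------------------------------
# independent straight-line oracle (shared with the acceptance suite)
# ---------------------------------------------------------------------------


def oracle_window_counts(frags: pd.DataFrame, region: GenomicInterval, cfg: NPSConfig):
    half = (cfg.window - 1) // 2
    lengths = frags["end"] - frags["start"]
    f = frags[
        (frags["chrom"] == region.chrom) & (lengths >= cfg.size_min) & (lengths <= cfg.size_max)
    ]
    s = f["start"].to_numpy()
    e = f["end"].to_numpy()
    n_span = np.empty(len(region), dtype=np.int64)
    n_within = np.empty(len(region), dtype=np.int64)
    for j, i in enumerate(range(region.start, region.end)):
        lo, hi = i - half, i + half
        n_span[j] = int(np.sum((s <= lo) & (e >= hi + 1)))
        in1 = (s >= lo) & (s <= hi)
        in2 = (e - 1 >= lo) & (e - 1 <= hi)
        n_within[j] = int(np.sum(in1 | in2))
    return n_span, n_within


def oracle_pool(n_span, n_within, cfg: NPSConfig):
    L = len(n_span)
    r = cfg.pool_radius
    vals = np.full(L, np.nan)
    for i in range(L):
        lo, hi = max(0, i - r), min(L, i + r + 1)
        den = n_within[lo:hi].sum()
        if den > 0:
            vals[i] = n_span[lo:hi].sum() / den
    return vals


def oracle_impute(vals):
    L = len(vals)
    out = vals.copy()
    defined = np.flatnonzero(~np.isnan(vals))
    for i in range(L):
        if not np.isnan(vals[i]):
            continue
        left = defined[defined < i]
        right = defined[defined > i]
        if len(left) and len(right):
            l, r = left[-1], right[0]
            out[i] = vals[l] + (vals[r] - vals[l]) * (i - l) / (r - l)
        elif len(left):
            out[i] = vals[left[-1]]
        else:
            out[i] = vals[right[0]]
    return out


def _quad_fit_eval(x, y, at):
    # direct least-squares quadratic via the normal equations
    A = np.vander(x.astype(float), 3, increasing=True)
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    return coef[0] + coef[1] * at + coef[2] * at**2


def oracle_smooth(vals, cfg: NPSConfig):
    L = len(vals)
    w = cfg.sg_window
    half = (w - 1) // 2
    out = np.empty(L)
    x = np.arange(w, dtype=float)
    for i in range(half, L - half):
        out[i] = _quad_fit_eval(x, vals[i - half : i + half + 1], float(half))
    # edges: one polynomial per terminal window, evaluated inside it
    for i in range(half):
        out[i] = _quad_fit_eval(x, vals[:w], float(i))
        out[L - 1 - i] = _quad_fit_eval(x, vals[L - w :], float(w - 1 - i))
    return out


def oracle_call(vals, region_start, cfg: NPSConfig):
    L = len(vals)
    half = (cfg.call_window - 1) // 2
    cand = [
        i for i in range(L) if vals[i] >= vals[max(0, i - half) : min(L, i + half + 1)].max()
    ]
    centers = []
    chain = [cand[0]] if cand else []
    for i in cand[1:]:
        if i - chain[-1] <= cfg.merge_distance:
            chain.append(i)
        else:
            centers.append(int(np.floor((chain[0] + chain[-1]) / 2 + 0.5)))
            chain = [i]
    if chain:
        centers.append(int(np.floor((chain[0] + chain[-1]) / 2 + 0.5)))
    return [c + region_start for c in centers]


def oracle_features(vals, centers, region, cfg: NPSConfig):
    feats = []
    for c1, c2 in zip(centers[:-1], centers[1:]):
        if c2 - c1 > cfg.pair_gap:
            continue
        m = int(np.floor((c1 + c2) / 2 + 0.5))
        lo = max(region.start, m - cfg.feature_radius)
        hi = min(region.end, m + cfg.feature_radius + 1)
        feats.append(vals[lo - region.start : hi - region.start].min())
    return np.array(feats)


def oracle_full_chain(frags, region, cfg: NPSConfig):
    """End-to-end independent NPS implementation."""
    n_span, n_within = oracle_window_counts(frags, region, cfg)
    pooled = oracle_pool(n_span, n_within, cfg)
    na_frac = np.isnan(pooled).mean()
    if na_frac > cfg.na_threshold or np.isnan(pooled).all():
        return None
    imputed = oracle_impute(pooled)
    if len(imputed) < cfg.sg_window:
        return None
    smoothed = oracle_smooth(imputed, cfg)
    centers = oracle_call(smoothed, region.start, cfg)
    return smoothed, centers, oracle_features(smoothed, centers, region, cfg)


# ---------------------------------------------------------------------------
# unit tests
# ---------------------------------------------------------------------------


def test_window_counts_hand_example():
    # fragment [0, 250): at i=125 the window is [65, 185]; the fragment covers
    # it entirely (span) but neither endpoint (0, 249) falls inside (within=0)
    frags = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [250]})
    region = GenomicInterval("chr1", 100, 300)
    counts = window_counts(frags, region, CFG)
    j = 125 - region.start
    assert counts.n_span[j] == 1
    assert counts.n_within[j] == 0


def test_window_counts_empty_and_short_region():
    frags = pd.DataFrame({"chrom": [], "start": [], "end": []})
    region = GenomicInterval("chr1", 0, 300)
    counts = window_counts(frags, region, CFG)
    assert counts.n_span.sum() == 0 and counts.n_within.sum() == 0
    with pytest.raises(ValueError, match="shorter"):
        window_counts(frags, GenomicInterval("chr1", 0, 100), CFG)


@pytest.mark.parametrize("seed", range(5))
def test_window_counts_against_bruteforce(seed):
    rng = np.random.default_rng(seed)
    region = GenomicInterval("chr1", 5_000, 5_000 + int(rng.integers(200, 900)))
    frags = random_fragments_near(rng, "chr1", 4_500, 6_000, n=120, size_lo=100, size_hi=300)
    counts = window_counts(frags, region, CFG)
    n_span, n_within = oracle_window_counts(frags, region, CFG)
    np.testing.assert_array_equal(counts.n_span, n_span)
    np.testing.assert_array_equal(counts.n_within, n_within)


def test_pooled_nps_is_ratio_of_sums():
    region = GenomicInterval("chr1", 0, 200)
    counts = type("C", (), {})()
    rng = np.random.default_rng(1)
    n_span = rng.integers(0, 4, size=200)
    n_within = rng.integers(0, 3, size=200)
    from cfhmc.nps import NPSWindowCounts

    prof = pooled_nps(NPSWindowCounts(region, n_span, n_within), CFG)
    expected = oracle_pool(n_span, n_within, CFG)
    np.testing.assert_allclose(prof.pooled, expected, equal_nan=True)
    # constant counts give a constant ratio in the interior
    prof2 = pooled_nps(NPSWindowCounts(region, np.full(200, 2), np.ones(200, dtype=int)), CFG)
    assert np.allclose(prof2.pooled, 2.0)
    # all-zero denominator -> fully NA, region undefined
    prof3 = pooled_nps(NPSWindowCounts(region, np.ones(200, dtype=int), np.zeros(200, dtype=int)), CFG)
    assert prof3.na_mask.all() and prof3.undefined


@pytest.mark.parametrize(
    "values, expected",
    [
        ([1.0, np.nan, 3.0], [1.0, 2.0, 3.0]),
        ([np.nan, np.nan, 5.0, 7.0], [5.0, 5.0, 5.0, 7.0]),
        ([1.0, np.nan, np.nan, 7.0, np.nan], [1.0, 3.0, 5.0, 7.0, 7.0]),
    ],
)
def test_impute_examples(values, expected):
    vals = np.array(values)
    prof = NPSProfile(GenomicInterval("chr1", 0, len(vals)), vals, np.isnan(vals))
    np.testing.assert_allclose(impute_profile(prof).imputed, expected)


@pytest.mark.parametrize("seed", range(4))
def test_impute_against_piecewise_linear_oracle(seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=400)
    vals[rng.random(400) < 0.3] = np.nan
    if np.isnan(vals).all():
        vals[0] = 1.0
    prof = NPSProfile(GenomicInterval("chr1", 0, 400), vals.copy(), np.isnan(vals))
    np.testing.assert_allclose(impute_profile(prof).imputed, oracle_impute(vals), atol=1e-10)


def test_smoothing_reproduces_quadratics_and_constants():
    x = np.arange(400, dtype=float)
    quad = 0.5 + 0.01 * x - 3e-5 * x**2
    prof = NPSProfile(GenomicInterval("chr1", 0, 400), quad, np.zeros(400, bool), imputed=quad)
    sm = smooth_profile(prof, CFG).smoothed
    np.testing.assert_allclose(sm, quad, atol=1e-8)  # degree-2 exactness
    const = np.full(400, 3.0)
    prof2 = NPSProfile(GenomicInterval("chr1", 0, 400), const, np.zeros(400, bool), imputed=const)
    np.testing.assert_allclose(smooth_profile(prof2, CFG).smoothed, 3.0)


def test_smoothing_against_direct_least_squares():
    rng = np.random.default_rng(9)
    vals = rng.normal(size=500).cumsum()
    prof = NPSProfile(GenomicInterval("chr1", 0, 500), vals, np.zeros(500, bool), imputed=vals)
    sm = smooth_profile(prof, CFG).smoothed
    np.testing.assert_allclose(sm, oracle_smooth(vals, CFG), atol=1e-9)


def test_call_nucleosomes_two_isolated_peaks():
    L = 600
    x = np.arange(L, dtype=float)
    # two smooth bumps 200 bp apart, strictly monotone tails
    vals = np.exp(-((x - 200) / 50.0) ** 2) + np.exp(-((x - 400) / 50.0) ** 2)
    prof = NPSProfile(GenomicInterval("chr1", 0, L), vals, np.zeros(L, bool), imputed=vals, smoothed=vals)
    assert list(call_nucleosomes(prof, CFG)) == [200, 400]


def test_call_nucleosomes_merges_close_maxima_to_midpoint():
    L = 650
    x = np.arange(L, dtype=float)
    # two equal sharp maxima 50 bp apart on a strictly concave background
    tent = lambda c: np.clip(1.0 - np.abs(x - c) / 10.0, 0.0, None)
    vals = np.maximum(tent(300), tent(350)) - 1e-8 * (x - 325.0) ** 2
    prof = NPSProfile(GenomicInterval("chr1", 0, L), vals, np.zeros(L, bool), imputed=vals, smoothed=vals)
    assert list(call_nucleosomes(prof, CFG)) == [325]


def test_call_nucleosomes_flat_profile_single_center():
    L = 600
    vals = np.ones(L)
    prof = NPSProfile(GenomicInterval("chr1", 0, L), vals, np.zeros(L, bool), imputed=vals, smoothed=vals)
    with pytest.warns(UserWarning, match="flat"):
        centers = call_nucleosomes(prof, CFG)
    assert len(centers) == 1


def test_nps_features_gap_rule_and_valley():
    L = 1200
    x = np.arange(L, dtype=float)
    # V-shaped valley between nucleosomes at 400 and 600
    vals = np.abs(x - 500) / 100.0
    region = GenomicInterval("chr1", 0, L)
    prof = NPSProfile(region, vals, np.zeros(L, bool), imputed=vals, smoothed=vals)
    feats = nps_features(prof, np.array([400, 600]), CFG)
    assert len(feats) == 1
    assert feats.iloc[0] == pytest.approx(0.0)  # valley floor
    # pair 350 bp apart yields no feature
    assert len(nps_features(prof, np.array([400, 750]), CFG)) == 0


def test_depth_independence():
    """Exact k-fold duplication of the fragment set leaves pooled NPS unchanged."""
    rng = np.random.default_rng(17)
    region = GenomicInterval("chr1", 2_000, 3_500)
    frags = random_fragments_near(rng, "chr1", 1_500, 3_800, n=150, size_lo=120, size_hi=250)
    p1 = compute_nps_profile(frags, region, CFG)
    p3 = compute_nps_profile(pd.concat([frags] * 3, ignore_index=True), region, CFG)
    np.testing.assert_allclose(p1.pooled, p3.pooled, equal_nan=True)
    np.testing.assert_allclose(p1.smoothed, p3.smoothed)


@pytest.mark.parametrize("seed", range(8))
def test_full_chain_matches_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    L = int(rng.integers(300, 2000))
    start = int(rng.integers(0, 5_000))
    region = GenomicInterval("chr1", start, start + L)
    n = int(rng.integers(20, 200))
    frags = random_fragments_near(rng, "chr1", max(0, start - 400), start + L + 400, n=n, size_lo=100, size_hi=300)
    expected = oracle_full_chain(frags, region, CFG)
    prof = compute_nps_profile(frags, region, CFG)
    if expected is None:
        assert prof.undefined or prof.smoothed is None
        return
    smoothed, _, _ = expected
    np.testing.assert_allclose(prof.smoothed, smoothed, atol=1e-9)
    # downstream oracle on the verified smoothed array (float-tie safe)
    centers = oracle_call(prof.smoothed, region.start, CFG)
    got_centers = call_nucleosomes(prof, CFG)
    assert list(got_centers) == centers
    got_feats = nps_features(prof, got_centers, CFG).to_numpy()
    np.testing.assert_allclose(got_feats, oracle_features(prof.smoothed, centers, region, CFG), atol=1e-9)


def test_select_regions_ranking_and_ties():
    genome = {"chr1": 100_000}
    candidates = make_regions(
        "peak", [("chr1", 0, 1000), ("chr1", 2000, 3000), ("chr1", 4000, 5000)], genome
    )
    cov = pd.DataFrame({"s1": [5.0, 9.0, 5.0], "s2": [5.0, 9.0, 5.0]})
    top1 = select_nps_regions(cov, candidates, k=1)
    assert top1.df.iloc[0]["start"] == 2000  # clearly deepest region wins
    # tie at rank k broken by (chrom, start) order
    top2 = select_nps_regions(cov, candidates, k=2)
    assert list(top2.df["start"]) == [0, 2000]
    with pytest.warns(UserWarning, match="candidate regions"):
        all3 = select_nps_regions(cov, candidates, k=5)
    assert len(all3) == 3


@pytest.mark.parametrize("seed", range(3))
def test_select_regions_against_sort_oracle(seed):
    genome = {"chr1": 1_000_000}
    rng = np.random.default_rng(seed)
    rows = [("chr1", int(s), int(s + 500)) for s in np.arange(0, 40_000, 1000)]
    candidates = make_regions("peak", rows, genome, merge=False)
    cov = pd.DataFrame(rng.normal(10, 3, size=(len(rows), 5)))
    k = 7
    selected = select_nps_regions(cov, candidates, k=k)
    med = np.median(cov.to_numpy(), axis=1)
    # oracle: stable sort on (-median, start)
    order = sorted(range(len(rows)), key=lambda i: (-med[i], rows[i][1]))[:k]
    expected_starts = sorted(rows[i][1] for i in order)
    assert list(selected.df["start"]) == expected_starts
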