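import numpy as np
import pandas as pd
import pytest

from cfhmc.io import LibraryFragments, RegionSet


def make_regions(label, rows, genome, merge=True):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return RegionSet(label, df, genome, merge=merge)


def make_fragments(rows, sample_id="s1", library_type="input", total=None):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return LibraryFragments(sample_id, library_type, df, total if total is not None else 2 * len(df))


@pytest.fixture
def genome():
    return {"chr1": 1_000_000, "chr2": 500_000}


@pytest.fixture
def tiny_sim_config():
    from cfhmc.simulate import SimulationConfig

    return SimulationConfig(
        seed=5,
        n_per_class=3,
        n_chroms=1,
        chrom_length=2_000_000,
        n_enhancers=50,
        fragments_per_library=4_000,
        blacklist_per_chrom=1,
        blacklist_bp=20_000,
        gap_bp=30_000,
    )


def random_fragments_near(rng, region_chrom, lo, hi, n, size_lo=60, size_hi=320):
    """Random fragment table overlapping a window (for NPS/DELFI oracles)."""
    starts = rng.integers(lo, hi, size=n)
    lengths = rng.integers(size_lo, size_hi, size=n)
    return pd.DataFrame({"chrom": region_chrom, "start": starts, "end": starts + lengths})
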