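"""Seeded synthetic cfDNA cohort generator.

Emulates the statistical structure the analysis assumes, at desk scale:

* input libraries: fragment midpoints uniform over the non-blacklisted
  genome; fragment sizes a two-component normal mixture (mononucleosomal
  mode ~166 bp; a shorter tumor mode ~145 bp whose mixture weight is the
  sample's tumor fraction);
* hydroxymethylome ("pulldown") libraries: fragment midpoints drawn
  per-region with weight proportional to ``2**enrichment``, where each
  enhancer's log2 enrichment is Normal(mu0 + delta * [case & affected],
  sigma0) per sample, genic background is weighted so pulldown reads
  concentrate in genic regions (ratio ~1.8), and intergenic background has
  unit weight;
* spike-ins: Poisson counts per species, with pulldown means scaled by the
  expected enrichment fold (88/267/658 for the 1/3/6-hmC positive controls,
  1 and 0.38 for the 5mC and unmodified negative controls);
* covariates: age, sex, ethnicity, vendor, batch and lifestyle/medication
  flags, optionally confounded with class via a single coefficient.

Every random draw is keyed by ``(seed, sample_id, stream)`` so cohorts are
order-independent and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    LibraryFragments,
    RegionSet,
    SampleRecord,
    SpikeInCounts,
    SPIKE_SPECIES,
    write_fragments,
    write_genome,
    write_metadata,
    write_regions,
    write_spikein,
)

__all__ = ["SimulationConfig", "CohortSimulator", "make_genome", "simulate_cohort"]

# Expected pulldown/input enrichment folds for the five spike-in species.
DEFAULT_SPIKE_FOLDS = {"hmC1": 88.0, "hmC3": 267.0, "hmC6": 658.0, "mC6": 1.0, "C0": 0.38}

_STREAM_GENOME = 0
_STREAM_COVARIATES = 1
_STREAM_ENRICHMENT = 2
_STREAM_INPUT = 3
_STREAM_PULLDOWN = 4
_STREAM_SPIKE = 5


@dataclass
class SimulationConfig:
    """Desk-scale cohort simulation parameters (all randomness from ``seed``)."""

    seed: int = 0
    # cohort layout
    n_per_class: int = 50
    n_validation_per_class: int = 0
    n_dev_per_class: int = 0
    classes: tuple = ("control", "CRC")
    # genome
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    genic_block_bp: int = 500_000
    n_enhancers: int = 500
    enhancer_length: int = 1_000
    blacklist_per_chrom: int = 2
    blacklist_bp: int = 50_000
    gap_bp: int = 100_000
    peak_pad_bp: int = 250
    # 5hmC enrichment model (log2 scale)
    affected_fraction: float = 0.1
    effect_size: float = 0.9  # delta: case-vs-control shift on affected enhancers
    mu0: float = 2.0  # baseline enhancer log2 enrichment
    sigma0: float = 0.5  # between-sample enhancer dispersion
    genic_weight: float = 1.8  # per-bp pulldown weight of genic background
    # fragment-size model
    control_mode: float = 166.0
    control_sd: float = 10.0
    tumor_mode: float = 145.0
    tumor_sd: float = 10.0
    tumor_fraction: float = 0.1  # short-component weight in cancer samples
    fragments_per_library: int = 50_000
    # spike-ins
    spike_base_count: int = 500
    spike_folds: dict = field(default_factory=lambda: dict(DEFAULT_SPIKE_FOLDS))
    # covariates
    confound_coef: float = 0.0
    stage_probs: tuple = (0.2, 0.4, 0.3, 0.1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for name in ("chrom_length", "enhancer_length", "fragments_per_library"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.affected_fraction <= 1.0):
            raise ValueError("affected_fraction must be in [0, 1]")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _rng(seed: int, sample_id: str, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode()), stream])


def _subtract(intervals: list[tuple[int, int]], cuts: list[tuple[int, int]]):
    """Subtract sorted disjoint ``cuts`` from sorted disjoint ``intervals``."""
    out = []
    for s, e in intervals:
        cur = s
        for cs, ce in cuts:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                out.append((cur, min(cs, e)))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


class _GenomeBundle:
    """Genome sizes plus all derived RegionSets and the affected-enhancer mask."""

    def __init__(self, genome, regions, affected_mask):
        self.genome = genome
        self.regions = regions  # dict[str, RegionSet]
        self.affected_mask = affected_mask  # bool array over enhancer rows

    @property
    def enhancers(self) -> RegionSet:
        return self.regions["enhancer"]


def make_genome(config: SimulationConfig) -> _GenomeBundle:
    """Build the deterministic synthetic genome and its region sets.

    Genic territory alternates with intergenic in ``genic_block_bp`` blocks;
    enhancers occupy randomly chosen non-overlapping slots inside genic
    blocks; blacklist and gap intervals sit in intergenic blocks; peaks are
    padded enhancers plus every second genic block as a broad domain.
    """
    rng = _rng(config.seed, "__genome__", _STREAM_GENOME)
    genome = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}

    genic, intergenic = {}, {}
    for chrom, length in genome.items():
        blocks = [(s, min(s + config.genic_block_bp, length)) for s in range(0, length, config.genic_block_bp)]
        genic[chrom] = blocks[0::2]
        intergenic[chrom] = blocks[1::2]

    # enhancer slots: fixed grid inside genic blocks, sampled without replacement
    slot_pitch = 3 * config.enhancer_length
    slots = []
    for chrom in genome:
        for bs, be in genic[chrom]:
            for s in range(bs + 1_000, be - config.enhancer_length - 1_000, slot_pitch):
                slots.append((chrom, s))
    if config.n_enhancers > len(slots):
        raise ValueError(
            f"requested {config.n_enhancers} enhancers but genome capacity is {len(slots)}"
        )
    chosen = sorted(rng.choice(len(slots), size=config.n_enhancers, replace=False))
    enh_rows = [
        (slots[i][0], slots[i][1], slots[i][1] + config.enhancer_length, f"enh{k:05d}")
        for k, i in enumerate(chosen)
    ]
    n_affected = int(round(config.affected_fraction * config.n_enhancers))
    affected_mask = np.zeros(config.n_enhancers, dtype=bool)
    if n_affected:
        affected_mask[rng.choice(config.n_enhancers, size=n_affected, replace=False)] = True

    # blacklist + gaps inside intergenic blocks (disjoint from enhancers by construction)
    bl_rows, gap_rows = [], []
    for chrom in genome:
        blocks = intergenic[chrom]
        if not blocks:
            continue
        for j in range(config.blacklist_per_chrom):
            bs, be = blocks[j % len(blocks)]
            start = bs + 10_000 + j * (config.blacklist_bp + 10_000)
            bl_rows.append((chrom, start, min(start + config.blacklist_bp, be), None))
        if config.gap_bp > 0:
            bs, be = blocks[-1]
            gstart = be - config.gap_bp - 10_000
            gap_rows.append((chrom, max(bs, gstart), be - 10_000, None))

    def _rs(label, rows, merge=True):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        return RegionSet(label, df, genome, merge=merge)

    genic_rows = [(c, s, e, None) for c in genome for s, e in genic[c]]
    inter_rows = [(c, s, e, None) for c in genome for s, e in intergenic[c]]
    peak_rows = [
        (c, max(0, s - config.peak_pad_bp), min(genome[c], e + config.peak_pad_bp), None)
        for c, s, e, _ in enh_rows
    ]
    # broad peak domains: every second genic block
    for chrom in genome:
        for bs, be in genic[chrom][0::2]:
            peak_rows.append((chrom, bs, be, None))

    regions = {
        "enhancer": _rs("enhancer", enh_rows, merge=False),
        "genic": _rs("genic", genic_rows),
        "intergenic": _rs("intergenic", inter_rows),
        "blacklist": _rs("blacklist", bl_rows) if bl_rows else _rs("blacklist", []),
        "gap": _rs("gap", gap_rows) if gap_rows else _rs("gap", []),
        "peak": _rs("peak", peak_rows),
    }
    return _GenomeBundle(genome, regions, affected_mask)


class CohortSimulator:
    """Lazy cohort simulator: genome and metadata up front, fragments on demand.

    Fragment tables for a full cohort are large, so samples are drawn one at
    a time via :meth:`sample` and can be discarded after feature extraction.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.bundle = make_genome(config)
        self.records = self._make_records()
        self._territory = self._build_territory()

    # -- metadata -----------------------------------------------------------

    def _make_records(self) -> list[SampleRecord]:
        cfg = self.config
        records = []
        layout = [("train", cfg.n_per_class), ("validation", cfg.n_validation_per_class), ("dev", cfg.n_dev_per_class)]
        for cls in cfg.classes:
            counter = 0
            for split, n in layout:
                for _ in range(n):
                    sample_id = f"{cls}-{counter:04d}"
                    counter += 1
                    records.append(self._make_record(sample_id, cls, split))
        return records

    def _make_record(self, sample_id: str, cls: str, split: str) -> SampleRecord:
        cfg = self.config
        rng = _rng(cfg.seed, sample_id, _STREAM_COVARIATES)
        is_case = cls != "control"
        stage = None
        if cls == "CRC" or cls.startswith("other-cancer:"):
            stage = int(rng.choice([1, 2, 3, 4], p=cfg.stage_probs))
        c = cfg.confound_coef if is_case else 0.0
        covs = {
            "age": float(np.round(rng.normal(64.0 + 5.0 * c, 9.0), 1)),
            "sex": "F" if rng.random() < 0.52 else "M",
            "ethnicity": str(rng.choice(["White", "Asian", "Other"], p=[0.73, 0.11, 0.16])),
            "vendor": str(rng.choice(["V1", "V2", "V3"])),
            "batch": str(rng.choice(["B1", "B2", "B3", "B4"])),
            "smoking": "yes" if rng.random() < min(0.95, 0.20 + 0.10 * c) else "no",
            "diabetes": "yes" if rng.random() < 0.15 else "no",
            "statins": "yes" if rng.random() < 0.30 else "no",
            "nsaids": "yes" if rng.random() < 0.25 else "no",
            "alcohol": "yes" if rng.random() < 0.50 else "no",
        }
        return SampleRecord(sample_id=sample_id, diagnosis=cls, stage=stage, covariates=covs, split=split)

    # -- fragment territory -------------------------------------------------

    def _build_territory(self):
        """Disjoint weighted intervals for pulldown sampling and the uniform
        non-blacklist territory for input sampling."""
        regs = self.bundle.regions
        genome = self.bundle.genome
        excluded = {}
        excl_df = pd.concat([regs["blacklist"].df, regs["gap"].df], ignore_index=True)
        for chrom in genome:
            sub = excl_df[excl_df["chrom"] == chrom].sort_values("start")
            excluded[chrom] = list(zip(sub["start"], sub["end"]))

        # input: uniform over genome minus blacklist/gaps
        input_iv = []
        for chrom, length in genome.items():
            for s, e in _subtract([(0, length)], excluded[chrom]):
                input_iv.append((chrom, s, e))

        # pulldown partition: enhancers / genic-minus-enhancers / clean intergenic
        enh = regs["enhancer"].df
        pull_iv, pull_kind = [], []  # kind: enhancer row index or -1 genic, -2 intergenic
        for chrom in genome:
            esub = enh[enh["chrom"] == chrom]
            cuts = list(zip(esub["start"], esub["end"]))
            gsub = regs["genic"].df[regs["genic"].df["chrom"] == chrom]
            for s, e in _subtract(list(zip(gsub["start"], gsub["end"])), cuts):
                pull_iv.append((chrom, s, e))
                pull_kind.append(-1)
            isub = regs["intergenic"].df[regs["intergenic"].df["chrom"] == chrom]
            for s, e in _subtract(list(zip(isub["start"], isub["end"])), excluded[chrom]):
                pull_iv.append((chrom, s, e))
                pull_kind.append(-2)
        for idx, row in enumerate(enh.itertuples(index=False)):
            pull_iv.append((row.chrom, int(row.start), int(row.end)))
            pull_kind.append(idx)
        return {
            "input": input_iv,
            "pull_iv": pull_iv,
            "pull_kind": np.array(pull_kind),
            "pull_len": np.array([e - s for _, s, e in pull_iv], dtype=float),
        }

    # -- per-sample draws ---------------------------------------------------

    def latent_enrichment(self, record: SampleRecord) -> np.ndarray:
        """The sample's true per-enhancer log2 enrichment vector."""
        cfg = self.config
        rng = _rng(cfg.seed, record.sample_id, _STREAM_ENRICHMENT)
        e = cfg.mu0 + rng.normal(0.0, cfg.sigma0, size=cfg.n_enhancers)
        if record.is_cancer:
            e = e + cfg.effect_size * self.bundle.affected_mask
        return e

    def _tumor_fraction(self, record: SampleRecord) -> float:
        return self.config.tumor_fraction if record.is_cancer else 0.0

    def _draw_lengths(self, rng, n, tf):
        cfg = self.config
        tumor = rng.random(n) < tf
        lengths = np.where(
            tumor,
            rng.normal(cfg.tumor_mode, cfg.tumor_sd, n),
            rng.normal(cfg.control_mode, cfg.control_sd, n),
        )
        return np.clip(np.rint(lengths), 60, 500).astype(np.int64)

    def _positions_to_frame(self, chroms, mids, lengths):
        genome = self.bundle.genome
        starts = mids - lengths // 2
        starts = np.maximum(starts, 0)
        limits = np.array([genome[c] for c in chroms])
        starts = np.minimum(starts, limits - lengths)
        return pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + lengths})

    def _uniform_positions(self, rng, intervals, n):
        lens = np.array([e - s for _, s, e in intervals], dtype=float)
        cum = np.cumsum(lens)
        u = rng.random(n) * cum[-1]
        idx = np.searchsorted(cum, u, side="right")
        offset = (u - (cum[idx] - lens[idx])).astype(np.int64)
        chroms = np.array([intervals[i][0] for i in idx])
        mids = np.array([intervals[i][1] for i in idx], dtype=np.int64) + offset
        return chroms, mids

    def sample(self, record: SampleRecord):
        """Simulate one sample: (input library, pulldown library, spike counts).

        Spike counts are returned as ``{"input": SpikeInCounts, "pulldown":
        SpikeInCounts}``.
        """
        cfg = self.config
        tf = self._tumor_fraction(record)
        n = cfg.fragments_per_library

        rng_in = _rng(cfg.seed, record.sample_id, _STREAM_INPUT)
        chroms, mids = self._uniform_positions(rng_in, self._territory["input"], n)
        lengths = self._draw_lengths(rng_in, n, tf)
        input_lib = LibraryFragments(
            record.sample_id, "input", self._positions_to_frame(chroms, mids, lengths), 2 * n
        )

        rng_pd = _rng(cfg.seed, record.sample_id, _STREAM_PULLDOWN)
        e = self.latent_enrichment(record)
        kind = self._territory["pull_kind"]
        per_bp = np.where(kind == -1, cfg.genic_weight, 1.0)
        enh_rows = kind >= 0
        per_bp = per_bp.astype(float)
        per_bp[enh_rows] = 2.0 ** e[kind[enh_rows]]
        weights = per_bp * self._territory["pull_len"]
        counts = rng_pd.multinomial(n, weights / weights.sum())
        iv = self._territory["pull_iv"]
        chrom_list, mid_list = [], []
        for i in np.nonzero(counts)[0]:
            c, s, eiv = iv[i]
            k = counts[i]
            chrom_list.append(np.repeat(c, k))
            mid_list.append(rng_pd.integers(s, eiv, size=k))
        chroms = np.concatenate(chrom_list)
        mids = np.concatenate(mid_list).astype(np.int64)
        perm = rng_pd.permutation(n)
        lengths = self._draw_lengths(rng_pd, n, tf)
        pull_lib = LibraryFragments(
            record.sample_id,
            "pulldown",
            self._positions_to_frame(chroms[perm], mids[perm], lengths),
            2 * n,
        )

        rng_sp = _rng(cfg.seed, record.sample_id, _STREAM_SPIKE)
        base = cfg.spike_base_count
        spike_in = SpikeInCounts({sp: int(rng_sp.poisson(base)) for sp in SPIKE_SPECIES})
        spike_pull = SpikeInCounts(
            {sp: int(rng_sp.poisson(base * cfg.spike_folds[sp])) for sp in SPIKE_SPECIES}
        )
        return input_lib, pull_lib, {"input": spike_in, "pulldown": spike_pull}


def simulate_cohort(config: SimulationConfig, outdir=None):
    """Simulate a full cohort; optionally write every io format to ``outdir``.

    Returns the :class:`CohortSimulator` (fragments are drawn lazily).  When
    ``outdir`` is given, writes genome/region/fragment/spike-in/metadata
    files plus a manifest recording the seed and config hash.
    """
    sim = CohortSimulator(config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome(sim.bundle.genome, outdir / "genome.tsv")
        for label, rs in sim.bundle.regions.items():
            if len(rs):
                write_regions(rs, outdir / f"{label}.bed")
        write_metadata(sim.records, outdir / "metadata.tsv")
        spikes = {}
        fragdir = outdir / "fragments"
        fragdir.mkdir(exist_ok=True)
        for rec in sim.records:
            input_lib, pull_lib, spike = sim.sample(rec)
            write_fragments(input_lib, fragdir / f"{rec.sample_id}.input.bed")
            write_fragments(pull_lib, fragdir / f"{rec.sample_id}.pulldown.bed")
            spikes[(rec.sample_id, "input")] = spike["input"]
            spikes[(rec.sample_id, "pulldown")] = spike["pulldown"]
        write_spikein(spikes, outdir / "spikein.tsv")
        manifest = {
            "seed": config.seed,
            "config_hash": config.content_hash(),
            "n_samples": len(sim.records),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return sim
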