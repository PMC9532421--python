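"""Readers/writers for on-disk formats and the shared genomic data model.

All coordinates are 0-based half-open (BED convention) throughout the
package; strand is ignored (cfDNA fragments are double-stranded).  Region
files are plain 3/4-column BED, fragment files are 3-column BED-like,
tabular inputs (metadata, spike-ins, chromosome sizes, feature matrices)
are TSV with a header row and ``NA`` for missing values.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "LibraryFragments",
    "SampleRecord",
    "SpikeInCounts",
    "SPIKE_SPECIES",
    "COVARIATE_KEYS",
    "read_genome",
    "write_genome",
    "read_regions",
    "write_regions",
    "read_fragments",
    "write_fragments",
    "read_metadata",
    "write_metadata",
    "read_spikein",
    "write_spikein",
    "read_feature_matrix",
    "write_feature_matrix",
]

SPIKE_SPECIES = ("hmC1", "hmC3", "hmC6", "mC6", "C0")

COVARIATE_KEYS = (
    "age",
    "sex",
    "ethnicity",
    "vendor",
    "batch",
    "smoking",
    "diabetes",
    "statins",
    "nsaids",
    "alcohol",
)

REGION_LABELS = ("enhancer", "genic", "intergenic", "peak", "blacklist", "bin", "gap")

_CANCER_DIAGNOSES_PREFIX = "other-cancer:"
_STAGED_DIAGNOSES = ("CRC",)


class BedParseError(ValueError):
    """Malformed BED/TSV content (reported with a line number)."""


class SchemaError(ValueError):
    """A tabular input violates the declared schema."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _merge_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Sort intervals and merge strictly overlapping ones per chromosome.

    Abutting half-open intervals ([0,100) and [100,200)) are kept separate.
    """
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    out_rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        names = sub["name"].to_numpy()
        cur_s, cur_e, cur_n = starts[0], ends[0], names[0]
        for s, e, n in zip(starts[1:], ends[1:], names[1:]):
            if s < cur_e:  # strict overlap; abutting (s == cur_e) not merged
                cur_e = max(cur_e, e)
            else:
                out_rows.append((chrom, cur_s, cur_e, cur_n))
                cur_s, cur_e, cur_n = s, e, n
        out_rows.append((chrom, cur_s, cur_e, cur_n))
    return pd.DataFrame(out_rows, columns=["chrom", "start", "end", "name"])


class RegionSet:
    """Named, sorted, within-label non-overlapping genomic intervals.

    Parameters
    ----------
    label : str
        Role tag (enhancer | genic | intergenic | peak | blacklist | bin | gap).
    df : pandas.DataFrame
        Columns ``chrom``, ``start``, ``end`` and optionally ``name``.
    genome : dict[str, int]
        Chromosome-size map; every interval must lie within its chromosome.
    merge : bool
        Merge strictly overlapping intervals (default True).
    """

    def __init__(self, label: str, df: pd.DataFrame, genome: dict[str, int], merge: bool = True):
        if label not in REGION_LABELS:
            raise ValueError(f"unknown region label {label!r}")
        self.label = label
        self.genome = dict(genome)
        df = df.copy()
        if "name" not in df.columns:
            df["name"] = None
        df = df[["chrom", "start", "end", "name"]]
        if len(df):
            if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
                raise ValueError("invalid interval coordinates (need 0 <= start < end)")
            for chrom, sub in df.groupby("chrom"):
                if chrom not in self.genome:
                    raise ValueError(f"interval on unknown chromosome {chrom!r}")
                if int(sub["end"].max()) > self.genome[chrom]:
                    raise ValueError(
                        f"interval beyond end of {chrom} (length {self.genome[chrom]})"
                    )
            if merge:
                df = _merge_frame(df)
            else:
                df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)
        self.df["start"] = self.df["start"].astype(np.int64)
        self.df["end"] = self.df["end"].astype(np.int64)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), row.name)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def total_bp(self) -> int:
        return int(self.lengths.sum())

    def region_ids(self) -> list[str]:
        """Stable per-interval identifiers ``chrom:start-end``."""
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.df["chrom"], self.df["start"], self.df["end"])]

    def subset(self, mask) -> "RegionSet":
        return RegionSet(self.label, self.df[np.asarray(mask)], self.genome, merge=False)


@dataclass
class LibraryFragments:
    """One sample's mapped fragments for one library type.

    ``total_mapped_reads`` is the read count used as the RPKM denominator;
    by the paired-end convention each stored fragment represents 2 reads.
    """

    sample_id: str
    library_type: str  # "input" | "pulldown"
    df: pd.DataFrame  # columns chrom, start, end
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.library_type not in ("input", "pulldown"):
            raise ValueError(f"library_type must be input|pulldown, got {self.library_type!r}")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be > 0")
        self.df = self.df[["chrom", "start", "end"]].reset_index(drop=True)

    @property
    def n_fragments(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()


@dataclass
class SampleRecord:
    """Per-sample metadata: diagnosis, stage and the closed covariate set."""

    sample_id: str
    diagnosis: str  # control | CRC | adenoma-nonadvanced | adenoma-advanced | other-cancer:<site>
    stage: int | None = None
    covariates: dict = field(default_factory=dict)
    split: str = "train"  # train | validation | dev

    def __post_init__(self) -> None:
        if not _valid_diagnosis(self.diagnosis):
            raise SchemaError(f"unknown diagnosis {self.diagnosis!r}")
        staged = self.diagnosis in _STAGED_DIAGNOSES or self.diagnosis.startswith(
            _CANCER_DIAGNOSES_PREFIX
        )
        if staged and self.stage is None:
            raise SchemaError(f"{self.sample_id}: cancer diagnosis requires a stage")
        if not staged and self.stage is not None:
            raise SchemaError(f"{self.sample_id}: stage given for non-cancer diagnosis")
        if self.stage is not None and self.stage not in (1, 2, 3, 4):
            raise SchemaError(f"{self.sample_id}: stage must be 1-4")
        unknown = set(self.covariates) - set(COVARIATE_KEYS)
        if unknown:
            raise SchemaError(f"{self.sample_id}: unknown covariate keys {sorted(unknown)}")

    @property
    def is_cancer(self) -> bool:
        return self.stage is not None


def _valid_diagnosis(d: str) -> bool:
    if d in ("control", "CRC", "adenoma-nonadvanced", "adenoma-advanced"):
        return True
    return d.startswith(_CANCER_DIAGNOSES_PREFIX) and len(d) > len(_CANCER_DIAGNOSES_PREFIX)


@dataclass
class SpikeInCounts:
    """Read counts for the five 166 bp synthetic spike-in species.

    Positive controls carry 1, 3 or 6 5hmC residues; negative controls carry
    6 5mC residues or only unmodified cytosines.
    """

    counts: dict

    def __post_init__(self) -> None:
        missing = set(SPIKE_SPECIES) - set(self.counts)
        if missing:
            raise SchemaError(f"missing spike-in species {sorted(missing)}")
        for sp in SPIKE_SPECIES:
            if self.counts[sp] < 0:
                raise SchemaError(f"negative spike-in count for {sp}")
        self.counts = {sp: int(self.counts[sp]) for sp in SPIKE_SPECIES}

    def __getitem__(self, species: str) -> int:
        return self.counts[species]

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[sp] for sp in SPIKE_SPECIES], dtype=float)


# ---------------------------------------------------------------------------
# genome / region / fragment files
# ---------------------------------------------------------------------------


def read_genome(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` sizes file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    if df.empty:
        raise BedParseError(f"{path}: empty genome file")
    return {str(r.chrom): int(r.length) for r in df.itertuples()}


def write_genome(genome: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def _read_bed3(path, what: str) -> pd.DataFrame:
    rows = []
    text = Path(path).read_text() if not isinstance(path, _io.IOBase) else path.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise BedParseError(f"{what} line {lineno}: expected >=3 columns, got {len(fields)}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"{what} line {lineno}: non-integer coordinates") from exc
        if start < 0:
            raise BedParseError(f"{what} line {lineno}: negative start coordinate")
        if start >= end:
            raise BedParseError(f"{what} line {lineno}: start >= end")
        name = fields[3] if len(fields) > 3 else None
        rows.append((fields[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_regions(path, label: str, genome: dict[str, int]) -> RegionSet:
    """Read a BED file into a validated, sorted, merged-within-label RegionSet."""
    df = _read_bed3(path, what=f"regions[{label}]")
    return RegionSet(label, df, genome)


def write_regions(regions: RegionSet, path) -> None:
    cols = ["chrom", "start", "end"]
    df = regions.df.copy()
    if df["name"].notna().any():
        df["name"] = df["name"].fillna(".")
        cols.append("name")
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_fragments(
    path,
    sample_id: str,
    library_type: str,
    total_mapped_reads: int | None = None,
) -> LibraryFragments:
    """Read a fragment BED; fragments longer than 1000 bp are dropped.

    When no read-count sidecar value is supplied, ``total_mapped_reads``
    defaults to 2x the post-filter fragment count (each proper pair = 2 reads).
    """
    df = _read_bed3(path, what=f"fragments[{sample_id}/{library_type}]")
    if df.empty:
        raise BedParseError(f"{sample_id}/{library_type}: empty fragment file")
    df = df[(df["end"] - df["start"]) <= 1000].reset_index(drop=True)
    if total_mapped_reads is None:
        total_mapped_reads = 2 * len(df)
    return LibraryFragments(sample_id, library_type, df[["chrom", "start", "end"]], total_mapped_reads)


def write_fragments(lib: LibraryFragments, path) -> None:
    lib.df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# tabular files
# ---------------------------------------------------------------------------

_META_MANDATORY = ("sample_id", "diagnosis", "stage", "split")


def read_metadata(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_META_MANDATORY) - set(df.columns)
    if missing:
        raise SchemaError(f"metadata missing mandatory columns {sorted(missing)}")
    records = []
    for row in df.to_dict(orient="records"):
        stage = row["stage"]
        stage = None if stage in ("", "NA", "none") else int(stage)
        covs = {}
        for key in COVARIATE_KEYS:
            if key in row and row[key] not in ("", "NA"):
                covs[key] = float(row[key]) if key == "age" else row[key]
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                diagnosis=row["diagnosis"],
                stage=stage,
                covariates=covs,
                split=row["split"] or "train",
            )
        )
    return records


def write_metadata(records: list[SampleRecord], path) -> None:
    rows = []
    for rec in records:
        row = {
            "sample_id": rec.sample_id,
            "diagnosis": rec.diagnosis,
            "stage": "NA" if rec.stage is None else rec.stage,
            "split": rec.split,
        }
        for key in COVARIATE_KEYS:
            row[key] = rec.covariates.get(key, "NA")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spikein(path) -> dict[tuple[str, str], SpikeInCounts]:
    """Read a spike-in TSV keyed by (sample_id, library_type)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "library_type", *SPIKE_SPECIES} - set(df.columns)
    if missing:
        raise SchemaError(f"spike-in table missing columns {sorted(missing)}")
    out = {}
    for row in df.to_dict(orient="records"):
        counts = {sp: int(row[sp]) for sp in SPIKE_SPECIES}
        out[(str(row["sample_id"]), str(row["library_type"]))] = SpikeInCounts(counts)
    return out


def write_spikein(spikes: dict[tuple[str, str], SpikeInCounts], path) -> None:
    rows = []
    for (sample_id, library_type), sc in spikes.items():
        rows.append({"sample_id": sample_id, "library_type": library_type, **sc.counts})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    """Samples-in-rows feature matrix TSV (index column ``sample_id``)."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")


def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")
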