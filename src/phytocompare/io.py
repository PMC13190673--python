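"""Readers, writers and validation for every table the pipeline touches.

All tables are tab-delimited UTF-8 with "." as decimal separator; this
is the only dialect supported, matching national monitoring-data
exports. Volumes are stored internally in liters; an ``*_ml`` header is
converted at parse time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .taxonomy import RANKS, UNASSIGNED, DEFAULT_WHITELIST, parse_lineage

__all__ = [
    "FormatError",
    "ValidationError",
    "AsvTable",
    "read_asv_table",
    "write_asv_table",
    "read_microscopy_table",
    "write_microscopy_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "validate_inputs",
    "RunConfig",
    "QUANTITY_COLUMNS",
]


class FormatError(ValueError):
    """A file does not conform to the expected table layout."""


class ValidationError(ValueError):
    """A well-formed file carries invalid values."""


#: Required quantity columns of the microscopy long table.
QUANTITY_COLUMNS = ("cells_per_liter", "biovolume_um3_per_liter", "carbon_ugC_per_liter")

#: Metadata columns interpreted by the pipeline (beyond sample_id).
_OPTIONAL_META = ("station", "basin", "date", "replicate_id", "dna_concentration",
                  "dna_total", "spike_molecules", "salinity")


@dataclass(frozen=True)
class AsvTable:
    """Integer read counts, samples x ASVs, with spike-in ASVs flagged.

    Spike columns are flagged, never silently removed; normalizations
    decide how to treat them.
    """

    counts: pd.DataFrame
    spike_asv_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise ValidationError(f"duplicated sample id {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValidationError(f"duplicated ASV id {dup!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {counts.index[i]!r}, ASV {counts.columns[j]!r}"
            )
        unknown = set(self.spike_asv_ids) - set(counts.columns)
        if unknown:
            raise ValidationError(f"spike ids not in ASV ids: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def nonspike_ids(self) -> list[str]:
        spikes = set(self.spike_asv_ids)
        return [a for a in self.counts.columns if a not in spikes]

    def spike_reads(self) -> pd.Series:
        """Total spike reads per sample (multiple spike ASVs summed)."""
        if not self.spike_asv_ids:
            return pd.Series(0, index=self.counts.index)
        return self.counts[list(self.spike_asv_ids)].sum(axis=1)

    def nonspike_counts(self) -> pd.DataFrame:
        return self.counts[self.nonspike_ids]

    def subset(self, sample_ids) -> "AsvTable":
        return AsvTable(self.counts.loc[list(sample_ids)], self.spike_asv_ids)


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except pd.errors.ParserError as exc:  # pragma: no cover - passthrough detail
        raise FormatError(f"{path}: {exc}") from exc


def read_asv_table(path, spike_ids=(), samples_as_rows: bool = True) -> AsvTable:
    """Read a TSV of read counts into a validated :class:`AsvTable`.

    The default orientation has samples as rows and ASV ids in the
    header; set ``samples_as_rows=False`` for the transposed layout.
    Non-integer or negative cells raise a diagnostic naming the cell.
    """
    raw = _read_tsv(path, index_col=0, dtype=str)
    if not samples_as_rows:
        raw = raw.T
    values = np.empty(raw.shape, dtype=np.int64)
    arr = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = arr[i, j]
            try:
                x = float(cell)
                if not float(x).is_integer():
                    raise ValueError
                values[i, j] = int(x)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at row {raw.index[i]!r}, "
                    f"column {raw.columns[j]!r}"
                ) from None
    counts = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))
    counts.index.name = "sample_id"
    counts.columns.name = None
    return AsvTable(counts, tuple(spike_ids))


def write_asv_table(table: AsvTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_microscopy_table(path) -> pd.DataFrame:
    """Read a long-format microscopy table.

    Expected columns: ``sample_id``, lineage ranks (any subset of the
    eight kept ranks; empty cells preserved as unassigned-at-rank) and
    the three quantity columns (cells, biovolume, carbon per liter).
    """
    df = _read_tsv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    missing = [c for c in QUANTITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing quantity columns {missing}")
    rank_cols = [r for r in RANKS if r in df.columns]
    if not rank_cols:
        raise FormatError(f"{path}: no lineage rank columns found")
    for col in rank_cols:
        df[col] = df[col].fillna("").map(lambda s: s.strip() or UNASSIGNED)
    for col in QUANTITY_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise FormatError(f"{path}: non-numeric {col!r} at row {row}")
        if not np.isfinite(vals).all() or (vals < 0).any():
            row = df.index[(~np.isfinite(vals)) | (vals < 0)][0]
            raise ValidationError(f"{path}: invalid {col!r} at row {row}")
        df[col] = vals.astype(float)
    return df[["sample_id", *rank_cols, *QUANTITY_COLUMNS]]


def write_microscopy_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata keyed by ``sample_id``.

    Filtered volume may be given as ``volume_filtered`` /
    ``volume_filtered_l`` (liters) or ``volume_filtered_ml``
    (milliliters, converted); it must be positive. Optional columns
    absent from the file stay absent (normalizations depending on them
    are disabled downstream with a warning).
    """
    df = _read_tsv(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    df = df.set_index(df["sample_id"].astype(str)).drop(columns="sample_id")
    vol_cols = [c for c in ("volume_filtered", "volume_filtered_l", "volume_filtered_ml")
                if c in df.columns]
    if not vol_cols:
        raise FormatError(f"{path}: missing filtered-volume column")
    col = vol_cols[0]
    vol = pd.to_numeric(df[col], errors="coerce")
    if col.endswith("_ml"):
        vol = vol / 1000.0
    if vol.isna().any() or (vol <= 0).any():
        bad = vol.index[vol.isna() | (vol <= 0)][0]
        raise ValidationError(f"{path}: non-positive filtered volume for sample {bad!r}")
    out = df.drop(columns=vol_cols)
    out["volume_filtered"] = vol.astype(float)
    for col in ("dna_concentration", "dna_total", "spike_molecules", "salinity"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce")
    if "spike_molecules" in out.columns and (out["spike_molecules"].dropna() < 0).any():
        bad = out.index[out["spike_molecules"] < 0][0]
        raise ValidationError(f"{path}: negative spike_molecules for sample {bad!r}")
    return out


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy_table(path) -> pd.DataFrame:
    """Read an ASV -> ranked lineage table.

    Accepts either explicit rank columns or a single ``lineage`` column
    of semicolon-joined PR2-style strings (parsed on load). Returns a
    DataFrame indexed by ``asv_id`` with the eight rank columns.
    """
    df = _read_tsv(path, dtype=str)
    if "asv_id" not in df.columns:
        raise FormatError(f"{path}: missing 'asv_id' column")
    if df["asv_id"].duplicated().any():
        dup = df.loc[df["asv_id"].duplicated(), "asv_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate asv_id {dup!r}")
    idx = df["asv_id"].astype(str)
    if "lineage" in df.columns:
        rows = [parse_lineage(s if isinstance(s, str) else "").as_tuple() for s in df["lineage"]]
        out = pd.DataFrame(rows, columns=list(RANKS), index=idx)
    else:
        rank_cols = [r for r in RANKS if r in df.columns]
        if not rank_cols:
            raise FormatError(f"{path}: neither 'lineage' nor rank columns present")
        out = pd.DataFrame(UNASSIGNED, index=idx, columns=list(RANKS))
        for col in rank_cols:
            out[col] = df[col].fillna("").map(lambda s: s.strip() or UNASSIGNED).to_numpy()
    out.index.name = "asv_id"
    return out


def write_taxonomy_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="asv_id")


def validate_inputs(asv: AsvTable, metadata: pd.DataFrame) -> None:
    """Cross-validate ASV table against metadata at pipeline assembly."""
    missing = set(asv.sample_ids) - set(metadata.index)
    if missing:
        raise ValidationError(
            f"samples missing from metadata: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )


@dataclass
class RunConfig:
    """Run configuration: inputs, whitelist, statistical settings.

    The seed is recorded in all outputs; permutation count must be >= 1.
    """

    asv: str | None = None
    taxonomy: str | None = None
    microscopy: str | None = None
    metadata: str | None = None
    name_map: str | None = None
    spike_ids: list[str] = field(default_factory=list)
    whitelist: list[str] = field(default_factory=lambda: sorted(DEFAULT_WHITELIST))
    normalization: str = "relative"
    permutations: int = 999
    seed: int = 0
    zero_policy: str = "drop"
    dna_measure: str = "concentration"
    carbon_model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.permutations < 1:
            raise ValidationError("permutation count must be >= 1")
        if self.zero_policy not in ("drop", "pseudocount"):
            raise ValidationError(f"unknown zero_policy {self.zero_policy!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
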