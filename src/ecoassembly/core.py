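"""Core data types, TSV readers/writers, validation and run configuration.

The canonical in-memory orientation is OTUs as rows and samples as columns
(the BIOM convention); readers accept either orientation and normalise.
Missing metadata values are represented as NaN, never as zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "SampleMetadata",
    "RunConfig",
    "ValidationError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "metadata_frame",
    "relative_abundance",
    "COVARIATE_BLOCKS",
]

#: Environmental covariate blocks used by variance partitioning.
COVARIATE_BLOCKS = {
    "topography": ["MEA", "CON", "SLO", "ASP"],
    "light": ["ALA", "CC", "TR", "SR", "DR", "LT", "LAI"],
    "soil": ["soil_pH", "organic_matter", "alkaline_N", "available_P", "water_content"],
}

#: Covariates constrained to the unit interval.
_UNIT_INTERVAL = ("CC", "LT", "water_content")

_BAND_LABELS = ("LEG", "MEG", "HEG")


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass
class OTUTable:
    """Integer count matrix with OTU row ids and sample column ids.

    Parameters
    ----------
    otu_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of int, shape (n_otus, n_samples)
        Non-negative counts; every sample (column) must have total > 0.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = [str(x) for x in self.otu_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n_otus, n_samples = self.counts.shape
        if len(self.otu_ids) != n_otus or len(self.sample_ids) != n_samples:
            raise ValidationError("ID lists do not match matrix shape")
        if len(set(self.otu_ids)) != n_otus:
            raise ValidationError("duplicate OTU ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("duplicate sample ids")
        if n_otus < 2 or n_samples < 2:
            raise ValidationError("need at least 2 OTUs and 2 samples")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at OTU {self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            j = int(np.argmin(totals))
            raise ValidationError(f"sample {self.sample_ids[j]!r} has zero total count")

    # -- conveniences ----------------------------------------------------
    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: list[str]) -> "OTUTable":
        """Return a table restricted to *sample_ids* (order preserved)."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OTUTable(list(self.otu_ids), list(sample_ids), self.counts[:, idx].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample environmental covariates; NaN marks a missing value."""

    sample_id: str
    MEA: float = np.nan
    CON: float = np.nan
    SLO: float = np.nan
    ASP: float = np.nan
    ALA: float = np.nan
    CC: float = np.nan
    TR: float = np.nan
    SR: float = np.nan
    DR: float = np.nan
    LT: float = np.nan
    LAI: float = np.nan
    soil_pH: float = np.nan
    organic_matter: float = np.nan
    alkaline_N: float = np.nan
    available_P: float = np.nan
    water_content: float = np.nan
    band: str | None = None

    def __post_init__(self) -> None:
        for name in _UNIT_INTERVAL:
            v = getattr(self, name)
            if v is not None and np.isfinite(v) and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} for sample {self.sample_id!r} outside [0, 1]")
        if self.band is not None and not isinstance(self.band, str):
            raise ValidationError("band must be a string label or None")


@dataclass
class RunConfig:
    """Run-wide settings shared by every stochastic stage."""

    rng_seed: int = 0
    n_permutations: int = 1000
    envfit_permutations: int = 999
    ci_level: float = 0.95
    rarefy_depth: int | None = None
    outdir: str | None = None
    otu_table_path: str | None = None
    metadata_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValidationError("ci_level must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a plain ``key = value`` config file; '#' starts a comment."""
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
            if value.lower() in {"none", ""}:
                kwargs[key] = None
            elif key in {"rng_seed", "n_permutations", "envfit_permutations", "rarefy_depth"}:
                kwargs[key] = int(value)
            elif key == "ci_level":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, orientation: str = "otus_as_rows") -> OTUTable:
    """Read a TSV count table (header row, first column = ids).

    ``orientation`` is ``"otus_as_rows"`` or ``"samples_as_rows"``; the result
    is always normalised to OTUs-as-rows.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no data columns")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, cell in enumerate(df.iloc[:, j]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"{path}: non-numeric count {cell!r} at row {df.index[i]!r}, "
                        f"column {col!r}"
                    ) from None
        raise
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{path}: negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if not np.allclose(values, np.round(values)):
        i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValidationError(
            f"{path}: non-integer count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    counts = np.round(values).astype(np.int64)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "samples_as_rows":
        counts = counts.T
        row_ids, col_ids = col_ids, row_ids
    return OTUTable(row_ids, col_ids, counts)


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="otu_id")


_METADATA_FLOAT_COLS = [f.name for f in fields(SampleMetadata) if f.name not in ("sample_id", "band")]


def read_metadata(path: str | Path, table: OTUTable | None = None) -> list[SampleMetadata]:
    """Read sample metadata TSV; optionally cross-check ids against *table*."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'sample_id'")
    missing_cols = [c for c in _METADATA_FLOAT_COLS if c not in df.columns]
    if missing_cols:
        warnings.warn(f"{path}: metadata columns missing (left as NaN): {missing_cols}")
    records = []
    for _, row in df.iterrows():
        kwargs = {"sample_id": str(row["sample_id"])}
        for col in _METADATA_FLOAT_COLS:
            kwargs[col] = float(row[col]) if col in df.columns and pd.notna(row[col]) else np.nan
        if "band" in df.columns and pd.notna(row.get("band")):
            kwargs["band"] = str(row["band"])
        records.append(SampleMetadata(**kwargs))
    if table is not None:
        orphans = sorted(set(r.sample_id for r in records) - set(table.sample_ids))
        if orphans:
            raise ValidationError(f"{path}: sample ids absent from OTU table: {orphans}")
    return records


def write_metadata(records: list[SampleMetadata], path: str | Path) -> None:
    metadata_frame(records).to_csv(path, sep="\t", index=False)


def metadata_frame(records: list[SampleMetadata]) -> pd.DataFrame:
    """Tabular view of metadata records, one row per sample."""
    rows = []
    for r in records:
        d = {"sample_id": r.sample_id}
        d.update({c: getattr(r, c) for c in _METADATA_FLOAT_COLS})
        d["band"] = r.band
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def relative_abundance(table: OTUTable, axis: str = "per_sample") -> np.ndarray:
    """Normalise counts to proportions.

    ``per_sample``: each column sums to 1.  ``per_otu``: each row with a
    nonzero total sums to 1; all-zero rows are returned as zeros with a
    warning.
    """
    counts = table.counts.astype(float)
    if axis == "per_sample":
        return counts / counts.sum(axis=0, keepdims=True)
    if axis == "per_otu":
        totals = counts.sum(axis=1, keepdims=True)
        zero = totals[:, 0] == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} all-zero OTU row(s); returned as zeros")
        safe = np.where(totals == 0, 1.0, totals)
        return counts / safe
    raise ValueError(f"unknown axis {axis!r}")


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
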