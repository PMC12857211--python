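"""Reading and writing labeled volumes and annotation tables.

Owns the coordinate and unit conventions for the whole package:

* volumes are 3D integer label grids indexed ``(z, y, x)``, label 0 is
  background;
* voxel spacing is ``(dz, dy, dx)`` in micrometers, TIFF pages are z;
* the physical centroid of voxel ``(z, y, x)`` is
  ``((z + 0.5) * dz, (y + 0.5) * dy, (x + 0.5) * dx)``;
* all lengths are micrometers everywhere — no unit autodetection.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LabeledVolume",
    "FormatError",
    "ValidationError",
    "SchemaError",
    "read_volume",
    "write_volume",
    "read_table",
    "write_table",
    "voxel_centers",
]

Channel = Literal["cell", "pore"]

CELL_TYPES = ("TC", "PC")
PORE_KINDS = ("PD", "OP", "unset")

#: required columns per tabular schema
TABLE_SCHEMAS = {
    "cell_types": ["cell_label", "cell_type"],
    "pores": ["pore_id", "cz", "cy", "cx", "diameter", "kind"],
    "measurements": ["group", "replicate", "value"],
}


class FormatError(ValueError):
    """File does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Data violates a domain invariant."""


class SchemaError(ValueError):
    """Table is missing required columns."""


@dataclasses.dataclass(frozen=True)
class LabeledVolume:
    """A 3D integer label grid with physical voxel spacing.

    Parameters
    ----------
    labels
        Integer array indexed ``(z, y, x)``. Label 0 is background.
    spacing
        ``(dz, dy, dx)`` voxel edge lengths in micrometers, all > 0.
    channel
        ``"cell"`` for cell labels, ``"pore"`` for pore labels.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    channel: Channel = "cell"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError(f"labels must be 3D, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise FormatError(f"labels must be integer, got dtype={labels.dtype}")
        if labels.size and labels.min() < 0:
            raise ValidationError("negative labels are not allowed")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3:
            raise ValidationError("spacing must have 3 components (dz, dy, dx)")
        if not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValidationError(f"spacing must be finite and positive, got {spacing}")
        if self.channel not in ("cell", "pore"):
            raise ValidationError(f"unknown channel {self.channel!r}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Physical size (µm) of the grid along (z, y, x)."""
        return tuple(n * d for n, d in zip(self.shape, self.spacing))

    def label_set(self) -> np.ndarray:
        """Sorted distinct non-background labels."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_labels(self) -> int:
        return int(self.label_set().size)


def voxel_centers(indices: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Physical centers (µm) of voxels given integer ``(z, y, x)`` indices."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    return (idx + 0.5) * np.asarray(spacing, dtype=float)


def read_volume(
    path: str | Path,
    spacing: tuple[float, float, float],
    channel: Channel = "cell",
) -> LabeledVolume:
    """Read a multi-page TIFF stack of integer label images.

    Pages are z-slices; all pages must share a shape and an integer dtype.
    """
    with tifffile.TiffFile(str(path)) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D stack in {path}, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"non-integer pixel type {arr.dtype} in {path}")
    return LabeledVolume(labels=arr, spacing=spacing, channel=channel)


def write_volume(vol: LabeledVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF; round-trips labels bit-exactly."""
    try:
        tifffile.imwrite(str(path), vol.labels, photometric="minisblack")
    except OSError as exc:  # pragma: no cover - passthrough
        raise OSError(f"cannot write volume to {path}: {exc}") from exc


def _validate_cell_types(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["cell_label"] = df["cell_label"].astype(np.int64)
    df["cell_type"] = df["cell_type"].astype(str)
    if (df["cell_label"] <= 0).any():
        raise ValidationError("cell_label must be positive")
    if df["cell_label"].duplicated().any():
        dup = df.loc[df["cell_label"].duplicated(), "cell_label"].tolist()
        raise ValidationError(f"duplicate cell_label values: {dup}")
    bad = sorted(set(df["cell_type"]) - set(CELL_TYPES))
    if bad:
        raise ValidationError(f"unknown cell_type tokens: {bad}")
    return df


def _validate_pores(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["pore_id"] = df["pore_id"].astype(np.int64)
    for col in ("cz", "cy", "cx", "diameter"):
        df[col] = df[col].astype(float)
    df["kind"] = df["kind"].astype(str)
    if (df["pore_id"] <= 0).any():
        raise ValidationError("pore_id must be positive")
    if df["pore_id"].duplicated().any():
        raise ValidationError("duplicate pore_id values")
    if (df["diameter"] <= 0).any():
        raise ValidationError("pore diameter must be positive")
    bad = sorted(set(df["kind"]) - set(PORE_KINDS))
    if bad:
        raise ValidationError(f"unknown pore kind tokens: {bad}")
    return df


def _validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["group"] = df["group"].astype(str)
    df["replicate"] = df["replicate"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    if not np.isfinite(df["value"]).all():
        raise ValidationError("measurement values must be finite")
    return df


_VALIDATORS = {
    "cell_types": _validate_cell_types,
    "pores": _validate_pores,
    "measurements": _validate_measurements,
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against one of the known schemas.

    ``schema`` is one of ``"cell_types"``, ``"pores"``, ``"measurements"``.
    """
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {list(TABLE_SCHEMAS)}")
    df = pd.read_csv(path)
    missing = [c for c in TABLE_SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} for schema {schema!r}")
    return _VALIDATORS[schema](df)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as comma-separated UTF-8 CSV with '.' decimals."""
    df.to_csv(path, index=False)


def cell_type_map(table: pd.DataFrame) -> dict[int, str]:
    """Cell-type table as a ``{label: type}`` dict."""
    return dict(zip(table["cell_label"].astype(int), table["cell_type"]))
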