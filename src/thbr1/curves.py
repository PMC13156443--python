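"""Binned angular R1 curves and their CSV representation.

A curve holds, for one field, the per-bin mean apparent R1, its SD and the
voxel count on the 4.5-degree bin grid (centers 0, 4.5, ..., 90).  Empty
bins carry ``n_voxels = 0`` and NaN mean/SD; CSV files write them as empty
cells.  CSV columns: ``field_tesla, bin_center_deg, mean_r1, sd_r1,
n_voxels``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidDataError
from .fields import FieldContext, study_field

#: Default bin width [deg] and the resulting 21 centers 0 ... 90.
BIN_WIDTH_DEG = 4.5


def default_bin_centers(bin_width: float = BIN_WIDTH_DEG) -> np.ndarray:
    n = int(round(90.0 / bin_width)) + 1
    return np.arange(n) * bin_width


CSV_COLUMNS = ["field_tesla", "bin_center_deg", "mean_r1", "sd_r1", "n_voxels"]


@dataclass
class AngularCurve:
    """Per-field binned angular R1 data."""

    field: FieldContext
    bin_center: np.ndarray  # degrees
    mean_r1: np.ndarray     # 1/s, NaN where empty
    sd_r1: np.ndarray       # 1/s, NaN where empty
    n_voxels: np.ndarray    # counts
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_center = np.asarray(self.bin_center, dtype=float)
        self.mean_r1 = np.asarray(self.mean_r1, dtype=float)
        self.sd_r1 = np.asarray(self.sd_r1, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        self.validate()

    def validate(self) -> None:
        c = self.bin_center
        if c.ndim != 1 or not all(
                a.shape == c.shape
                for a in (self.mean_r1, self.sd_r1, self.n_voxels)):
            raise InvalidDataError("curve columns must be equal-length 1-D")
        if c.size and (np.any(np.diff(c) <= 0) or c[0] < 0 or c[-1] > 90):
            raise InvalidDataError(
                "bin centers must be strictly increasing within [0, 90] deg")
        if np.any(self.n_voxels < 0):
            raise InvalidDataError("n_voxels must be >= 0")
        few = self.n_voxels <= 1
        sd_ok = np.isnan(self.sd_r1[few]) | (self.sd_r1[few] == 0)
        if not np.all(sd_ok):
            raise InvalidDataError("sd_r1 must be 0 (or NaN) where n <= 1")

    @property
    def populated(self) -> np.ndarray:
        """Boolean mask of bins that carry data."""
        return (self.n_voxels > 0) & np.isfinite(self.mean_r1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "field_tesla": np.full(self.bin_center.shape, self.field.B),
            "bin_center_deg": self.bin_center,
            "mean_r1": self.mean_r1,
            "sd_r1": self.sd_r1,
            "n_voxels": self.n_voxels,
        })

    def to_csv(self, path) -> None:
        """Write the curve; numeric columns round-trip to 1e-12."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, field: FieldContext | None = None,
                 ) -> "AngularCurve":
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise InvalidDataError(f"cannot parse {path}: {exc}") from exc
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidDataError(
                f"{path}: missing columns {missing} (line 1)")
        if field is None:
            teslas = df["field_tesla"].dropna().unique()
            if len(teslas) != 1:
                raise InvalidDataError(
                    f"{path}: expected a single field_tesla value")
            field = study_field(float(teslas[0]))
        sd = df["sd_r1"].to_numpy(dtype=float)
        n = df["n_voxels"].fillna(0).to_numpy(dtype=int)
        sd = np.where((n <= 1) & ~np.isnan(sd), 0.0, sd)
        return cls(field=field,
                   bin_center=df["bin_center_deg"].to_numpy(dtype=float),
                   mean_r1=df["mean_r1"].to_numpy(dtype=float),
                   sd_r1=sd, n_voxels=n, meta={"source": str(path)})


def write_curves(curves: dict[float, AngularCurve], out_dir,
                 prefix: str = "curve") -> list[Path]:
    """Write one CSV per field, named ``<prefix>_<tesla>T.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tesla in sorted(curves):
        p = out_dir / f"{prefix}_{tesla:g}T.csv"
        curves[tesla].to_csv(p)
        paths.append(p)
    return paths


def read_curves(paths) -> dict[float, AngularCurve]:
    """Read several per-field CSVs into a dict keyed by tesla."""
    out = {}
    for p in paths:
        c = AngularCurve.from_csv(p)
        out[float(c.field.B)] = c
    return out
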