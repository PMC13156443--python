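"""Voxel-level angular analysis: fiber-to-field angles and R1 binning.

Takes co-registered scalar/vector volumes (apparent R1 map, principal
diffusion eigenvector V1, orientation dispersion index ODI, optional FA),
selects coherent white matter by an ODI band, computes each voxel's
fiber-to-field angle from V1 and the magnet axis, and aggregates R1 into
4.5-degree angle bins.  Registration is assumed done upstream; the module
only verifies that all volumes share a grid and affine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np

from .curves import BIN_WIDTH_DEG, AngularCurve, default_bin_centers
from .exceptions import GeometryError, InvalidDataError
from .fields import FieldContext

logger = logging.getLogger(__name__)

#: Default magnet axis in the volume's world frame (scanner z).
DEFAULT_B0_DIR = np.array([0.0, 0.0, 1.0])

#: Default ODI selection band for coherent white matter.
DEFAULT_ODI_RANGE = (0.0, 0.2)


@dataclass
class VoxelDataset:
    """Co-registered R1 / V1 / ODI (/ FA) volumes for one field."""

    r1: np.ndarray            # (X, Y, Z) [1/s]
    v1: np.ndarray            # (X, Y, Z, 3) unit vectors where defined
    odi: np.ndarray           # (X, Y, Z) in [0, 1]
    field: FieldContext
    fa: np.ndarray | None = None
    b0_dir: np.ndarray = dc_field(
        default_factory=lambda: DEFAULT_B0_DIR.copy())
    affine: np.ndarray = dc_field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.r1 = np.asarray(self.r1, dtype=float)
        self.v1 = np.asarray(self.v1, dtype=float)
        self.odi = np.asarray(self.odi, dtype=float)
        self.b0_dir = np.asarray(self.b0_dir, dtype=float)
        if self.fa is not None:
            self.fa = np.asarray(self.fa, dtype=float)
        shape = self.r1.shape
        if self.v1.shape != shape + (3,):
            raise GeometryError(
                f"v1 shape {self.v1.shape} does not match r1 {shape} + (3,)")
        for name, vol in (("odi", self.odi), ("fa", self.fa)):
            if vol is not None and vol.shape != shape:
                raise GeometryError(
                    f"{name} shape {vol.shape} does not match r1 {shape}")
        nrm = np.linalg.norm(self.b0_dir)
        if nrm == 0:
            raise InvalidDataError("b0_dir must be nonzero")
        self.b0_dir = self.b0_dir / nrm

    @classmethod
    def from_nifti(cls, r1_path, v1_path, odi_path, field: FieldContext,
                   fa_path=None, b0_dir=None) -> "VoxelDataset":
        """Load co-registered NIfTI volumes (V1 as a 4-D 3-component image).

        Raises :class:`GeometryError` when shapes or affines disagree.
        """
        imgs = {"r1": nib.load(str(r1_path)), "v1": nib.load(str(v1_path)),
                "odi": nib.load(str(odi_path))}
        if fa_path is not None:
            imgs["fa"] = nib.load(str(fa_path))
        ref = imgs["r1"]
        for name, img in imgs.items():
            if img.shape[:3] != ref.shape[:3]:
                raise GeometryError(
                    f"{name} grid {img.shape[:3]} != r1 grid {ref.shape[:3]}")
            if not np.allclose(img.affine, ref.affine, atol=1e-4):
                raise GeometryError(f"{name} affine differs from r1 affine")
        if imgs["v1"].shape[3:] != (3,):
            raise GeometryError("v1 image must have 3 components (4-D NIfTI)")
        return cls(
            r1=np.asanyarray(imgs["r1"].dataobj, dtype=float),
            v1=np.asanyarray(imgs["v1"].dataobj, dtype=float),
            odi=np.asanyarray(imgs["odi"].dataobj, dtype=float),
            fa=(np.asanyarray(imgs["fa"].dataobj, dtype=float)
                if "fa" in imgs else None),
            field=field,
            b0_dir=DEFAULT_B0_DIR if b0_dir is None else np.asarray(b0_dir),
            affine=np.array(ref.affine))


def fiber_field_angle(v1, b0_dir) -> np.ndarray:
    """Fiber-to-field angle [deg, 0-90] from eigenvectors and magnet axis.

    theta = arccos(|v . b|) with both vectors normalised; antipodal
    eigenvectors map to the same angle (axial symmetry).  Zero vectors yield
    NaN (invalid-voxel marker) rather than raising.
    """
    v1 = np.asarray(v1, dtype=float)
    b = np.asarray(b0_dir, dtype=float)
    bn = np.linalg.norm(b)
    if bn == 0:
        raise InvalidDataError("b0_dir must be nonzero")
    b = b / bn
    vn = np.linalg.norm(v1, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(np.tensordot(v1, b, axes=([-1], [0]))) / vn
    theta = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    return np.where(vn > 0, theta, np.nan)


def select_voxels(ds: VoxelDataset, odi_range=DEFAULT_ODI_RANGE,
                  fa_min: float | None = None) -> np.ndarray:
    """Boolean mask of voxels entering the angular analysis.

    True iff ODI in [lo, hi] (inclusive), FA >= fa_min when given, V1 is a
    nonzero finite vector, and R1 is finite and positive.
    """
    lo, hi = odi_range
    if not (0 <= lo <= hi <= 1):
        raise InvalidDataError("odi_range must satisfy 0 <= lo <= hi <= 1")
    mask = (np.isfinite(ds.odi) & (ds.odi >= lo) & (ds.odi <= hi)
            & np.isfinite(ds.r1) & (ds.r1 > 0)
            & np.all(np.isfinite(ds.v1), axis=-1)
            & (np.linalg.norm(ds.v1, axis=-1) > 0))
    if fa_min is not None:
        if ds.fa is None:
            raise InvalidDataError("fa_min given but dataset has no FA map")
        mask &= np.isfinite(ds.fa) & (ds.fa >= fa_min)
    if not mask.any():
        logger.warning("voxel selection produced an empty mask "
                       "(ODI range %s, fa_min %s)", odi_range, fa_min)
    return mask


def assign_bins(theta_deg, bin_width: float = BIN_WIDTH_DEG) -> np.ndarray:
    """Nearest-center bin index on the 0, 4.5, ..., 90 grid.

    Exact ties between two centers go to the lower center:
    idx = ceil(theta / width - 1/2).
    """
    theta = np.asarray(theta_deg, dtype=float)
    idx = np.ceil(theta / bin_width - 0.5).astype(int)
    n_bins = int(round(90.0 / bin_width)) + 1
    return np.clip(idx, 0, n_bins - 1)


def bin_r1_by_angle(ds: VoxelDataset, mask: np.ndarray,
                    bin_width: float = BIN_WIDTH_DEG) -> AngularCurve:
    """Aggregate masked voxels' R1 into angle bins.

    Per bin: mean, sample SD (n-1 denominator, 0 when n <= 1) and count.
    Bins with no voxels get NaN mean/SD and count 0.  The per-bin counts sum
    to the mask cardinality (voxels whose V1 is undefined are excluded by
    :func:`select_voxels` upstream).
    """
    centers = default_bin_centers(bin_width)
    n_bins = centers.size
    theta = fiber_field_angle(ds.v1[mask], ds.b0_dir)
    r1 = ds.r1[mask]
    valid = np.isfinite(theta)
    theta, r1 = theta[valid], r1[valid]
    idx = assign_bins(theta, bin_width)
    n = np.bincount(idx, minlength=n_bins)
    s = np.bincount(idx, weights=r1, minlength=n_bins)
    ss = np.bincount(idx, weights=r1 * r1, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        var = np.where(n > 1, (ss - n * mean ** 2) / np.maximum(n - 1, 1), 0.0)
        sd = np.sqrt(np.clip(var, 0.0, None))
    sd = np.where(n > 0, sd, np.nan)
    sd = np.where(n == 1, 0.0, sd)
    return AngularCurve(field=ds.field, bin_center=centers, mean_r1=mean,
                        sd_r1=sd, n_voxels=n,
                        meta={"bin_width_deg": bin_width,
                              "mask_voxels": int(np.count_nonzero(mask))})
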