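"""Synthetic inputs with the statistical structure the analysis assumes.

Two levels are generated:

* curve level — angular R1 profiles evaluated by the forward model on the
  bin grid, with Gaussian noise on the bin means (SD ``noise_sd/sqrt(n)``),
  one curve per field;

* voxel level — NIfTI-backed image phantoms whose voxels carry
  Watson-dispersed fiber directions, the deterministic ODI implied by the
  Watson concentration, a cosmetic FA, and R1 drawn from the forward model
  at the voxel's fiber-to-field angle plus Gaussian noise.  An optional
  region with reduced bound-water fraction and a near-parallel mean
  direction emulates the low-angle dip seen in large-axon tracts
  (cortico-spinal-tract-like).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np

from .binning import DEFAULT_B0_DIR, VoxelDataset
from .curves import AngularCurve, default_bin_centers
from .exceptions import InvalidParameterError
from .fields import FieldContext, study_fields
from .params import PUBLISHED_R1I, BiophysParams
from .physics import r1_apparent

__all__ = [
    "generate_curves", "sample_watson", "odi_from_kappa", "kappa_from_odi",
    "PhantomRegion", "PhantomSpec", "generate_phantom", "write_phantom",
]


# ---------------------------------------------------------------------------
# Curve-level generation
# ---------------------------------------------------------------------------

def generate_curves(truth: BiophysParams, r1i: dict[float, float],
                    fields: dict[float, FieldContext] | None = None,
                    bin_centers=None, noise_sd: float = 0.0,
                    n_per_bin: int = 100, seed: int | None = None,
                    ) -> dict[float, AngularCurve]:
    """Forward-model angular curves with Gaussian bin noise, per field.

    ``mean_r1 = R1app(center) + N(0, noise_sd/sqrt(n_per_bin))``;
    ``sd_r1`` is set to ``noise_sd`` (the voxel-level scatter the bin mean
    was notionally averaged from).  Reproducible given ``seed``.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if fields is None:
        fields = study_fields(sorted(r1i))
    if bin_centers is None:
        bin_centers = default_bin_centers()
    bin_centers = np.asarray(bin_centers, dtype=float)
    rng = np.random.default_rng(seed)
    out = {}
    for tesla in sorted(fields):
        ctx = fields[tesla]
        clean = r1_apparent(truth, r1i[tesla], bin_centers, ctx, warn=False)
        noise = rng.normal(0.0, 1.0, size=bin_centers.shape)
        mean = clean + (noise_sd / np.sqrt(n_per_bin)) * noise
        # the curve invariant forces sd = 0 when a bin holds <= 1 voxel
        sd = np.full_like(mean, float(noise_sd) if n_per_bin > 1 else 0.0)
        out[tesla] = AngularCurve(
            field=ctx, bin_center=bin_centers, mean_r1=mean, sd_r1=sd,
            n_voxels=np.full(bin_centers.shape, n_per_bin, dtype=int),
            meta={"synthetic": True, "noise_sd": noise_sd, "seed": seed})
    return out


# ---------------------------------------------------------------------------
# Watson-dispersed directions and the NODDI dispersion index
# ---------------------------------------------------------------------------

def _orthonormal_frame(mean_dir: np.ndarray) -> np.ndarray:
    """3x3 rotation whose third column is mean_dir."""
    w = mean_dir / np.linalg.norm(mean_dir)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(w[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.column_stack([u, v, w])


def sample_watson(mean_dir, kappa: float, n: int,
                  seed_or_rng=None) -> np.ndarray:
    """Draw ``n`` axes from a Watson distribution about ``mean_dir``.

    Density on the sphere is proportional to exp(kappa (mu.x)^2)
    (concentrated, kappa > 0).  Sampled by rejection on t = mu.x with
    envelope exp(kappa (t^2 - 1)) <= 1 and a uniform azimuth, then rotated
    into the mean frame.  Axes are sign-ambiguous by construction.
    """
    if kappa <= 0:
        raise InvalidParameterError("kappa must be positive")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    ts = np.empty(0)
    rate = 1.0  # running acceptance estimate sizes the next batch
    while ts.size < n:
        m = int(np.clip(1.5 * (n - ts.size) / rate, 1024, 4_000_000))
        t = rng.uniform(-1.0, 1.0, size=m)
        u = rng.uniform(0.0, 1.0, size=m)
        acc = np.log(u) < kappa * (t * t - 1.0)
        rate = max((np.count_nonzero(acc) + 1.0) / (m + 2.0), 1e-6)
        ts = np.concatenate([ts, t[acc]])
    t = ts[:n]
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    s = np.sqrt(np.clip(1.0 - t * t, 0.0, None))
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), t])
    return local @ _orthonormal_frame(np.asarray(mean_dir, dtype=float)).T


def odi_from_kappa(kappa):
    """NODDI orientation dispersion index, ODI = (2/pi) arctan(1/kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise InvalidParameterError("kappa must be positive")
    return (2.0 / np.pi) * np.arctan(1.0 / kappa)


def kappa_from_odi(odi):
    """Inverse of :func:`odi_from_kappa`."""
    odi = np.asarray(odi, dtype=float)
    if np.any((odi <= 0) | (odi >= 1)):
        raise InvalidParameterError("odi must lie strictly in (0, 1)")
    return 1.0 / np.tan(np.pi * odi / 2.0)


def fa_from_odi(odi):
    """Cosmetic FA map: monotone decreasing in ODI, FA = 0.8 (1 - ODI/0.5),
    clipped to [0, 1].  Not a physical model; sufficient for FA-threshold
    testing."""
    return np.clip(0.8 * (1.0 - np.asarray(odi, dtype=float) / 0.5), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Voxel-level phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomRegion:
    """A box-shaped region of the phantom grid.

    ``box`` is ((x0, x1), (y0, y1), (z0, z1)) in voxel indices, half-open.
    ``param_overrides`` patches the shared biophysical parameters inside the
    region (e.g. ``{"nwA": 0.0175}`` halves the bound-water fraction for a
    CST-like tract); ``r1i`` optionally overrides the per-field isotropic
    rate.
    """

    box: tuple
    mean_dir: tuple = (0.0, 1.0, 0.0)
    kappa: float = 20.0
    param_overrides: dict = dc_field(default_factory=dict)
    r1i: dict | None = None
    r1i_scale: float = 1.0

    def slices(self):
        return tuple(slice(int(a), int(b)) for a, b in self.box)


@dataclass
class PhantomSpec:
    """Specification of a multi-region voxel phantom."""

    shape: tuple = (24, 24, 24)
    voxel_size: float = 2.0  # mm
    regions: tuple = ()
    noise_sd: float = 0.05   # 1/s voxel-level R1 noise
    fields: tuple = (1.5, 3.0, 7.0)
    b0_dir: tuple = tuple(DEFAULT_B0_DIR)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        for r in self.regions:
            if r.kappa <= 0:
                raise InvalidParameterError("region kappa must be positive")
        occ = np.zeros(self.shape, dtype=int)
        for r in self.regions:
            occ[r.slices()] += 1
        if np.any(occ > 1):
            raise InvalidParameterError("phantom regions must not overlap")

    def to_jsonable(self) -> dict:
        return {
            "shape": list(self.shape), "voxel_size": self.voxel_size,
            "noise_sd": self.noise_sd, "fields": list(self.fields),
            "b0_dir": list(self.b0_dir), "seed": self.seed,
            "regions": [
                {"box": [list(b) for b in r.box],
                 "mean_dir": list(r.mean_dir), "kappa": r.kappa,
                 "param_overrides": dict(r.param_overrides),
                 "r1i_scale": r.r1i_scale,
                 "r1i": None if r.r1i is None else
                 {str(k): v for k, v in r.r1i.items()}}
                for r in self.regions],
        }


def default_phantom_spec(cst_region: bool = True, shape=(24, 24, 24),
                         kappa: float = 20.0, noise_sd: float = 0.05,
                         seed: int = 0) -> PhantomSpec:
    """A two-region phantom: a large coherent region with fibers roughly
    perpendicular to B0, and (optionally) a small near-parallel region with
    halved bound-water fraction that produces the low-angle R1 dip."""
    nx = shape[0]
    split = max(nx // 4, 1)
    regions = [PhantomRegion(
        box=((split, nx), (0, shape[1]), (0, shape[2])),
        mean_dir=(0.0, 1.0, 0.0), kappa=kappa)]
    if cst_region:
        # mean direction ~5 deg off B0 (within the low-angle bins); large
        # axons carry less THB-forming water in both channels, so both the
        # anisotropic fraction nwA and the isotropic rate R1I are reduced
        tilt = np.deg2rad(5.0)
        regions.insert(0, PhantomRegion(
            box=((0, split), (0, shape[1]), (0, shape[2])),
            mean_dir=(np.sin(tilt), 0.0, np.cos(tilt)), kappa=kappa,
            param_overrides={"nwA_scale": 0.5}, r1i_scale=0.98))
    return PhantomSpec(shape=shape, regions=tuple(regions),
                       noise_sd=noise_sd, seed=seed)


def _region_params(base: BiophysParams, region: PhantomRegion,
                   ) -> BiophysParams:
    over = dict(region.param_overrides)
    scale = over.pop("nwA_scale", None)
    p = base.replace(**over) if over else base
    if scale is not None:
        p = p.replace(nwA=p.nwA * scale)
    return p


def generate_phantom(spec: PhantomSpec, base_params: BiophysParams,
                     r1i: dict[float, float] | None = None,
                     fields: dict[float, FieldContext] | None = None,
                     ) -> dict[float, VoxelDataset]:
    """Build per-field voxel datasets from a phantom specification.

    Per voxel: a fiber axis drawn from its region's Watson distribution
    (shared across fields), ODI = odi_from_kappa(kappa), FA from the
    cosmetic ODI map, and R1 = R1app(theta) + N(0, noise_sd).  Voxels
    outside every region are background: zero V1 (invalid marker), ODI 1,
    R1 0 — excluded by the selection mask downstream.  Bit-reproducible for
    a given spec + seed.
    """
    if r1i is None:
        r1i = {t: PUBLISHED_R1I[t] for t in spec.fields}
    if fields is None:
        fields = study_fields(spec.fields)
    rng = np.random.default_rng(spec.seed)
    b0 = np.asarray(spec.b0_dir, dtype=float)
    b0 = b0 / np.linalg.norm(b0)

    shape = tuple(spec.shape)
    v1 = np.zeros(shape + (3,))
    odi = np.ones(shape)
    theta = np.full(shape, np.nan)
    region_params = []
    region_masks = []
    for region in spec.regions:
        sl = region.slices()
        nvox = int(np.prod([s.stop - s.start for s in sl]))
        dirs = sample_watson(region.mean_dir, region.kappa, nvox, rng)
        box_shape = tuple(s.stop - s.start for s in sl)
        v1[sl] = dirs.reshape(box_shape + (3,))
        odi[sl] = float(odi_from_kappa(region.kappa))
        cosang = np.abs(dirs @ b0)
        theta[sl] = np.degrees(np.arccos(np.clip(cosang, 0, 1))
                               ).reshape(box_shape)
        region_params.append(_region_params(base_params, region))
        m = np.zeros(shape, dtype=bool)
        m[sl] = True
        region_masks.append(m)
    fa = fa_from_odi(odi)

    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    out = {}
    for tesla in sorted(fields):
        ctx = fields[tesla]
        r1 = np.zeros(shape)
        for region, p, m in zip(spec.regions, region_params, region_masks):
            r1i_here = (region.r1i or {}).get(tesla, r1i[tesla]) \
                * region.r1i_scale
            r1[m] = r1_apparent(p, r1i_here, theta[m], ctx, warn=False)
        if spec.noise_sd > 0:
            any_region = np.logical_or.reduce(region_masks) if region_masks \
                else np.zeros(shape, dtype=bool)
            r1[any_region] += rng.normal(0.0, spec.noise_sd,
                                         size=int(any_region.sum()))
        out[tesla] = VoxelDataset(r1=r1, v1=v1, odi=odi, fa=fa, field=ctx,
                                  b0_dir=b0, affine=affine)
    return out


def write_phantom(datasets: dict[float, VoxelDataset], out_dir,
                  spec: PhantomSpec | None = None) -> dict[float, dict]:
    """Write per-field NIfTI volumes (+ a provenance JSON when a spec is
    given).  Returns the path map keyed by tesla."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tesla, ds in datasets.items():
        tag = f"{tesla:g}T"
        p = {
            "r1": out_dir / f"r1_{tag}.nii.gz",
            "v1": out_dir / f"v1_{tag}.nii.gz",
            "odi": out_dir / f"odi_{tag}.nii.gz",
            "fa": out_dir / f"fa_{tag}.nii.gz",
        }
        nib.save(nib.Nifti1Image(ds.r1, ds.affine), str(p["r1"]))
        nib.save(nib.Nifti1Image(ds.v1, ds.affine), str(p["v1"]))
        nib.save(nib.Nifti1Image(ds.odi, ds.affine), str(p["odi"]))
        nib.save(nib.Nifti1Image(ds.fa, ds.affine), str(p["fa"]))
        paths[tesla] = {k: str(v) for k, v in p.items()}
    if spec is not None:
        with open(out_dir / "phantom_spec.json", "w") as fh:
            json.dump(spec.to_jsonable(), fh, indent=2)
    return paths
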