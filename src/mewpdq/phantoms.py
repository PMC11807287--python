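"""Parametric pelvic phantoms and virtual-patient populations.

The anatomy is a deliberately simple stand-in for a CT-derived pelvis:
an elliptic-cylinder soft-tissue body, a pelvic bone compartment (a
bony ring plus a posterior sacro-iliac mass that hosts the lesion), a
gut compartment, and a spherical lesion embedded in bone.  Four volumes
of interest (VOIs) partition the body: background (1), bone (2), gut
(3), and lesion (4).  Activity concentration maps (Bq/mL) for Th-227
and Ra-223 are constant per VOI unless lumpy intra-regional
heterogeneity is applied.

The module also provides the virtual-imaging-trial population sampler
(lesion diameter, lesion location, per-region uptake, and body size all
randomized), the lumpy-texture heterogeneity model, its mixture with
the homogeneous phantom, and rigid misregistration of the underlying
activity/attenuation relative to the (stale) VOI labels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .attenuation import (
    TISSUE_AIR,
    TISSUE_BONE,
    TISSUE_SOFT,
    reference_mu_map,
)

__all__ = [
    "GridSpec",
    "Phantom",
    "RegionalUptake",
    "LumpyParams",
    "VITConfig",
    "VOI_NAMES",
    "BACKGROUND",
    "BONE",
    "GUT",
    "LESION",
    "TABLE_RATIOS",
    "make_pelvic_phantom",
    "uptake_from_ratios",
    "standard_uptake",
    "apply_lumpy_heterogeneity",
    "mix_heterogeneity",
    "sample_vit_population",
    "apply_rigid_misregistration",
    "save_phantom",
    "load_phantom",
]

BACKGROUND, BONE, GUT, LESION = 1, 2, 3, 4
VOI_NAMES = {BACKGROUND: "background", BONE: "bone", GUT: "gut", LESION: "lesion"}
N_REGIONS = 4

#: Regional activity-concentration ratios (background, bone, gut, lesion)
#: used as the standard uptake pattern for the two isotopes.
TABLE_RATIOS = {
    "Th227": np.array([12.0, 30.0, 100.0, 300.0]),
    "Ra223chain": np.array([2.0, 5.0, 25.0, 20.0]),
}

#: Standard administered Th-227 activity (Bq) and Th:Ra total-activity ratio.
STANDARD_TOTAL_TH_BQ = 11e6
STANDARD_TH_RA_RATIO = 5.0


@dataclass(frozen=True)
class GridSpec:
    """Isotropic voxel grid: shape (nx, ny, nz) and voxel side in mm."""

    shape: tuple[int, int, int]
    voxel_mm: float

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_mm**3 / 1000.0

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates (mm) relative to the grid center."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * self.voxel_mm for n in self.shape
        ]
        return np.meshgrid(*axes, indexing="ij")

    @classmethod
    def default(cls) -> "GridSpec":
        # 283 x 283 x 141 mm field of view at 4.42 mm voxels.
        return cls((64, 64, 32), 4.42)


@dataclass
class RegionalUptake:
    """Mean activity concentration (Bq/mL) per VOI for both isotopes."""

    lambda_th: np.ndarray  # shape (K,), index 0 = VOI label 1
    lambda_ra: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_th = np.asarray(self.lambda_th, dtype=float)
        self.lambda_ra = np.asarray(self.lambda_ra, dtype=float)
        if self.lambda_th.shape != self.lambda_ra.shape:
            raise ValueError("isotope uptake vectors must share length")
        if np.any(self.lambda_th < 0) or np.any(self.lambda_ra < 0):
            raise ValueError("regional uptake must be nonnegative")

    @property
    def n_regions(self) -> int:
        return len(self.lambda_th)

    def composite(self) -> np.ndarray:
        """The 2K-vector (Th block then Ra block)."""
        return np.concatenate([self.lambda_th, self.lambda_ra])


@dataclass(frozen=True)
class LumpyParams:
    """Parameters of the lumpy intra-regional heterogeneity texture."""

    mean_num_lumps: float
    lump_width_mm: float
    region: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_num_lumps < 0:
            raise ValueError("mean lump count must be >= 0")
        if self.lump_width_mm <= 0:
            raise ValueError("lump width must be positive")


@dataclass
class Phantom:
    """Digital phantom: VOI labels, tissue classes, and activity maps."""

    grid: GridSpec
    voi_labels: np.ndarray  # int, 0 outside body
    tissue_classes: np.ndarray  # 0 air / 1 soft / 2 bone
    activity_th: np.ndarray  # Bq/mL
    activity_ra: np.ndarray  # Bq/mL
    mu_ref: np.ndarray | None = None  # 1/cm at the reference energy
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shp = tuple(self.grid.shape)
        for name in ("voi_labels", "tissue_classes", "activity_th", "activity_ra"):
            arr = getattr(self, name)
            if arr.shape != shp:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shp}")
        if self.mu_ref is None:
            self.mu_ref = reference_mu_map(self.tissue_classes)

    @property
    def n_regions(self) -> int:
        return int(self.voi_labels.max())

    def region_mask(self, region: int) -> np.ndarray:
        return self.voi_labels == region

    def region_volumes_ml(self) -> np.ndarray:
        counts = np.bincount(self.voi_labels.ravel(), minlength=N_REGIONS + 1)
        return counts[1:] * self.grid.voxel_volume_ml

    def region_means(self, isotope: str) -> np.ndarray:
        """Voxel-mean activity concentration per VOI (Bq/mL)."""
        amap = self.activity(isotope)
        out = np.zeros(self.n_regions)
        for k in range(1, self.n_regions + 1):
            mask = self.voi_labels == k
            out[k - 1] = amap[mask].mean() if mask.any() else 0.0
        return out

    def activity(self, isotope: str) -> np.ndarray:
        if isotope == "Th227":
            return self.activity_th
        if isotope == "Ra223chain":
            return self.activity_ra
        raise ValueError(f"unknown isotope {isotope!r}")

    def total_activity_bq(self, isotope: str) -> float:
        return float(self.activity(isotope).sum() * self.grid.voxel_volume_ml)

    def copy(self) -> "Phantom":
        return Phantom(
            grid=self.grid,
            voi_labels=self.voi_labels.copy(),
            tissue_classes=self.tissue_classes.copy(),
            activity_th=self.activity_th.copy(),
            activity_ra=self.activity_ra.copy(),
            mu_ref=None if self.mu_ref is None else self.mu_ref.copy(),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Anatomy construction
# ---------------------------------------------------------------------------

# Default anatomy dimensions in mm (before body_scale).  Tuned to a male
# pelvis-sized torso that fits a 283 mm transaxial field of view.
_ANATOMY = {
    "body_semi_xy": (130.0, 95.0),
    "ring_center_y": -15.0,
    "ring_outer": (88.0, 72.0),
    "ring_inner": (58.0, 42.0),
    "ring_z": (-55.0, 35.0),
    "iliac_center": (0.0, -38.0, -10.0),
    "iliac_semi": (55.0, 38.0, 42.0),
    "gut_center_y": 50.0,
    "gut_semi_xy": (55.0, 28.0),
    "gut_z": (0.0, 60.0),
}


def _build_masks(grid: GridSpec, body_scale: float):
    x, y, z = grid.coords_mm()
    s = body_scale
    a = _ANATOMY
    bx, by = a["body_semi_xy"]
    # Axial extent leaves a small margin to the grid faces so that rigid
    # misregistration never pushes tissue out of the field of view.
    half_z = 0.46 * grid.shape[2] * grid.voxel_mm
    body = (
        ((x / (s * bx)) ** 2 + (y / (s * by)) ** 2 <= 1.0)
        & (np.abs(z) <= half_z)
    )

    cy = s * a["ring_center_y"]
    ox, oy = a["ring_outer"]
    ix, iy = a["ring_inner"]
    in_outer = (x / (s * ox)) ** 2 + ((y - cy) / (s * oy)) ** 2 <= 1.0
    in_inner = (x / (s * ix)) ** 2 + ((y - cy) / (s * iy)) ** 2 <= 1.0
    z0, z1 = (s * v for v in a["ring_z"])
    ring = in_outer & ~in_inner & (z >= z0) & (z <= z1)

    icx, icy, icz = (s * v for v in a["iliac_center"])
    sx, sy, sz = (s * v for v in a["iliac_semi"])
    iliac = ((x - icx) / sx) ** 2 + ((y - icy) / sy) ** 2 + (
        (z - icz) / sz
    ) ** 2 <= 1.0
    bone = (ring | iliac) & body

    gx, gy = a["gut_semi_xy"]
    gcy = s * a["gut_center_y"]
    gz0, gz1 = (s * v for v in a["gut_z"])
    gut = (
        ((x / (s * gx)) ** 2 + ((y - gcy) / (s * gy)) ** 2 <= 1.0)
        & (z >= gz0)
        & (z <= gz1)
        & body
        & ~bone
    )
    return body, bone, gut


def make_pelvic_phantom(
    lesion_diameter_mm: float = 33.75,
    uptake: RegionalUptake | None = None,
    body_scale: float = 1.0,
    grid: GridSpec | None = None,
    lesion_center_mm: tuple[float, float, float] | None = None,
) -> Phantom:
    """Build a four-VOI pelvic phantom with a spherical bone lesion.

    The lesion must lie entirely within the bone compartment; a lesion
    overflowing bone raises a ``ValueError`` naming the overflow.  When
    ``uptake`` is omitted the activity maps are zero.
    """
    if lesion_diameter_mm <= 0:
        raise ValueError("lesion diameter must be positive")
    grid = grid or GridSpec.default()
    body, bone, gut = _build_masks(grid, body_scale)
    if not body.any():
        raise ValueError("body does not intersect the grid")

    x, y, z = grid.coords_mm()
    if lesion_center_mm is None:
        lesion_center_mm = tuple(
            body_scale * v for v in _ANATOMY["iliac_center"]
        )
    cx, cy, cz = lesion_center_mm
    r = lesion_diameter_mm / 2.0
    lesion = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
    overflow = int((lesion & ~bone).sum())
    if overflow:
        raise ValueError(
            f"lesion (diameter {lesion_diameter_mm} mm at {lesion_center_mm}) "
            f"extends outside the bone compartment by {overflow} voxels"
        )

    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[body] = BACKGROUND
    labels[gut] = GUT
    labels[bone] = BONE
    labels[lesion] = LESION

    classes = np.zeros(grid.shape, dtype=np.int16)
    classes[body] = TISSUE_SOFT
    classes[bone] = TISSUE_BONE  # lesion voxels remain bone tissue

    act_th = np.zeros(grid.shape)
    act_ra = np.zeros(grid.shape)
    if uptake is not None:
        if uptake.n_regions != N_REGIONS:
            raise ValueError("uptake must have one entry per VOI")
        for k in range(1, N_REGIONS + 1):
            mask = labels == k
            act_th[mask] = uptake.lambda_th[k - 1]
            act_ra[mask] = uptake.lambda_ra[k - 1]

    return Phantom(
        grid=grid,
        voi_labels=labels,
        tissue_classes=classes,
        activity_th=act_th,
        activity_ra=act_ra,
        meta={
            "lesion_diameter_mm": lesion_diameter_mm,
            "lesion_center_mm": list(lesion_center_mm),
            "body_scale": body_scale,
        },
    )


def uptake_from_ratios(
    phantom: Phantom,
    ratios_th: np.ndarray,
    ratios_ra: np.ndarray,
    total_th_bq: float,
    total_ra_bq: float,
) -> RegionalUptake:
    """Scale concentration ratios to absolute Bq/mL hitting given totals.

    Each isotope's ratio vector is multiplied by the constant that makes
    the phantom-wide total activity of that isotope equal the target.
    """
    vols = phantom.region_volumes_ml()
    ratios_th = np.asarray(ratios_th, dtype=float)
    ratios_ra = np.asarray(ratios_ra, dtype=float)
    c_th = total_th_bq / float(ratios_th @ vols)
    c_ra = total_ra_bq / float(ratios_ra @ vols)
    return RegionalUptake(c_th * ratios_th, c_ra * ratios_ra)


def standard_uptake(
    phantom: Phantom,
    th_ra_ratio: float = STANDARD_TH_RA_RATIO,
    total_th_bq: float = STANDARD_TOTAL_TH_BQ,
    lesion_to_bone_ratio: float | None = None,
) -> RegionalUptake:
    """Standard uptake pattern scaled to absolute activity.

    Total Th-227 activity is ``total_th_bq`` and total Ra-223 activity is
    ``total_th_bq / th_ra_ratio``.  ``lesion_to_bone_ratio`` overrides the
    lesion:bone concentration ratio of both isotopes, holding the other
    regional ratios at their standard values.
    """
    ratios_th = TABLE_RATIOS["Th227"].copy()
    ratios_ra = TABLE_RATIOS["Ra223chain"].copy()
    if lesion_to_bone_ratio is not None:
        ratios_th[LESION - 1] = lesion_to_bone_ratio * ratios_th[BONE - 1]
        ratios_ra[LESION - 1] = lesion_to_bone_ratio * ratios_ra[BONE - 1]
    return uptake_from_ratios(
        phantom, ratios_th, ratios_ra, total_th_bq, total_th_bq / th_ra_ratio
    )


# ---------------------------------------------------------------------------
# Intra-regional heterogeneity (lumpy texture and mixture)
# ---------------------------------------------------------------------------


def _lumpy_field(
    grid: GridSpec, mask: np.ndarray, params: LumpyParams, rng: np.random.Generator
) -> np.ndarray | None:
    """Sum-of-Gaussians texture on the region support; None if no lumps."""
    n_lumps = int(rng.poisson(params.mean_num_lumps))
    if n_lumps == 0:
        return None
    idx = np.argwhere(mask)
    choice = rng.integers(0, len(idx), size=n_lumps)
    centers = (idx[choice] + rng.uniform(-0.5, 0.5, size=(n_lumps, 3)))  # voxels
    sigma_vox = params.lump_width_mm / grid.voxel_mm
    half = int(np.ceil(4.0 * sigma_vox))  # 4-sigma truncation
    field_ = np.zeros(grid.shape)
    norm = 1.0 / (sigma_vox * np.sqrt(2.0 * np.pi)) ** 3
    nx, ny, nz = grid.shape
    for c in centers:
        lo = np.maximum(np.ceil(c - half).astype(int), 0)
        hi = np.minimum(np.floor(c + half).astype(int) + 1, [nx, ny, nz])
        if np.any(lo >= hi):
            continue
        ax = [np.arange(lo[d], hi[d]) - c[d] for d in range(3)]
        g = (
            np.exp(-0.5 * (ax[0] / sigma_vox) ** 2)[:, None, None]
            * np.exp(-0.5 * (ax[1] / sigma_vox) ** 2)[None, :, None]
            * np.exp(-0.5 * (ax[2] / sigma_vox) ** 2)[None, None, :]
        )
        field_[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += norm * g
    field_ *= mask
    return field_


def apply_lumpy_heterogeneity(
    phantom: Phantom, params: LumpyParams, rng: np.random.Generator | None = None
) -> Phantom:
    """Replace one region's homogeneous uptake by a lumpy texture.

    The lump count is Poisson, centers are uniform over the region
    support, and the texture magnitude is rescaled per isotope so the
    region's voxel-mean uptake matches the homogeneous value exactly.
    If zero lumps are drawn, the region is left homogeneous.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    mask = phantom.region_mask(params.region)
    if not mask.any():
        raise ValueError(f"region {params.region} is empty")
    out = phantom.copy()
    field_ = _lumpy_field(phantom.grid, mask, params, rng)
    if field_ is None:
        return out  # documented fallback: homogeneous region
    field_mean = field_[mask].mean()
    if field_mean <= 0:
        return out
    for name in ("activity_th", "activity_ra"):
        amap = getattr(out, name)
        target_mean = amap[mask].mean()
        amap[mask] = field_[mask] * (target_mean / field_mean)
    return out


def mix_heterogeneity(f_het: Phantom, f_hom: Phantom, weight: float) -> Phantom:
    """Voxelwise mixture W*heterogeneous + (1-W)*homogeneous."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("mixture weight must be in [0, 1]")
    if f_het.grid != f_hom.grid:
        raise ValueError("phantoms must share the same grid")
    if not np.array_equal(f_het.voi_labels, f_hom.voi_labels):
        raise ValueError("phantoms must share VOI labels")
    out = f_hom.copy()
    out.activity_th = weight * f_het.activity_th + (1 - weight) * f_hom.activity_th
    out.activity_ra = weight * f_het.activity_ra + (1 - weight) * f_hom.activity_ra
    out.meta["mixture_weight"] = weight
    return out


# ---------------------------------------------------------------------------
# Virtual imaging trial population
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VITConfig:
    """Population distributions of the virtual imaging trial."""

    grid: GridSpec = field(default_factory=GridSpec.default)
    lesion_diameter_mean_mm: float = 33.75
    lesion_diameter_sd_mm: float = 12.64
    lesion_diameter_min_mm: float = 10.0
    uptake_cv: float = 0.10  # relative SD of each regional ratio
    th_ra_ratio: float = STANDARD_TH_RA_RATIO
    total_th_bq: float = STANDARD_TOTAL_TH_BQ
    body_scale_log_sd: float = 0.08  # lognormal, median 1
    max_retries: int = 200


def _sample_lesion(
    grid: GridSpec,
    bone: np.ndarray,
    rng: np.random.Generator,
    cfg: VITConfig,
) -> tuple[float, tuple[float, float, float]]:
    """Draw a (diameter, center) pair with the lesion contained in bone."""
    # Distance (voxels) from each bone voxel to the nearest non-bone voxel
    # bounds the largest sphere that fits when centered there.
    dist = ndimage.distance_transform_edt(bone)
    x, y, z = grid.coords_mm()
    for _ in range(cfg.max_retries):
        d = rng.normal(cfg.lesion_diameter_mean_mm, cfg.lesion_diameter_sd_mm)
        if d < cfg.lesion_diameter_min_mm:
            continue
        r_vox = d / 2.0 / grid.voxel_mm
        eligible = np.argwhere(dist >= r_vox + 1.0)  # +1 voxel margin
        if len(eligible) == 0:
            continue
        i, j, k = eligible[rng.integers(0, len(eligible))]
        return d, (float(x[i, j, k]), float(y[i, j, k]), float(z[i, j, k]))
    raise RuntimeError(
        "could not place a lesion inside bone after "
        f"{cfg.max_retries} attempts"
    )


def sample_vit_population(
    n_patients: int,
    seed: int,
    config: VITConfig | None = None,
) -> list[tuple[Phantom, RegionalUptake]]:
    """Sample a virtual patient population.

    Per patient: body scale ~ lognormal(median 1), lesion diameter ~
    truncated Gaussian, lesion center uniform over bone voxels that
    contain the sphere, and each regional concentration ratio of each
    isotope drawn independently around its standard value with 10%
    relative SD (truncated at zero).  Absolute scaling uses the fixed
    nominal conversion of the standard pattern, so the population-mean
    total-activity ratio of Th-227 to Ra-223 equals the configured value.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    cfg = config or VITConfig()
    master = np.random.SeedSequence(seed)
    out: list[tuple[Phantom, RegionalUptake]] = []
    for child in master.spawn(n_patients):
        rng = np.random.default_rng(child)
        body_scale = float(np.exp(rng.normal(0.0, cfg.body_scale_log_sd)))
        _, bone, _ = _build_masks(cfg.grid, body_scale)
        diameter, center = _sample_lesion(cfg.grid, bone, rng, cfg)

        template = make_pelvic_phantom(
            diameter, uptake=None, body_scale=body_scale, grid=cfg.grid,
            lesion_center_mm=center,
        )
        nominal = standard_uptake(
            template, th_ra_ratio=cfg.th_ra_ratio, total_th_bq=cfg.total_th_bq
        )
        lam_th = np.maximum(
            rng.normal(nominal.lambda_th, cfg.uptake_cv * nominal.lambda_th), 0.0
        )
        lam_ra = np.maximum(
            rng.normal(nominal.lambda_ra, cfg.uptake_cv * nominal.lambda_ra), 0.0
        )
        uptake = RegionalUptake(lam_th, lam_ra)
        phantom = make_pelvic_phantom(
            diameter, uptake=uptake, body_scale=body_scale, grid=cfg.grid,
            lesion_center_mm=center,
        )
        out.append((phantom, uptake))
    return out


# ---------------------------------------------------------------------------
# Rigid misregistration
# ---------------------------------------------------------------------------


def apply_rigid_misregistration(
    phantom: Phantom,
    shift_voxels: tuple[float, float] = (0.0, 0.0),
    rotation_deg_about_y: float = 0.0,
) -> Phantom:
    """Shift/rotate the patient while keeping the VOI labels fixed.

    Activity maps and the attenuation map are resampled trilinearly
    (tissue classes nearest-neighbor); the VOI label map is deliberately
    NOT transformed, emulating VOIs segmented from a CT scan that no
    longer matches the patient position during the emission scan.
    Raises if the transformed body would be clipped by the grid.
    """
    dx, dy = shift_voxels
    theta = np.deg2rad(rotation_deg_about_y)
    if dx == 0 and dy == 0 and theta == 0:
        return phantom.copy()
    # Rotation about the y axis mixes x and z; build the pull-back affine.
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    center = (np.asarray(phantom.grid.shape) - 1) / 2.0
    shift = np.array([dx, dy, 0.0])
    # output voxel v maps to input R^{-1}(v - center - shift) + center
    matrix = rot.T
    offset = center - matrix @ (center + shift)

    def _warp(arr: np.ndarray, order: int) -> np.ndarray:
        return ndimage.affine_transform(
            arr, matrix, offset=offset, order=order, mode="constant", cval=0.0
        )

    out = phantom.copy()
    out.activity_th = np.maximum(_warp(phantom.activity_th, 1), 0.0)
    out.activity_ra = np.maximum(_warp(phantom.activity_ra, 1), 0.0)
    out.mu_ref = np.maximum(_warp(phantom.mu_ref, 1), 0.0)
    out.tissue_classes = _warp(
        phantom.tissue_classes.astype(np.float64), 0
    ).astype(np.int16)
    out.meta["misregistration"] = {
        "shift_voxels": [dx, dy],
        "rotation_deg_about_y": rotation_deg_about_y,
    }

    # The body must stay inside the grid transaxially.  The axial (z)
    # edges are exempt: the body spans the axial field of view by design
    # (patients extend beyond it), so axial truncation is expected.
    edge = np.zeros(phantom.grid.shape, dtype=bool)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    if np.any(out.mu_ref[edge] > 1e-6):
        raise ValueError("transform clips the body at the grid boundary")
    return out


# ---------------------------------------------------------------------------
# NIfTI + manifest I/O
# ---------------------------------------------------------------------------


def save_phantom(phantom: Phantom, directory: str | Path) -> None:
    """Write the phantom as NIfTI volumes plus a JSON manifest."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag([phantom.grid.voxel_mm] * 3 + [1.0])
    volumes = {
        "voi_labels": phantom.voi_labels.astype(np.int16),
        "tissue_classes": phantom.tissue_classes.astype(np.int16),
        "activity_th": phantom.activity_th,
        "activity_ra": phantom.activity_ra,
        "mu_ref": phantom.mu_ref,
    }
    for name, vol in volumes.items():
        nib.save(nib.Nifti1Image(vol, affine), directory / f"{name}.nii")
    manifest = {
        "grid": {"shape": list(phantom.grid.shape), "voxel_mm": phantom.grid.voxel_mm},
        "voi_names": {str(k): v for k, v in VOI_NAMES.items()},
        "meta": phantom.meta,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_phantom(directory: str | Path) -> Phantom:
    import nibabel as nib

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    grid = GridSpec(tuple(manifest["grid"]["shape"]), manifest["grid"]["voxel_mm"])

    def _read(name: str) -> np.ndarray:
        return np.asarray(nib.load(directory / f"{name}.nii").dataobj)

    return Phantom(
        grid=grid,
        voi_labels=_read("voi_labels").astype(np.int16),
        tissue_classes=_read("tissue_classes").astype(np.int16),
        activity_th=_read("activity_th").astype(float),
        activity_ra=_read("activity_ra").astype(float),
        mu_ref=_read("mu_ref").astype(float),
        meta=manifest.get("meta", {}),
    )
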