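"""Synthetic skull phantom, projection, setup-error motion, and noise.

Stands in for a head-and-neck phantom (a human skull with lower-density
filling in the cranium and the oral/nasal cavities): an ellipsoidal bone
shell enclosing soft tissue, with two air cavities carved into the lower
anterior region.  Two beam qualities project it:

* ``kv`` — kilovoltage-like attenuation coefficients, high bone/soft
  contrast: the DRR surrogate;
* ``mv`` — megavoltage-like coefficients with a much smaller bone-to-soft
  ratio (Compton-dominated): the EPID surrogate, further degraded by
  detector blur and additive noise.

Projection is parallel-beam along the view axis; beam divergence is
absorbed into the geometric magnification factor, which is how the
detector pixel pitch of the output images is derived
(``voxel_mm * magnification / detector_upsample``).

Setup errors are applied as per-view 2D rigid motions of the megavoltage
projection (AP: columns carry X, rows carry Z, in-plane rotation carries
rz; LAT: columns carry Y, rows carry Z, rotation carries rx).  This keeps
the recovery problem exactly observable by a 2D rigid registration, which
is what the pipeline estimates; a secondary volumetric mode rotates the
label volume itself before projecting, for qualitative realism only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter, rotate as nd_rotate, shift as nd_shift, zoom


from .image_core import IntensityGrid, ProjectionGeometry, ViewLabel
from .mi_register import RigidTransform2D, SetupError3D, warp_image

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "SimulatedCase",
    "PhantomGeometryError",
    "OverlapError",
    "AIR",
    "SOFT",
    "BONE",
    "CAVITY",
    "build_phantom",
    "project",
    "apply_view_motion",
    "apply_volume_motion",
    "corrupt",
    "make_case",
]

AIR, SOFT, BONE, CAVITY = 0, 1, 2, 3

#: Intensity ceiling of the simulated 16-bit detector.
FULL_SCALE = 65535.0


class PhantomGeometryError(ValueError):
    """Phantom ellipsoids violate their containment requirements."""


class OverlapError(ValueError):
    """A rigid motion leaves less than the required image overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric skull phantom and per-beam attenuation.

    Semi-axes and centres are in mm in patient coordinates
    (X medio-lateral, Y anterior-posterior, Z cranio-caudal), origin at the
    volume centre.  Attenuation coefficients are in 1/mm; the kv
    bone-to-soft ratio must exceed the mv ratio, which must exceed 1 —
    megavoltage contrast is intrinsically lower.

    Defaults give a 128³ volume of 2 mm voxels (256 mm extent), an 8 mm
    calvarial shell, and linear-attenuation values in the range tabulated
    for cortical bone and soft tissue at diagnostic vs. therapy energies.
    """

    shape_vox: tuple[int, int, int] = (128, 128, 128)
    voxel_mm: float = 2.0
    outer_semi_mm: tuple[float, float, float] = (70.0, 85.0, 95.0)
    inner_semi_mm: tuple[float, float, float] = (62.0, 77.0, 87.0)
    nasal_center_mm: tuple[float, float, float] = (0.0, 40.0, -30.0)
    nasal_semi_mm: tuple[float, float, float] = (10.0, 16.0, 12.0)
    oral_center_mm: tuple[float, float, float] = (0.0, 30.0, -55.0)
    oral_semi_mm: tuple[float, float, float] = (14.0, 16.0, 10.0)
    mu_bone_kv: float = 0.060
    mu_soft_kv: float = 0.020
    mu_bone_mv: float = 0.008
    mu_soft_mv: float = 0.005
    detector_upsample: int = 2

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.shape_vox):
            raise ValueError("volume must be at least 8 voxels per axis")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be > 0")
        if not all(i < o for i, o in zip(self.inner_semi_mm, self.outer_semi_mm)):
            raise PhantomGeometryError(
                "inner ellipsoid must be strictly inside the outer (nonzero shell)"
            )
        if min(self.inner_semi_mm) <= 0:
            raise PhantomGeometryError("inner semi-axes must be positive")
        ratio_kv = self.mu_bone_kv / self.mu_soft_kv
        ratio_mv = self.mu_bone_mv / self.mu_soft_mv
        if not ratio_kv > ratio_mv > 1.0:
            raise ValueError(
                "attenuation ratios must satisfy kv bone/soft > mv bone/soft > 1"
            )
        if self.detector_upsample < 1:
            raise ValueError("detector_upsample must be >= 1")

    def mu_lookup(self, beam: str) -> np.ndarray:
        """Per-label attenuation (1/mm) for the given beam quality."""
        if beam == "kv":
            soft, bone = self.mu_soft_kv, self.mu_bone_kv
        elif beam == "mv":
            soft, bone = self.mu_soft_mv, self.mu_bone_mv
        else:
            raise ValueError(f"unknown beam quality {beam!r}")
        return np.array([0.0, soft, bone, 0.0])  # air, soft, bone, cavity


@dataclass(frozen=True)
class NoiseSpec:
    """EPID degradation: Gaussian detector blur then additive noise.

    ``noise_sigma_frac`` is the noise standard deviation as a fraction of
    the image dynamic range.  A fixed seed makes the corruption
    byte-reproducible.
    """

    psf_sigma_px: float = 1.0
    noise_sigma_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_px < 0 or self.noise_sigma_frac < 0:
            raise ValueError("blur and noise parameters must be non-negative")


def _ellipsoid_mask(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: tuple[float, float, float],
    semi: tuple[float, float, float],
) -> np.ndarray:
    q = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semi))
    return q <= 1.0


def build_phantom(spec: PhantomSpec) -> np.ndarray:
    """Voxelise the phantom into a uint8 label volume.

    Axes are (X, Y, Z) in patient coordinates.  Labels: 0 air, 1 soft
    tissue, 2 bone, 3 air cavity.  Deterministic — the same spec always
    yields the identical volume.  Raises if a cavity pokes out of the head.
    """
    nx, ny, nz = spec.shape_vox
    ax = (np.arange(nx) - (nx - 1) / 2.0) * spec.voxel_mm
    ay = (np.arange(ny) - (ny - 1) / 2.0) * spec.voxel_mm
    az = (np.arange(nz) - (nz - 1) / 2.0) * spec.voxel_mm
    coords = (
        ax[:, None, None],
        ay[None, :, None],
        az[None, None, :],
    )
    origin = (0.0, 0.0, 0.0)
    outer = _ellipsoid_mask(coords, origin, spec.outer_semi_mm)
    inner = _ellipsoid_mask(coords, origin, spec.inner_semi_mm)
    cavities = _ellipsoid_mask(
        coords, spec.nasal_center_mm, spec.nasal_semi_mm
    ) | _ellipsoid_mask(coords, spec.oral_center_mm, spec.oral_semi_mm)

    if np.any(cavities & ~outer):
        raise PhantomGeometryError("a cavity extends outside the head")

    labels = np.zeros(spec.shape_vox, dtype=np.uint8)
    labels[outer] = BONE
    labels[inner] = SOFT
    labels[cavities] = CAVITY
    return labels


def project(
    volume: np.ndarray,
    beam: str,
    view: ViewLabel | str,
    spec: PhantomSpec,
    geometry: ProjectionGeometry | None = None,
) -> IntensityGrid:
    """Parallel-beam exp-attenuation projection of the label volume.

    AP integrates along the patient Y axis (image rows = Z, columns = X);
    LAT integrates along X (rows = Z, columns = Y).  The transmitted
    fraction ``exp(-∫mu dl)`` is rescaled to the 16-bit detector range and
    linearly upsampled by ``spec.detector_upsample``.  The pixel pitch of
    the result is ``voxel_mm * magnification / detector_upsample``.
    """
    geometry = geometry or ProjectionGeometry()
    view = ViewLabel(view)
    mu = spec.mu_lookup(beam)
    integral = mu[volume].sum(axis=1 if view is ViewLabel.AP else 0) * spec.voxel_mm
    img = np.exp(-integral).T * FULL_SCALE  # rows = Z, cols = X (AP) or Y (LAT)
    k = spec.detector_upsample
    if k > 1:
        img = zoom(img, k, order=1, mode="nearest", grid_mode=True)
    spacing = spec.voxel_mm * geometry.magnification / k
    return IntensityGrid(img, spacing_px_mm=spacing)


def apply_view_motion(
    img: IntensityGrid,
    motion: RigidTransform2D,
    min_overlap: float = 0.75,
) -> IntensityGrid:
    """Apply an in-plane rigid motion by bilinear resampling.

    Pixels pulled from outside the frame replicate the nearest edge (the
    frame edge of a portal image is unattenuated background).  Raises
    :class:`OverlapError` when less than ``min_overlap`` of the frame
    remains covered by true image content.  Integer translations are
    lossless in the overlap region.
    """
    marker = warp_image(np.ones(img.shape), motion, mode="constant", cval=0.0)
    inside = float((marker > 0.999).mean())
    if inside < min_overlap:
        raise OverlapError(
            f"motion leaves {inside:.0%} of the frame covered; need {min_overlap:.0%}"
        )
    moved = warp_image(img.as_float(), motion, mode="nearest")
    return IntensityGrid(moved, spacing_px_mm=img.spacing_px_mm)


def corrupt(img: IntensityGrid, noise: NoiseSpec) -> IntensityGrid:
    """Degrade a clean megavoltage projection into an EPID-like image.

    Gaussian blur with ``psf_sigma_px`` models the detector point-spread;
    seeded additive Gaussian noise with standard deviation
    ``noise_sigma_frac`` of the image dynamic range models quantum and
    electronic noise.  Output is clipped to the input value range.
    """
    vals = img.as_float()
    vmin, vmax = float(vals.min()), float(vals.max())
    out = gaussian_filter(vals, noise.psf_sigma_px) if noise.psf_sigma_px > 0 else vals.copy()
    if noise.noise_sigma_frac > 0 and vmax > vmin:
        rng = np.random.default_rng(noise.seed)
        out = out + rng.normal(0.0, noise.noise_sigma_frac * (vmax - vmin), vals.shape)
        out = np.clip(out, vmin, vmax)
    return IntensityGrid(out, spacing_px_mm=img.spacing_px_mm)


def apply_volume_motion(
    volume: np.ndarray, error: SetupError3D, spec: PhantomSpec
) -> np.ndarray:
    """Rigidly move the label volume itself (qualitative-realism mode).

    Nearest-neighbour resampling keeps the labels integral: translate by
    the couch error, rotate about the Z axis (rz, in the X-Y plane) and
    the X axis (rx, in the Y-Z plane) around the volume centre.  Unlike
    the per-view 2D motions this introduces out-of-plane effects that a
    2D rigid registration cannot fully recover, so no recovery guarantee
    attaches to images projected from the result.
    """
    out = volume
    if error.rz_deg != 0.0:
        out = nd_rotate(out, error.rz_deg, axes=(0, 1), reshape=False, order=0, cval=AIR)
    if error.rx_deg != 0.0:
        out = nd_rotate(out, error.rx_deg, axes=(1, 2), reshape=False, order=0, cval=AIR)
    shift_vox = (
        error.tx_mm / spec.voxel_mm,
        error.ty_mm / spec.voxel_mm,
        error.tz_mm / spec.voxel_mm,
    )
    if any(s != 0.0 for s in shift_vox):
        out = nd_shift(out, shift_vox, order=0, cval=AIR)
    return out.astype(np.uint8)


@dataclass(frozen=True)
class SimulatedCase:
    """One simulated treatment fraction: four images plus ground truth."""

    drr_ap: IntensityGrid
    drr_lat: IntensityGrid
    epid_ap: IntensityGrid
    epid_lat: IntensityGrid
    truth: SetupError3D
    ap_motion: RigidTransform2D
    lat_motion: RigidTransform2D


def motions_for_error(
    error: SetupError3D, px_per_mm: float
) -> tuple[RigidTransform2D, RigidTransform2D]:
    """Per-view 2D motions implied by a couch setup error.

    AP: columns carry X, rows carry Z, in-plane rotation carries rz.
    LAT: columns carry Y, rows carry Z, rotation carries rx.  Millimetres
    are scaled to detector pixels by ``px_per_mm`` (magnification over
    pixel pitch).
    """
    ap = RigidTransform2D(
        t_col_px=error.tx_mm * px_per_mm,
        t_row_px=error.tz_mm * px_per_mm,
        theta_deg=error.rz_deg,
    )
    lat = RigidTransform2D(
        t_col_px=error.ty_mm * px_per_mm,
        t_row_px=error.tz_mm * px_per_mm,
        theta_deg=error.rx_deg,
    )
    return ap, lat


def make_case(
    error: SetupError3D,
    spec: PhantomSpec | None = None,
    noise: NoiseSpec | None = None,
    geometry: ProjectionGeometry | None = None,
    volume: np.ndarray | None = None,
) -> SimulatedCase:
    """Simulate one orthogonal DRR/EPID image set with a known setup error.

    DRRs are clean kilovoltage projections at zero error; EPIDs are
    megavoltage projections moved by the per-view motions implied by
    ``error`` and then blurred/noised.  The AP and LAT views receive
    independent noise streams derived from ``noise.seed``.  A prebuilt
    label ``volume`` may be passed to amortise phantom construction across
    cases.
    """
    spec = spec or PhantomSpec()
    noise = noise or NoiseSpec()
    geometry = geometry or ProjectionGeometry()
    if max(abs(error.tx_mm), abs(error.ty_mm), abs(error.tz_mm)) > 10.0:
        raise ValueError("translations beyond +/-10 mm are outside the study range")
    if max(abs(error.rx_deg), abs(error.rz_deg)) > 3.0:
        raise ValueError("rotations beyond +/-3 degrees are outside the study range")

    if volume is None:
        volume = build_phantom(spec)
    drr_ap = project(volume, "kv", ViewLabel.AP, spec, geometry)
    drr_lat = project(volume, "kv", ViewLabel.LAT, spec, geometry)
    mv_ap = project(volume, "mv", ViewLabel.AP, spec, geometry)
    mv_lat = project(volume, "mv", ViewLabel.LAT, spec, geometry)

    px_per_mm = geometry.magnification / drr_ap.spacing_px_mm
    ap_motion, lat_motion = motions_for_error(error, px_per_mm)
    epid_ap = corrupt(apply_view_motion(mv_ap, ap_motion), noise)
    epid_lat = corrupt(apply_view_motion(mv_lat, lat_motion), replace(noise, seed=noise.seed + 1))
    return SimulatedCase(
        drr_ap=drr_ap,
        drr_lat=drr_lat,
        epid_ap=epid_ap,
        epid_lat=epid_lat,
        truth=error,
        ap_motion=ap_motion,
        lat_motion=lat_motion,
    )
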