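"""Mutual-information rigid registration of orthogonal portal-image pairs.

Each DRR/EPID view pair is aligned by a 2D rigid transform (in-plane
translation plus rotation about the image centre) that maximises the
mutual information

    I(A, B) = H(A) + H(B) - H(A, B)

in bits, where H is the Shannon entropy of the min-max binned intensity
histogram and H(A, B) the joint entropy.  MI needs no intensity
correspondence between the kilovoltage-quality reference and the
megavoltage acquisition, which is why it is the standard cross-modality
similarity here.

The optimiser is deterministic: an exhaustive coarse grid over integer
pixel translations and coarse rotation steps, followed by Powell
refinement in continuous coordinates.  Out-of-bounds pixels created by
resampling are excluded from the joint histogram rather than zero-filled
(zero fill manufactures spurious MI).

The two orthogonal views are finally fused into a 3D couch-space setup
error: anteroposterior (AP) columns give the medio-lateral X shift,
lateral (LAT) columns the anterior-posterior Y shift, and the shared row
axis gives the cranio-caudal Z shift (averaged between views), each scaled
from detector pixels to isocenter millimetres by the magnification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform
from scipy.optimize import minimize

from .image_core import (
    IntensityGrid,
    ProjectionGeometry,
    detector_px_to_isocenter_mm,
    isocenter_mm_to_detector_px,
)

__all__ = [
    "RigidTransform2D",
    "MIConfig",
    "SetupError3D",
    "RegistrationError",
    "histogram_entropy",
    "mutual_information",
    "register_view",
    "fuse_views",
    "warp_image",
]


class RegistrationError(RuntimeError):
    """No admissible transform candidate (all rejected for low overlap)."""


def _rot_rowcol(theta_deg: float) -> np.ndarray:
    """Rotation matrix acting on (row, col) vectors.

    Positive angles rotate content counter-clockwise in array coordinates
    (col' = c*col - s*row with the row axis pointing down the screen).
    """
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, s], [-s, c]])


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid motion: rotate about the image centre, then translate.

    Maps a pixel p = (row, col) to ``R(p - c) + c + t`` where c is the
    image centre and t = (t_row_px, t_col_px).
    """

    t_col_px: float = 0.0
    t_row_px: float = 0.0
    theta_deg: float = 0.0

    @property
    def t_rowcol(self) -> np.ndarray:
        return np.array([self.t_row_px, self.t_col_px], dtype=np.float64)

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return self ∘ other (apply ``other`` first)."""
        t = _rot_rowcol(self.theta_deg) @ other.t_rowcol + self.t_rowcol
        return RigidTransform2D(
            t_col_px=float(t[1]),
            t_row_px=float(t[0]),
            theta_deg=self.theta_deg + other.theta_deg,
        )

    def inverse(self) -> "RigidTransform2D":
        t = -_rot_rowcol(-self.theta_deg) @ self.t_rowcol
        return RigidTransform2D(
            t_col_px=float(t[1]), t_row_px=float(t[0]), theta_deg=-self.theta_deg
        )


def warp_image(
    values: np.ndarray,
    transform: RigidTransform2D,
    mode: str = "constant",
    cval: float = np.nan,
    order: int = 1,
) -> np.ndarray:
    """Resample ``values`` under ``transform`` (bilinear by default).

    Output pixel q takes the input value at T^-1(q); pixels mapping outside
    the input are filled per ``mode``/``cval`` (NaN marks them for
    exclusion downstream).
    """
    arr = np.asarray(values, dtype=np.float64)
    c = (np.array(arr.shape, dtype=np.float64) - 1.0) / 2.0
    r_inv = _rot_rowcol(-transform.theta_deg)
    offset = c - r_inv @ (c + transform.t_rowcol)
    return affine_transform(
        arr, r_inv, offset=offset, order=order, mode=mode, cval=cval
    )


@dataclass(frozen=True)
class MIConfig:
    """Mutual-information registration settings.

    The coarse grid spans +/- ``grid_t_mm`` (isocenter mm, converted to
    detector pixels) in each translation at ``grid_step_px`` steps and
    +/- ``grid_r_deg`` at ``grid_step_deg`` steps; Powell then refines with
    tolerance ``refine_tol``.  Candidates with less than ``min_overlap`` of
    pixels in the resampled overlap are rejected.
    """

    n_bins: int = 64
    grid_t_mm: float = 10.0
    grid_r_deg: float = 3.0
    grid_step_px: int = 1
    grid_step_deg: float = 0.5
    refine_tol: float = 1e-3
    min_overlap: float = 0.25

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.grid_t_mm <= 0 or self.grid_r_deg <= 0:
            raise ValueError("search bounds must be positive")
        if self.grid_step_px < 1 or self.grid_step_deg <= 0:
            raise ValueError("grid steps must be positive")


@dataclass(frozen=True)
class SetupError3D:
    """Couch-space rigid setup error.

    Translations along the patient axes X (medio-lateral), Y
    (anterior-posterior), Z (cranio-caudal) in mm; in-plane rotations of
    the lateral view (rx) and anteroposterior view (rz) in degrees.
    """

    tx_mm: float = 0.0
    ty_mm: float = 0.0
    tz_mm: float = 0.0
    rx_deg: float = 0.0
    rz_deg: float = 0.0

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.tx_mm, self.ty_mm, self.tz_mm, self.rx_deg, self.rz_deg)


# ---------------------------------------------------------------------------
# Entropy and mutual information
# ---------------------------------------------------------------------------


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def histogram_entropy(img: IntensityGrid | np.ndarray, n_bins: int = 64) -> float:
    """Shannon entropy (bits) of the min-max binned intensity histogram.

    Intensities are rescaled to the bin range and hard-binned; a constant
    image has zero entropy, and 0*log(0) terms are dropped.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = img.as_float() if isinstance(img, IntensityGrid) else np.asarray(img, float)
    counts, _ = np.histogram(vals.ravel(), bins=n_bins)
    return _entropy_from_counts(counts)


def mutual_information(
    a: IntensityGrid | np.ndarray, b: IntensityGrid | np.ndarray, n_bins: int = 64
) -> float:
    """Mutual information I(A,B) = H(A) + H(B) - H(A,B) in bits.

    Both marginal entropies are computed from the joint histogram so that
    I(A, A) equals H(A) exactly and the value is non-negative up to
    floating error.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    va = (a.as_float() if isinstance(a, IntensityGrid) else np.asarray(a, float)).ravel()
    vb = (b.as_float() if isinstance(b, IntensityGrid) else np.asarray(b, float)).ravel()
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    joint, _, _ = np.histogram2d(va, vb, bins=n_bins)
    h_a = _entropy_from_counts(joint.sum(axis=1))
    h_b = _entropy_from_counts(joint.sum(axis=0))
    h_ab = _entropy_from_counts(joint.ravel())
    return h_a + h_b - h_ab


def _bin_indices(
    values: np.ndarray, n_bins: int, vmin: float, vmax: float
) -> np.ndarray:
    """Hard bin indices in [0, n_bins-1]; NaN pixels get -1."""
    out = np.full(values.shape, -1, dtype=np.int32)
    valid = np.isfinite(values)
    if vmax > vmin:
        scaled = (values[valid] - vmin) * (n_bins / (vmax - vmin))
        out[valid] = np.clip(scaled.astype(np.int32), 0, n_bins - 1)
    else:
        out[valid] = 0
    return out


def _mi_from_codes(ia: np.ndarray, ib: np.ndarray, n_bins: int) -> float:
    valid = (ia >= 0) & (ib >= 0)
    if not valid.any():
        return -np.inf
    codes = ia[valid].astype(np.int64) * n_bins + ib[valid]
    joint = np.bincount(codes, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    return (
        _entropy_from_counts(joint.sum(axis=1))
        + _entropy_from_counts(joint.sum(axis=0))
        - _entropy_from_counts(joint.ravel())
    )


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


def register_view(
    reference: IntensityGrid,
    moving: IntensityGrid,
    cfg: MIConfig | None = None,
    geometry: ProjectionGeometry | None = None,
) -> tuple[RigidTransform2D, float]:
    """Estimate the rigid motion carrying ``reference`` onto ``moving``.

    Deterministic two-stage search: for each coarse rotation angle the
    reference is resampled once, and every integer-pixel translation on the
    grid is scored by MI over the overlap (a pure array shift, no further
    interpolation); Powell then refines (t_col, t_row, theta) continuously
    from the best grid node.  Returns the transform and the attained MI.

    Candidates whose resampled overlap covers less than ``cfg.min_overlap``
    of the frame are rejected; if every candidate is rejected a
    :class:`RegistrationError` is raised.
    """
    cfg = cfg or MIConfig()
    geometry = geometry or ProjectionGeometry()
    if reference.shape != moving.shape:
        raise ValueError("reference and moving images must share a shape")

    spacing = reference.spacing_px_mm
    t_px = int(round(isocenter_mm_to_detector_px(cfg.grid_t_mm, geometry, spacing)))
    nb = cfg.n_bins
    ref = reference.as_float()
    mov = moving.as_float()
    rmin, rmax = float(ref.min()), float(ref.max())
    mov_idx = _bin_indices(mov, nb, float(mov.min()), float(mov.max()))
    n_total = mov.size
    min_px = cfg.min_overlap * n_total

    n_rot = int(round(cfg.grid_r_deg / cfg.grid_step_deg))
    thetas = np.arange(-n_rot, n_rot + 1) * cfg.grid_step_deg
    shifts = range(-t_px, t_px + 1, cfg.grid_step_px)

    best_mi, best = -np.inf, None
    nr, nc = ref.shape
    for th in thetas:
        rot = warp_image(ref, RigidTransform2D(theta_deg=float(th)))
        rot_idx = _bin_indices(rot, nb, rmin, rmax)
        for dr in shifts:
            r0, r1 = max(0, dr), nr + min(0, dr)
            if r1 - r0 <= 0:
                continue
            for dc in shifts:
                c0, c1 = max(0, dc), nc + min(0, dc)
                if c1 - c0 <= 0:
                    continue
                ia = rot_idx[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
                ib = mov_idx[r0:r1, c0:c1]
                valid = ia >= 0
                if valid.sum() < min_px:
                    continue
                mi = _mi_from_codes(ia[valid], ib[valid], nb)
                if mi > best_mi:
                    best_mi, best = mi, (dc, dr, float(th))
    if best is None:
        raise RegistrationError(
            "every grid candidate left less than the minimum overlap"
        )

    def neg_mi(params: np.ndarray) -> float:
        tc, tr, th = params
        w = warp_image(ref, RigidTransform2D(tc, tr, th))
        widx = _bin_indices(w, nb, rmin, rmax)
        if (widx >= 0).sum() < min_px:
            return 1e6
        return -_mi_from_codes(widx, mov_idx, nb)

    res = minimize(
        neg_mi,
        x0=np.array(best, dtype=np.float64),
        method="Powell",
        bounds=[(-t_px, t_px), (-t_px, t_px), (-cfg.grid_r_deg, cfg.grid_r_deg)],
        options={"xtol": cfg.refine_tol, "ftol": 1e-8},
    )
    mi_refined = -float(res.fun)
    if mi_refined >= best_mi:
        tc, tr, th = res.x
        return RigidTransform2D(float(tc), float(tr), float(th)), mi_refined
    dc, dr, th = best
    return RigidTransform2D(float(dc), float(dr), th), float(best_mi)


def fuse_views(
    ap: RigidTransform2D,
    lat: RigidTransform2D,
    geometry: ProjectionGeometry | None = None,
    spacing_px_mm: float | None = None,
    rotation_labels: tuple[str, str] = ("rz", "rx"),
) -> SetupError3D:
    """Fuse the two per-view transforms into a 3D couch setup error.

    AP columns map to patient X, LAT columns to patient Y; the shared row
    axis gives Z as the average of the two views.  Each pixel shift is
    scaled to isocenter mm.  ``rotation_labels`` assigns the (AP, LAT)
    in-plane rotations to the reported axes; the default labels the AP
    rotation rz and the LAT rotation rx, mirroring how orthogonal-view
    rotations are conventionally reported.
    """
    geometry = geometry or ProjectionGeometry()
    if spacing_px_mm is None:
        from .image_core import DEFAULT_SPACING_MM

        spacing_px_mm = DEFAULT_SPACING_MM

    def to_mm(px: float) -> float:
        return detector_px_to_isocenter_mm(px, geometry, spacing_px_mm)

    tx = to_mm(ap.t_col_px)
    ty = to_mm(lat.t_col_px)
    tz = 0.5 * (to_mm(ap.t_row_px) + to_mm(lat.t_row_px))
    rotations = {rotation_labels[0]: ap.theta_deg, rotation_labels[1]: lat.theta_deg}
    return SetupError3D(
        tx_mm=tx,
        ty_mm=ty,
        tz_mm=tz,
        rx_deg=rotations.get("rx", 0.0),
        rz_deg=rotations.get("rz", 0.0),
    )
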