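"""From depth-resolved A-line stacks to registered en-face measurement maps.

A PS-OCT acquisition yields, per lateral pixel, a depth profile of phase
retardance (degrees) and of apparent optic-axis orientation (degrees,
axial, [-90, 90)).  Two reductions produce the en-face inputs of the 3D
estimator:

* apparent birefringence: the slope of an ordinary least-squares fit of the
  retardance profile over a fixed depth window (default 150 um) below the
  tissue surface, converted by dn' = slope(deg/um) * lambda0(um) / 360
  (single-pass retardance convention; a flag halves double-pass input);
* en-face orientation: the center of the maximal bin of a wrap-aware
  histogram (default 5 deg bins) of the orientation samples in the same
  window, ties broken toward the circular mean.

The tilted-illumination maps are then registered onto the normal-beam frame
with a 2D affine transform (for a 15 deg tilt the dominant distortion is an
affine foreshortening): the transform is fit on the birefringence maps by
maximizing normalized cross-correlation and then applied to the orientation
maps, with nearest-neighbor resampling and a rotation-angle correction of
the orientation values (angles are axial; linear interpolation across the
+/-90 wrap would corrupt them).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation

from .geometry import wrap_theta, wrap_theta_diff

__all__ = [
    "ALineStack",
    "EnFaceMaps",
    "AffineTransform2D",
    "RegistrationError",
    "apparent_birefringence_from_retardance",
    "enface_orientation",
    "register_tilted_to_normal",
    "write_enface_maps",
    "read_enface_maps",
]


@dataclass
class ALineStack:
    """Depth-resolved retardance / orientation grids, shape (ny, nx, nz).

    retardance is single-pass phase retardance in degrees unless
    ``double_pass`` is set, in which case profiles are halved before the
    regression; dz is the axial sampling in um.
    """

    retardance: np.ndarray
    orientation: np.ndarray
    dz: float
    wavelength_nm: float = 1300.0
    double_pass: bool = False

    def __post_init__(self):
        self.retardance = np.asarray(self.retardance, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.retardance.shape != self.orientation.shape:
            raise ValueError("retardance and orientation grids must be congruent")
        if self.retardance.ndim != 3:
            raise ValueError("expected (ny, nx, nz) grids")
        if self.dz <= 0:
            raise ValueError("dz must be positive")
        if np.any(self.retardance < 0):
            raise ValueError("retardance must be non-negative")


@dataclass
class EnFaceMaps:
    """En-face apparent birefringence and orientation with fit quality."""

    dn_app: np.ndarray
    theta_app: np.ndarray
    fit_r2: np.ndarray
    pixel_um: float = 10.0
    mask: np.ndarray = None

    def __post_init__(self):
        shapes = {np.shape(self.dn_app), np.shape(self.theta_app),
                  np.shape(self.fit_r2)}
        if len(shapes) != 1:
            raise ValueError("en-face grids must share one shape")
        if self.mask is None:
            self.mask = np.isfinite(np.asarray(self.dn_app, dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)


def _depth_window(stack: ALineStack, values: np.ndarray, depth_um: float,
                  surface_z) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gather per-pixel depth-window samples: (samples, depths_um, valid)."""
    ny, nx, nz = values.shape
    n_win = int(np.floor(depth_um / stack.dz)) + 1
    if surface_z is None:
        surface = np.zeros((ny, nx), dtype=int)
    else:
        surface = np.broadcast_to(np.asarray(surface_z, dtype=int), (ny, nx))
    idx = surface[..., None] + np.arange(n_win)
    valid = idx < nz
    samples = np.take_along_axis(values, np.minimum(idx, nz - 1), axis=2)
    depths = (idx - surface[..., None]) * stack.dz
    return samples, depths, valid


def apparent_birefringence_from_retardance(stack: ALineStack,
                                           depth_um: float = 150.0,
                                           surface_z=None):
    """Per-pixel OLS slope of retardance vs depth, as apparent birefringence.

    Returns (dn_app, fit_r2, mask); pixels with fewer than 3 samples in the
    window are masked.  dn' = slope * (lambda0 in um) / 360.
    """
    ret = stack.retardance / 2.0 if stack.double_pass else stack.retardance
    y, x, valid = _depth_window(stack, ret, depth_um, surface_z)
    w = valid.astype(float)
    n = w.sum(axis=2)
    mask = n >= 3

    sx = (w * x).sum(axis=2)
    sy = (w * y).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = (w * x * x).sum(axis=2) - sx * sx / n
        syy = (w * y * y).sum(axis=2) - sy * sy / n
        sxy = (w * x * y).sum(axis=2) - sx * sy / n
        slope = sxy / sxx
        r2 = np.where(syy > 0, sxy * sxy / (sxx * syy), 0.0)

    lam_um = stack.wavelength_nm / 1000.0
    dn_app = np.clip(slope, 0.0, None) * lam_um / 360.0
    dn_app = np.where(mask, dn_app, np.nan)
    r2 = np.where(mask, r2, np.nan)
    return dn_app, r2, mask


def enface_orientation(stack: ALineStack, depth_um: float = 150.0,
                       bin_deg: float = 5.0, surface_z=None):
    """Histogram-peak en-face orientation over the depth window.

    Orientation samples are binned with period-180 wrap-aware bins *centered*
    on multiples of ``bin_deg`` (which must divide 180): the bin at -90
    collects samples from both interval ends, so a cluster straddling +/-90
    lands in one bin instead of splitting.  theta' is the center of the
    maximal bin, ties broken toward the bin nearest the circular mean.
    Returns (theta_app, mask); empty windows are masked.
    """
    n_bins = 180.0 / bin_deg
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_deg must divide 180")
    n_bins = int(round(n_bins))

    samples, _, valid = _depth_window(stack, stack.orientation, depth_um, surface_z)
    ny, nx, n_win = samples.shape
    mask = valid.any(axis=2)

    wrapped = wrap_theta(samples)
    bin_idx = np.round((wrapped + 90.0) / bin_deg).astype(int) % n_bins

    pix = np.arange(ny * nx).reshape(ny, nx, 1)
    flat = (pix * n_bins + bin_idx)[valid]
    counts = np.bincount(flat, minlength=ny * nx * n_bins).reshape(ny, nx, n_bins)

    # circular mean (period 180) for tie-breaking
    ang = np.deg2rad(wrapped * 2.0)
    cs = np.where(valid, np.cos(ang), 0.0).sum(axis=2)
    sn = np.where(valid, np.sin(ang), 0.0).sum(axis=2)
    circ_mean = np.degrees(np.arctan2(sn, cs)) / 2.0

    centers = -90.0 + np.arange(n_bins) * bin_deg
    max_counts = counts.max(axis=2, keepdims=True)
    dist = np.abs(wrap_theta_diff(centers, circ_mean[..., None]))
    dist = np.where(counts == max_counts, dist, np.inf)
    theta = centers[np.argmin(dist, axis=2)]
    theta = np.where(mask, wrap_theta(theta), np.nan)
    return theta, mask


class RegistrationError(RuntimeError):
    """Raised when the two illuminations cannot be brought into register."""

    def __init__(self, message: str, ncc: float):
        super().__init__(f"{message} (normalized cross-correlation {ncc:.3f})")
        self.ncc = ncc


@dataclass
class AffineTransform2D:
    """Pull-back affine: reference-frame (row, col) -> moving-frame coords.

    Invalid (NaN) moving pixels stay invalid after resampling: the validity
    footprint is warped alongside the image and any output pixel whose
    support touches invalid input is masked.
    """

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    ncc: float = np.nan

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the linear part (polar decomposition)."""
        a = self.matrix
        return float(np.degrees(np.arctan2(a[1, 0] - a[0, 1], a[0, 0] + a[1, 1])))

    def apply(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        finite = np.isfinite(image)
        w = ndimage.affine_transform(np.where(finite, image, 0.0), self.matrix,
                                     self.offset, order=order, cval=0.0,
                                     mode="constant")
        support = ndimage.affine_transform(finite.astype(float), self.matrix,
                                           self.offset, order=min(order, 1),
                                           cval=0.0, mode="constant")
        return np.where(support > 0.99, w, np.nan)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 16:
        return -1.0
    av, bv = a[m], b[m]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av * av).sum() * (bv * bv).sum())
    if denom == 0:
        return -1.0
    return float((av * bv).sum() / denom)


def register_tilted_to_normal(ref: EnFaceMaps, mov: EnFaceMaps,
                              ncc_floor: float = 0.2):
    """Register the tilted-beam maps onto the normal-beam frame.

    Fits a 2D affine transform maximizing normalized cross-correlation of
    the apparent-birefringence maps (translation initialized by phase
    correlation, then a 6-parameter Powell refinement), and applies it to
    all moving maps: birefringence with linear interpolation, orientation
    with nearest-neighbor plus a rotation correction of the angle values.

    Returns (AffineTransform2D, EnFaceMaps).  Raises RegistrationError if
    the final correlation is below ``ncc_floor``.
    """
    a = np.asarray(ref.dn_app, dtype=float)
    b = np.asarray(mov.dn_app, dtype=float)
    if a.ndim != 2 or b.shape != a.shape:
        raise ValueError("registration expects congruent 2D maps")

    shift, _, _ = phase_cross_correlation(np.nan_to_num(a), np.nan_to_num(b),
                                          upsample_factor=20,
                                          normalization=None)

    # parameterize the linear part about the image center so rotation/scale
    # and translation stay decoupled during the search
    center = (np.array(a.shape, dtype=float) - 1.0) / 2.0

    def to_transform(params):
        mat = params[:4].reshape(2, 2)
        offset = center - mat @ center + params[4:]
        return AffineTransform2D(matrix=mat.copy(), offset=offset)

    ref_valid = float(np.isfinite(a).sum())

    def cost(params):
        w = to_transform(params).apply(b, order=1)
        overlap = (np.isfinite(a) & np.isfinite(w)).sum() / ref_valid
        if overlap < 0.5:  # guard against shrinking the footprint
            return 1.0 + (0.5 - overlap)
        return -_ncc(a, w)

    x0 = np.array([1.0, 0.0, 0.0, 1.0, -shift[0], -shift[1]])
    # direction steps matched to parameter scales (matrix entries vs pixels)
    direc = np.diag([0.02, 0.02, 0.02, 0.02, 1.0, 1.0])
    res = minimize(cost, x0, method="Powell",
                   options={"xtol": 1e-6, "ftol": 1e-12, "maxiter": 6000,
                            "direc": direc})
    tform = to_transform(res.x)
    tform.ncc = -float(res.fun)
    if tform.ncc < ncc_floor:
        raise RegistrationError("registration failed", tform.ncc)

    dn_res = tform.apply(np.asarray(mov.dn_app, dtype=float), order=1)
    r2_res = tform.apply(np.asarray(mov.fit_r2, dtype=float), order=0)
    theta_res = tform.apply(np.asarray(mov.theta_app, dtype=float), order=0)
    # moving-frame angles are rotated by the transform's rotation relative
    # to the reference frame
    theta_res = wrap_theta(theta_res + tform.rotation_deg)
    out_mask = np.isfinite(dn_res)
    theta_res = np.where(out_mask, theta_res, np.nan)
    resampled = EnFaceMaps(dn_app=dn_res, theta_app=theta_res, fit_r2=r2_res,
                           pixel_um=ref.pixel_um, mask=out_mask)
    return tform, resampled


def write_enface_maps(maps: EnFaceMaps, prefix, **meta) -> list[Path]:
    """Write en-face maps as one 3-page TIFF plus a JSON sidecar.

    Pages are (dn_app, theta_app, fit_r2); ``meta`` (e.g. omega_deg,
    wavelength_nm) is recorded in the sidecar together with the pixel size.
    """
    import tifffile

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tif = prefix.with_suffix(".tif")
    stack = np.stack([np.asarray(maps.dn_app, dtype=np.float32),
                      np.asarray(maps.theta_app, dtype=np.float32),
                      np.asarray(maps.fit_r2, dtype=np.float32)])
    tifffile.imwrite(tif, stack, photometric="minisblack")
    sidecar = prefix.with_suffix(".json")
    payload = {"pixel_um": maps.pixel_um, "pages": ["dn_app", "theta_app", "fit_r2"],
               **meta}
    sidecar.write_text(json.dumps(payload, indent=2))
    return [tif, sidecar]


def write_pair_map(pair_map, prefix, **meta) -> list[Path]:
    """Write a registered MeasurementPairMap as a 5-page TIFF + JSON sidecar.

    Pages: dn1, theta1, dn2, theta2, mask.
    """
    import tifffile

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tif = prefix.with_suffix(".tif")
    stack = np.stack([pair_map.dn1, pair_map.theta1, pair_map.dn2,
                      pair_map.theta2, pair_map.mask.astype(float)])
    tifffile.imwrite(tif, stack.astype(np.float32), photometric="minisblack")
    sidecar = prefix.with_suffix(".json")
    payload = {"omega_deg": pair_map.omega_deg,
               "pages": ["dn1", "theta1", "dn2", "theta2", "mask"], **meta}
    sidecar.write_text(json.dumps(payload, indent=2))
    return [tif, sidecar]


def read_pair_map(prefix):
    """Read a pair map written by write_pair_map; returns (pair_map, meta)."""
    import tifffile

    from .estimator import MeasurementPairMap

    prefix = Path(prefix)
    stack = tifffile.imread(prefix.with_suffix(".tif")).astype(float)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    pm = MeasurementPairMap(dn1=stack[0], theta1=stack[1], dn2=stack[2],
                            theta2=stack[3], omega_deg=float(meta["omega_deg"]),
                            mask=stack[4] > 0.5)
    return pm, meta


def read_enface_maps(prefix) -> tuple[EnFaceMaps, dict]:
    """Read maps written by write_enface_maps; returns (maps, sidecar dict)."""
    import tifffile

    prefix = Path(prefix)
    stack = tifffile.imread(prefix.with_suffix(".tif")).astype(float)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    maps = EnFaceMaps(dn_app=stack[0], theta_app=stack[1], fit_r2=stack[2],
                      pixel_um=float(meta.get("pixel_um", 10.0)))
    return maps, meta
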