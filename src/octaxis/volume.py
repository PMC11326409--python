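"""Volume assembly, color-coded rendering, and NIfTI export.

Serial blockface sectioning preserves inter-slice geometry, so per-slice
orientation maps stack directly into a volume (default spacing 10 um
in-plane, 150 um between slices) without inter-slice registration.  The
axis field exports as a 3-component NIfTI volume (plus a scalar true
birefringence volume) for external tractography viewers; rendering follows
the usual conventions — a cyclic hue wheel for angle maps, |ox|,|oy|,|oz| to
RGB for the 3D axis — with brightness modulated by birefringence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import nibabel as nib
from matplotlib.colors import hsv_to_rgb

from .estimator import OrientationMap

__all__ = ["OrientationVolume", "stack_slices", "colorize", "export_nifti",
           "load_nifti"]

DEFAULT_SPACING_UM = (10.0, 10.0, 150.0)  # (x, y, z)


@dataclass
class OrientationVolume:
    """Stacked per-slice estimation results; grids are (nz, ny, nx)."""

    dn: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    axis: np.ndarray  # (nz, ny, nx, 3)
    mask: np.ndarray
    spacing_um: tuple = DEFAULT_SPACING_UM

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing must be positive")
        if self.axis.shape != self.dn.shape + (3,):
            raise ValueError("axis grid must be dn grid plus a 3-vector axis")
        norms = np.linalg.norm(self.axis[self.mask], axis=-1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("axis must be unit-norm where valid")

    @property
    def shape(self):
        return self.dn.shape


def stack_slices(slices, slice_thickness_um: float = 150.0,
                 pixel_um: float = 10.0) -> OrientationVolume:
    """Stack per-slice OrientationMaps in acquisition order.

    Blockface geometry: no inter-slice alignment is performed.
    """
    slices = list(slices)
    if not slices:
        raise ValueError("no slices to stack")
    shapes = {s.dn.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError("slice shapes differ")
    return OrientationVolume(
        dn=np.stack([s.dn for s in slices]),
        theta=np.stack([s.theta for s in slices]),
        alpha=np.stack([s.alpha for s in slices]),
        axis=np.stack([s.axis for s in slices]),
        mask=np.stack([s.mask for s in slices]),
        spacing_um=(pixel_um, pixel_um, slice_thickness_um),
    )


def volume_from_map(m: OrientationMap, pixel_um: float = 10.0,
                    slice_thickness_um: float = 150.0) -> OrientationVolume:
    """A single-slice volume from one en-face orientation map."""
    return stack_slices([m], slice_thickness_um, pixel_um)


def colorize(kind: str, angles_or_axis, brightness, mask=None) -> np.ndarray:
    """Render an angle map or axis field to RGB in [0, 1].

    kind='inplane' / 'throughplane': cyclic hue over the +/-90 deg angle
    range; kind='axis3d': |ox|, |oy|, |oz| to R, G, B.  Brightness (apparent
    or true birefringence) is normalized to its valid maximum and multiplies
    the color; masked or zero-birefringence pixels come out black.
    """
    data = np.asarray(angles_or_axis, dtype=float)
    bright = np.asarray(brightness, dtype=float).copy()
    if mask is None:
        mask = np.isfinite(bright)
        if kind == "axis3d":
            mask &= np.isfinite(data).all(axis=-1)
        else:
            mask &= np.isfinite(data)
    bright = np.where(mask, bright, 0.0)
    top = bright.max()
    if top > 0:
        bright = np.clip(bright / top, 0.0, 1.0)

    if kind in ("inplane", "throughplane"):
        hue = ((data + 90.0) / 180.0) % 1.0
        hsv = np.stack([hue, np.ones_like(hue), bright], axis=-1)
        rgb = hsv_to_rgb(np.nan_to_num(hsv))
    elif kind == "axis3d":
        rgb = np.abs(np.nan_to_num(data)) * bright[..., None]
    else:
        raise ValueError(f"unknown map kind {kind!r}")
    return np.clip(rgb, 0.0, 1.0)


def export_nifti(volume: OrientationVolume, out_dir, prefix: str = "octaxis"
                 ) -> dict[str, Path]:
    """Write the axis field and true birefringence as NIfTI volumes.

    Data are stored (x, y, z[, 3]) with the voxel spacing in mm in the
    affine; masked voxels export as zero vectors.  Round-trips bit-exactly
    through load_nifti.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sx, sy, sz = (s / 1000.0 for s in volume.spacing_um)
    affine = np.diag([sx, sy, sz, 1.0])

    axis = np.where(volume.mask[..., None], volume.axis, 0.0)
    # internal (z, y, x, c) -> file (x, y, z, c)
    axis_xyz = np.ascontiguousarray(np.transpose(axis, (2, 1, 0, 3)))
    dn_xyz = np.ascontiguousarray(
        np.transpose(np.where(volume.mask, volume.dn, 0.0), (2, 1, 0)))

    paths = {}
    for name, arr in (("axis", axis_xyz), ("dn", dn_xyz)):
        img = nib.Nifti1Image(arr.astype(np.float64), affine)
        img.header.set_zooms((sx, sy, sz) + ((1.0,) if arr.ndim == 4 else ()))
        p = out_dir / f"{prefix}_{name}.nii"
        nib.save(img, p)
        paths[name] = p
    return paths


def write_orientation_map(m: OrientationMap, prefix, **meta):
    """Write an estimated orientation map as a 4-page TIFF + JSON sidecar.

    Pages: dn, theta, alpha, mask; the unit axis is recomputed from the
    angles on read.
    """
    import json
    import tifffile

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([m.dn, m.theta, m.alpha, m.mask.astype(float)])
    tifffile.imwrite(prefix.with_suffix(".tif"), stack.astype(np.float32),
                     photometric="minisblack")
    payload = {"pages": ["dn", "theta", "alpha", "mask"], **meta}
    prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2))
    return [prefix.with_suffix(".tif"), prefix.with_suffix(".json")]


def read_orientation_map(prefix) -> tuple[OrientationMap, dict]:
    """Read a map written by write_orientation_map."""
    import json
    import tifffile

    prefix = Path(prefix)
    stack = tifffile.imread(prefix.with_suffix(".tif")).astype(float)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    dn, theta, alpha, mask = stack[0], stack[1], stack[2], stack[3] > 0.5
    t, a = np.deg2rad(theta), np.deg2rad(alpha)
    axis = np.stack([np.cos(t) * np.cos(a), np.sin(t) * np.cos(a), np.sin(a)],
                    axis=-1)
    axis = np.where(mask[..., None], axis, 0.0)
    m = OrientationMap(dn=np.where(mask, dn, np.nan),
                       theta=np.where(mask, theta, np.nan),
                       alpha=np.where(mask, alpha, np.nan),
                       axis=axis, objective=np.full(dn.shape, np.nan),
                       converged=mask.copy(), mask=mask)
    return m, meta


def load_nifti(axis_path, dn_path=None):
    """Read volumes written by export_nifti.

    Returns (axis (nz,ny,nx,3), dn or None, spacing_um).
    """
    img = nib.load(str(axis_path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    axis = np.transpose(arr, (2, 1, 0, 3))
    zooms = img.header.get_zooms()[:3]
    spacing_um = tuple(float(z) * 1000.0 for z in zooms)
    dn = None
    if dn_path is not None:
        dn = np.transpose(np.asarray(nib.load(str(dn_path)).dataobj,
                                     dtype=np.float64), (2, 1, 0))
    return axis, dn, spacing_um
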