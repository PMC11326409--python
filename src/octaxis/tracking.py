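"""Minimal deterministic streamline tracker over an axial orientation field.

Fixed-step bidirectional integration with nearest-neighbor axis lookup.
Because the optic axis is axial, at every step the sign of the local axis is
chosen to minimize turning relative to the current direction; a step whose
turning angle exceeds the threshold (default 60 deg) terminates the track.
No intensity threshold is applied by default; the validity mask still
terminates tracks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .volume import OrientationVolume

__all__ = ["Streamline", "track_streamlines"]


@dataclass
class Streamline:
    """An ordered polyline in um, with why each end stopped."""

    points: np.ndarray  # (n, 3) positions in um, (x, y, z)
    seed: np.ndarray
    termination_reason: str            # forward end
    termination_reason_backward: str


def _lookup(volume: OrientationVolume, pos_um):
    """Nearest-neighbor axis at a position in um; None if outside or masked."""
    sx, sy, sz = volume.spacing_um
    ix = int(round(pos_um[0] / sx))
    iy = int(round(pos_um[1] / sy))
    iz = int(round(pos_um[2] / sz))
    nz, ny, nx = volume.shape
    if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
        return None, "bounds"
    if not volume.mask[iz, iy, ix]:
        return None, "mask"
    return volume.axis[iz, iy, ix], None


def _trace(volume, seed_um, direction, step_um, cos_threshold, max_length_um):
    points = []
    pos = np.asarray(seed_um, dtype=float).copy()
    d = np.asarray(direction, dtype=float)
    length = 0.0
    while True:
        axis, why = _lookup(volume, pos)
        if axis is None:
            return points, why
        dot = float(d @ axis)
        step_dir = axis if dot >= 0 else -axis
        if abs(dot) < cos_threshold:
            return points, "angle"
        pos = pos + step_um * step_dir
        d = step_dir
        points.append(pos.copy())
        length += step_um
        if length >= max_length_um:
            return points, "max_length"


def track_streamlines(volume: OrientationVolume, seeds_um, step_um: float = None,
                      angle_threshold_deg: float = 60.0,
                      max_length_um: float = 1e5) -> list[Streamline]:
    """Track one bidirectional streamline per seed (positions in um, (x,y,z)).

    The default step is half the in-plane voxel size.  Seeds outside the
    volume are skipped with a warning.
    """
    if step_um is None:
        step_um = 0.5 * min(volume.spacing_um[0], volume.spacing_um[1])
    cos_thr = math.cos(math.radians(angle_threshold_deg))

    out = []
    for seed in np.atleast_2d(np.asarray(seeds_um, dtype=float)):
        axis, why = _lookup(volume, seed)
        if axis is None:
            warnings.warn(f"seed {seed.tolist()} outside volume or masked "
                          f"({why}); skipped")
            continue
        fwd, why_f = _trace(volume, seed, axis, step_um, cos_thr, max_length_um)
        bwd, why_b = _trace(volume, seed, -axis, step_um, cos_thr, max_length_um)
        pts = np.array(list(reversed(bwd)) + [seed] + fwd, dtype=float)
        out.append(Streamline(points=pts, seed=np.asarray(seed, dtype=float),
                              termination_reason=why_f,
                              termination_reason_backward=why_b))
    return out
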