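"""Coordinate conventions, angle algebra and the forward measurement model.

The optic axis of a birefringent fiber is an *axial* quantity (the axis and
its negation are the same physical object).  We parameterize it by an
in-plane orientation ``theta`` (azimuth in the imaging plane, degrees,
half-open range [-90, 90)) and a through-plane inclination ``alpha``
(elevation out of the imaging plane toward the beam, degrees, closed range
[-90, 90]), with the unit axis

    [ox, oy, oz] = [cos(theta) cos(alpha), sin(theta) cos(alpha), sin(alpha)]

in a right-handed laboratory frame: x-y is the imaging plane, z points along
the normal illumination beam into the tissue.

A single beam with propagation direction ``p`` observes an *apparent*
birefringence ``dn' = dn * sin^2(psi)``, where ``psi`` is the polar angle of
the axis in the beam frame (``cos(psi) = p . axis``), together with the
in-beam-frame azimuth ``theta'`` of the projected axis.  A fiber parallel to
the beam is invisible (dn' = 0, theta' undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "wrap_theta",
    "wrap_theta_diff",
    "Beam",
    "TrueBirefringenceVector",
    "ApparentMeasurement",
    "axis_from_angles",
    "angles_from_axis",
    "canonical_axis",
    "apparent_from_true",
    "apparent_vector",
    "estimated_apparent_vector",
    "apparent_maps",
    "SWAP_ROTATION",
]

# Rotation by -90 deg about z: maps the y-tilted beam [sinW, 0, cosW] onto
# the x-tilted beam [0, -sinW, cosW].  Used by the estimator's xy-swap branch.
SWAP_ROTATION = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


def wrap_theta(theta_deg):
    """Wrap an axial angle (period 180) into [-90, 90)."""
    return (np.asarray(theta_deg) + 90.0) % 180.0 - 90.0


def wrap_theta_diff(a_deg, b_deg):
    """Signed wrapped difference a - b of axial angles, in (-90, 90]."""
    d = (np.asarray(a_deg) - np.asarray(b_deg) - 90.0) % (-180.0) + 90.0
    return d


@dataclass(frozen=True)
class Beam:
    """An illumination beam: unit propagation vector plus its frame rotation.

    ``rotation`` carries the beam frame into the laboratory frame; its third
    column is ``p``.  The apparent in-plane orientation theta' reported for
    this beam is the azimuth of the apparent birefringence vector expressed
    in the beam frame.
    """

    p: np.ndarray
    omega_deg: float
    tilt_axis: str  # 'none' | 'y' | 'x'
    rotation: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if not math.isclose(float(np.linalg.norm(p)), 1.0, abs_tol=1e-12):
            raise ValueError("beam propagation vector must be unit length")
        if (self.tilt_axis == "none") != (self.omega_deg == 0.0):
            raise ValueError("tilt_axis='none' iff omega_deg == 0")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))

    @staticmethod
    def normal() -> "Beam":
        """Normal illumination p1 = [0, 0, 1]."""
        return Beam(p=np.array([0.0, 0.0, 1.0]), omega_deg=0.0, tilt_axis="none",
                    rotation=np.eye(3))

    @staticmethod
    def tilted_y(omega_deg: float) -> "Beam":
        """Beam tilted by omega about the y axis: p2 = [sinW, 0, cosW]."""
        w = math.radians(omega_deg)
        rot = np.array([
            [math.cos(w), 0.0, math.sin(w)],
            [0.0, 1.0, 0.0],
            [-math.sin(w), 0.0, math.cos(w)],
        ])
        return Beam(p=rot[:, 2].copy(), omega_deg=omega_deg, tilt_axis="y",
                    rotation=rot)

    @staticmethod
    def tilted_x(omega_deg: float) -> "Beam":
        """Beam tilted by omega about the x axis: p3 = [0, -sinW, cosW].

        The frame is chosen so that an apparent vector with beam-frame
        azimuth theta' embeds as dn' [cos(theta'), cosW sin(theta'),
        sinW sin(theta')] in the laboratory frame.
        """
        w = math.radians(omega_deg)
        rot = np.array([
            [1.0, 0.0, 0.0],
            [0.0, math.cos(w), -math.sin(w)],
            [0.0, math.sin(w), math.cos(w)],
        ])
        return Beam(p=rot[:, 2].copy(), omega_deg=omega_deg, tilt_axis="x",
                    rotation=rot)


def canonical_axis(axis) -> np.ndarray:
    """Return the canonical representative of an axial unit vector.

    The axis and its negation are physically identical; the canonical sign
    is fixed by the first nonzero of (ox, oy, oz) being positive.
    """
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("zero vector has no axis")
    a = a / n
    if a[0] < 0 or (a[0] == 0 and (a[1] < 0 or (a[1] == 0 and a[2] < 0))):
        a = -a
    return a


def angles_from_axis(axis) -> tuple[float, float]:
    """(theta, alpha) in degrees from a canonical unit axis.

    theta is wrapped into [-90, 90); at the theta = +90 boundary the stored
    representative is (-90, -alpha), which denotes the same axis.
    """
    a = canonical_axis(axis)
    alpha = math.degrees(math.asin(max(-1.0, min(1.0, a[2]))))
    theta = math.degrees(math.atan2(a[1], a[0]))
    if theta >= 90.0:  # ox == 0, oy > 0
        theta -= 180.0
        alpha = -alpha
    return theta, alpha


@dataclass(frozen=True)
class TrueBirefringenceVector:
    """The unknown per-pixel quantity: true birefringence and 3D optic axis.

    ``dn`` is dimensionless (order 1e-4 in myelinated white matter); the
    axis is stored canonically.  The full birefringence vector is
    ``dn * axis``.
    """

    dn: float
    theta: float
    alpha: float
    axis: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return self.dn * self.axis


def axis_from_angles(theta: float, alpha: float, dn: float) -> TrueBirefringenceVector:
    """Build a canonical birefringence vector from (theta, alpha, dn) in degrees."""
    if dn < 0:
        raise ValueError("true birefringence must be non-negative")
    t, a = math.radians(theta), math.radians(alpha)
    raw = np.array([math.cos(t) * math.cos(a), math.sin(t) * math.cos(a), math.sin(a)])
    ax = canonical_axis(raw)
    th, al = angles_from_axis(ax)
    return TrueBirefringenceVector(dn=float(dn), theta=th, alpha=al, axis=ax)


def vector_to_true(vec) -> TrueBirefringenceVector:
    """Canonical TrueBirefringenceVector from an unnormalized 3-vector."""
    v = np.asarray(vec, dtype=float)
    dn = float(np.linalg.norm(v))
    if dn == 0:
        raise ValueError("zero birefringence vector")
    ax = canonical_axis(v)
    th, al = angles_from_axis(ax)
    return TrueBirefringenceVector(dn=dn, theta=th, alpha=al, axis=ax)


@dataclass(frozen=True)
class ApparentMeasurement:
    """What one beam sees at one pixel: (dn', theta') plus the beam.

    ``defined`` is False when the fiber is (numerically) parallel to the
    beam, where theta' carries no information.
    """

    dn_app: float
    theta_app: float
    beam: Beam
    defined: bool = True

    def __post_init__(self):
        if self.dn_app < 0:
            raise ValueError("apparent birefringence must be non-negative")


def apparent_from_true(v: TrueBirefringenceVector, b: Beam,
                       parallel_tol: float = 1e-12) -> ApparentMeasurement:
    """Forward model: apparent (dn', theta') of a true axis under a beam.

    dn' = dn * sin^2(psi) with cos(psi) = p . axis; theta' is the beam-frame
    azimuth of the axis projected onto the plane orthogonal to p.
    """
    c = float(b.p @ v.axis)
    sin2 = max(0.0, 1.0 - c * c)
    dn_app = v.dn * sin2
    if sin2 <= parallel_tol:
        return ApparentMeasurement(dn_app=0.0, theta_app=0.0, beam=b, defined=False)
    proj = v.axis - c * b.p
    pb = b.rotation.T @ proj
    theta_app = float(wrap_theta(math.degrees(math.atan2(pb[1], pb[0]))))
    return ApparentMeasurement(dn_app=dn_app, theta_app=theta_app, beam=b)


def apparent_vector(m: ApparentMeasurement) -> np.ndarray:
    """Laboratory-frame apparent birefringence 3-vector of a measurement.

    For the normal beam this is dn' [cos t', sin t', 0]; for the y-tilted
    beam dn' [cosW cos t', sin t', -sinW cos t']; for the x-tilted beam
    dn' [cos t', cosW sin t', sinW sin t'].
    """
    if not m.defined:
        raise ValueError("theta' undefined: axis parallel to beam")
    t = math.radians(m.theta_app)
    return m.dn_app * (m.beam.rotation @ np.array([math.cos(t), math.sin(t), 0.0]))


def estimated_apparent_vector(v_trial: TrueBirefringenceVector, b: Beam) -> np.ndarray:
    """Closed-form apparent vector of a trial birefringence vector.

    (d - (p.d) p) * sqrt(1 - (p.d)^2 / |d|^2): the projection of d onto the
    plane orthogonal to p supplies one factor of sin(psi), the square root
    the second.  Equals apparent_vector(apparent_from_true(v, b)) up to the
    overall axial sign.
    """
    d = v_trial.vector
    dd = float(d @ d)
    if dd == 0:
        raise ValueError("singular at |dn~| = 0")
    c = float(b.p @ d)
    s = math.sqrt(max(0.0, 1.0 - c * c / dd))
    return (d - c * b.p) * s


def apparent_maps(axis, dn, beam: Beam, parallel_tol: float = 1e-12):
    """Vectorized forward model over grids.

    Parameters
    ----------
    axis : (..., 3) array of unit axes.
    dn : (...) array of true birefringence.
    beam : Beam.

    Returns
    -------
    dn_app, theta_app, defined : arrays of shape (...).
    """
    axis = np.asarray(axis, dtype=float)
    dn = np.asarray(dn, dtype=float)
    c = axis @ beam.p
    sin2 = np.clip(1.0 - c * c, 0.0, None)
    dn_app = dn * sin2
    defined = sin2 > parallel_tol
    proj = axis - c[..., None] * beam.p
    pb = proj @ beam.rotation  # == rotation.T applied to each row vector
    theta_app = wrap_theta(np.degrees(np.arctan2(pb[..., 1], pb[..., 0])))
    theta_app = np.where(defined, theta_app, 0.0)
    return dn_app, theta_app, defined
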