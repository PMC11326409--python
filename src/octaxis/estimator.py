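"""Per-pixel recovery of the true birefringence vector from two beams.

Each pixel provides two apparent measurements, one from the normal beam and
one from a beam tilted by Omega about the y axis.  The true birefringence
vector d = dn * axis is recovered by minimizing the sum of squared distances
between the model's apparent vectors and the measured apparent vectors under
both beams (derivative-free Nelder-Mead simplex, as a function of the three
components of d).

Because the optic axis is axial, each measured apparent vector is known only
up to sign; the objective therefore scores each beam's residual against
+/- the measured vector and keeps the smaller.

For fibers whose in-plane orientation lies near +/-90 deg the measured
theta wraps at the interval boundary, so measurements are first re-expressed
in a laboratory frame rotated by 90 deg about z (the "xy-swap": the y-tilted
beam becomes an x-tilted beam and theta moves near 0); the estimate is
rotated back afterwards.  The swap is an exact change of coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    SWAP_ROTATION,
    ApparentMeasurement,
    Beam,
    TrueBirefringenceVector,
    apparent_vector,
    vector_to_true,
    wrap_theta,
)

__all__ = [
    "MeasurementPair",
    "MeasurementPairMap",
    "EstimatorConfig",
    "EstimationResult",
    "OrientationMap",
    "objective",
    "choose_branch",
    "estimate_pixel",
    "estimate_map",
    "brute_force_oracle",
]


@dataclass(frozen=True)
class MeasurementPair:
    """One pixel's measurements under the normal and the tilted beam."""

    m1: ApparentMeasurement
    m2: ApparentMeasurement
    omega_deg: float
    valid: bool = True

    def __post_init__(self):
        if self.valid:
            if self.m1.beam.tilt_axis != "none":
                raise ValueError("m1 must come from the normal beam")
            if self.m2.beam.tilt_axis not in ("y", "x"):
                raise ValueError("m2 must come from a tilted beam")
            if self.omega_deg <= 0:
                raise ValueError("omega_deg must be positive")


@dataclass
class MeasurementPairMap:
    """Registered en-face grids of paired measurements plus validity mask."""

    dn1: np.ndarray
    theta1: np.ndarray
    dn2: np.ndarray
    theta2: np.ndarray
    omega_deg: float
    mask: np.ndarray  # True where the pixel is usable

    def __post_init__(self):
        shapes = {np.shape(a) for a in (self.dn1, self.theta1, self.dn2,
                                        self.theta2, self.mask)}
        if len(shapes) != 1:
            raise ValueError("measurement grids must share one shape")

    @property
    def shape(self):
        return np.shape(self.dn1)

    def pixel(self, i: int, j: int) -> MeasurementPair:
        b1 = Beam.normal()
        b2 = Beam.tilted_y(self.omega_deg)
        return MeasurementPair(
            m1=ApparentMeasurement(float(self.dn1[i, j]), float(self.theta1[i, j]), b1),
            m2=ApparentMeasurement(float(self.dn2[i, j]), float(self.theta2[i, j]), b2),
            omega_deg=self.omega_deg,
            valid=bool(self.mask[i, j]),
        )


@dataclass(frozen=True)
class EstimatorConfig:
    """Optimizer settings.

    init_strategy
        'closed_form' (default): start the simplex from a closed-form
        inclination scan — theta is fixed by the normal beam, the magnitude
        is slaved to each candidate alpha through dn1' = dn cos^2(alpha),
        and the best candidate of each alpha sign seeds one simplex run
        (the lower final objective wins).  'paper_zero': a near-zero start
        [eps, eps, eps] kept as a compatibility option (the objective is
        singular at exactly zero).
    ftol
        absolute tolerance on the objective decrease (dimensionless^2).
    swap_threshold_deg
        |theta1| at or above which the xy-swap branch is used.
    dn_floor
        pixels with both apparent birefringences below this are masked as
        unidentifiable (the axis is essentially parallel to both beams or
        the signal is gone).
    """

    init_strategy: str = "closed_form"
    ftol: float = 1e-20
    max_iter: int = 2000
    swap_threshold_deg: float = 45.0
    dn_floor: float = 1e-6

    def __post_init__(self):
        if self.ftol <= 0:
            raise ValueError("ftol must be positive")
        if not 0 < self.swap_threshold_deg < 90:
            raise ValueError("swap_threshold_deg must be in (0, 90)")
        if self.init_strategy not in ("closed_form", "paper_zero", "custom"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")


@dataclass(frozen=True)
class EstimationResult:
    v_hat: TrueBirefringenceVector | None
    objective: float
    swapped: bool
    converged: bool
    n_iter: int
    masked: bool = False


def _pair_vectors_and_beams(pair: MeasurementPair, swapped: bool):
    """Measured lab-frame apparent vectors and model beams, per branch.

    In the swapped branch both measured vectors are rotated by -90 deg about
    z and the tilted model beam becomes the x-tilted one.
    """
    a1 = apparent_vector(pair.m1) if pair.m1.defined else None
    a2 = apparent_vector(pair.m2) if pair.m2.defined else None
    if not swapped:
        return (a1, a2), (Beam.normal(), Beam.tilted_y(pair.omega_deg))
    a1s = SWAP_ROTATION @ a1 if a1 is not None else None
    a2s = SWAP_ROTATION @ a2 if a2 is not None else None
    return (a1s, a2s), (Beam.normal(), Beam.tilted_x(pair.omega_deg))


def _objective_scalar(d, terms):
    """Sum over beams of min_{+/-} |estimated - measured|^2, plain floats.

    ``terms`` is a sequence of (measured_vector_or_None, beam_p) float
    tuples; kept scalar because this runs hundreds of times per pixel.
    """
    dx, dy, dz = d
    dd = dx * dx + dy * dy + dz * dz
    if dd == 0.0:
        return math.inf
    total = 0.0
    for a, p in terms:
        px, py, pz = p
        c = px * dx + py * dy + pz * dz
        s = math.sqrt(max(0.0, 1.0 - c * c / dd))
        ex = (dx - c * px) * s
        ey = (dy - c * py) * s
        ez = (dz - c * pz) * s
        if a is None:
            # theta' undefined: only the magnitude (which is ~0) is informative
            total += ex * ex + ey * ey + ez * ez
            continue
        ax, ay, az = a
        rm = (ex - ax) ** 2 + (ey - ay) ** 2 + (ez - az) ** 2
        rp = (ex + ax) ** 2 + (ey + ay) ** 2 + (ez + az) ** 2
        total += rm if rm < rp else rp
    return total


def objective(v_trial: TrueBirefringenceVector, pair: MeasurementPair,
              swapped: bool = False) -> float:
    """Least-squares misfit of a trial birefringence vector to a pixel's pair.

    The trial vector is given in the laboratory frame regardless of branch;
    with the sign-resolved residual the standard and swapped branches yield
    the same value on the same trial axis.
    """
    if not pair.valid:
        raise ValueError("pair is masked")
    measured, beams = _pair_vectors_and_beams(pair, swapped)
    d = SWAP_ROTATION @ v_trial.vector if swapped else v_trial.vector
    terms = [(None if a is None else tuple(a), tuple(b.p))
             for a, b in zip(measured, beams)]
    return _objective_scalar(tuple(d), terms)


def choose_branch(m1: ApparentMeasurement, threshold_deg: float = 45.0) -> str:
    """'standard' iff |theta1| < threshold, else 'swapped' (ties swap)."""
    if not m1.defined:
        raise ValueError("theta1 undefined; pixel should be masked")
    return "standard" if abs(m1.theta_app) < threshold_deg else "swapped"


def _closed_form_inits(dn1, dn2, theta_work_deg, measured, beams):
    """Simplex starting vectors from a 1D inclination scan.

    The normal beam fixes the in-plane azimuth (theta1' equals theta for the
    normal beam), and for any candidate inclination alpha the magnitude
    follows from dn1' = dn cos^2(alpha).  Scanning alpha on a 1 deg comb and
    scoring the objective picks the right basin of attraction — in
    particular the sign of alpha and the large-|alpha| regime where both
    apparent signals are small — before the simplex refines.
    """
    floor = 1e-3 * max(dn1, dn2)
    alphas = np.deg2rad(np.arange(-89.0, 89.5, 1.0))
    ca, sa = np.cos(alphas), np.sin(alphas)
    dn_cand = max(dn1, floor) / (ca * ca)
    t = math.radians(theta_work_deg)
    d = np.stack([math.cos(t) * ca, math.sin(t) * ca, sa], axis=-1) * dn_cand[:, None]

    total = np.zeros(len(alphas))
    dd = np.sum(d * d, axis=-1)
    for a, b in zip(measured, beams):
        c = d @ b.p
        s = np.sqrt(np.clip(1.0 - c * c / dd, 0.0, None))
        est = (d - c[:, None] * b.p) * s[:, None]
        if a is None:
            total += np.sum(est * est, axis=-1)
            continue
        total += np.minimum(np.sum((est - a) ** 2, axis=-1),
                            np.sum((est + a) ** 2, axis=-1))

    best = int(np.argmin(total))
    starts = [d[best]]
    # A second start with the opposite inclination sign is only worthwhile
    # when the scan cannot separate the two basins (alpha near 0, or noise
    # comparable to the tilt-induced asymmetry of the apparent signals).
    opposite = np.where(np.sign(alphas) != np.sign(alphas[best]))[0]
    if opposite.size:
        second = opposite[np.argmin(total[opposite])]
        margin = (0.1 * max(dn1, dn2)) ** 2
        if total[second] <= total[best] + margin:
            starts.append(d[second])
    return starts


def estimate_pixel(pair: MeasurementPair, cfg: EstimatorConfig = EstimatorConfig()
                   ) -> EstimationResult:
    """Recover the true birefringence vector of one pixel.

    Runs the Nelder-Mead simplex on the three components of the trial
    vector (scaled by the larger apparent birefringence so the parameters
    are order one), in the standard or swapped frame per choose_branch.
    """
    if not pair.valid or not pair.m1.defined:
        return EstimationResult(None, math.nan, False, False, 0, masked=True)
    dn1, dn2 = pair.m1.dn_app, pair.m2.dn_app
    if max(dn1, dn2) < cfg.dn_floor:
        return EstimationResult(None, math.nan, False, False, 0, masked=True)

    swapped = choose_branch(pair.m1, cfg.swap_threshold_deg) == "swapped"
    measured, beams = _pair_vectors_and_beams(pair, swapped)

    theta_work = pair.m1.theta_app - 90.0 if swapped else pair.m1.theta_app
    starts = _closed_form_inits(dn1, dn2, theta_work, measured, beams)
    if cfg.init_strategy == "paper_zero":
        starts = [np.full(3, 1e-8)]
    dn0 = max(float(np.linalg.norm(starts[0])), dn1, dn2)

    terms = [(None if a is None else (float(a[0]), float(a[1]), float(a[2])),
              (float(b.p[0]), float(b.p[1]), float(b.p[2])))
             for a, b in zip(measured, beams)]
    fun = lambda x: _objective_scalar((x[0] * dn0, x[1] * dn0, x[2] * dn0),
                                      terms) / (dn0 * dn0)
    best = None
    n_iter = 0
    for x0 in starts:
        res = minimize(fun, np.asarray(x0) / dn0, method="Nelder-Mead",
                       options={"fatol": cfg.ftol / (dn0 * dn0), "xatol": 1e-9,
                                "maxiter": cfg.max_iter, "maxfev": 4 * cfg.max_iter})
        n_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res

    d_hat = best.x * dn0
    if swapped:
        d_hat = SWAP_ROTATION.T @ d_hat
    if not np.any(d_hat):
        return EstimationResult(None, math.nan, swapped, False, n_iter, masked=True)
    v_hat = vector_to_true(d_hat)
    return EstimationResult(
        v_hat=v_hat,
        objective=float(best.fun) * dn0 * dn0,
        swapped=swapped,
        converged=bool(best.success),
        n_iter=n_iter,
    )


@dataclass
class OrientationMap:
    """Per-pixel estimation results over an en-face grid."""

    dn: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    axis: np.ndarray  # (..., 3)
    objective: np.ndarray
    converged: np.ndarray
    mask: np.ndarray  # True where an estimate exists


def estimate_map(maps: MeasurementPairMap, cfg: EstimatorConfig = EstimatorConfig()
                 ) -> OrientationMap:
    """Apply estimate_pixel to every valid pixel of a registered pair map.

    The estimate is a deterministic function of a pixel's four measurement
    values, so pixels with bitwise-identical measurements (common in
    homogeneous phantoms) are solved once and shared.
    """
    shape = maps.shape
    dn = np.full(shape, np.nan)
    theta = np.full(shape, np.nan)
    alpha = np.full(shape, np.nan)
    axis = np.zeros(shape + (3,))
    obj = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    out_mask = np.zeros(shape, dtype=bool)
    cache: dict[tuple, EstimationResult] = {}
    for i in range(shape[0]):
        for j in range(shape[1]):
            if not maps.mask[i, j]:
                continue
            key = (float(maps.dn1[i, j]), float(maps.theta1[i, j]),
                   float(maps.dn2[i, j]), float(maps.theta2[i, j]))
            r = cache.get(key)
            if r is None:
                r = estimate_pixel(maps.pixel(i, j), cfg)
                cache[key] = r
            if r.masked:
                continue
            out_mask[i, j] = True
            dn[i, j] = r.v_hat.dn
            theta[i, j] = r.v_hat.theta
            alpha[i, j] = r.v_hat.alpha
            axis[i, j] = r.v_hat.axis
            obj[i, j] = r.objective
            conv[i, j] = r.converged
    return OrientationMap(dn=dn, theta=theta, alpha=alpha, axis=axis,
                          objective=obj, converged=conv, mask=out_mask)


def brute_force_oracle(pair: MeasurementPair, grid_step_deg: float = 1.0,
                       dn_grid=None) -> EstimationResult:
    """Exhaustive grid search over (theta, alpha, dn) — a test oracle.

    Evaluates the same objective as the simplex on a dense regular grid and
    returns the global grid minimizer.  Vectorized, but still far slower
    than the simplex; intended only for validating the optimizer.
    """
    if grid_step_deg > 5:
        raise ValueError("oracle grid must be <= 5 deg")
    if dn_grid is None or len(dn_grid) == 0:
        raise ValueError("dn_grid must be non-empty")
    if not pair.valid:
        raise ValueError("pair is masked")

    measured, beams = _pair_vectors_and_beams(pair, swapped=False)
    thetas = np.deg2rad(np.arange(-90.0, 90.0, grid_step_deg))
    alphas = np.deg2rad(np.arange(-90.0, 90.0 + grid_step_deg / 2, grid_step_deg))
    T, A = np.meshgrid(thetas, alphas, indexing="ij")
    axes = np.stack([np.cos(T) * np.cos(A), np.sin(T) * np.cos(A), np.sin(A)],
                    axis=-1)  # (nt, na, 3)
    dn_grid = np.asarray(dn_grid, dtype=float)
    d = axes[None, ...] * dn_grid[:, None, None, None]  # (nd, nt, na, 3)

    total = np.zeros(d.shape[:-1])
    dd = np.sum(d * d, axis=-1)
    for a, b in zip(measured, beams):
        c = d @ b.p
        s = np.sqrt(np.clip(1.0 - c * c / dd, 0.0, None))
        est = (d - c[..., None] * b.p) * s[..., None]
        if a is None:
            total += np.sum(est * est, axis=-1)
            continue
        rm = np.sum((est - a) ** 2, axis=-1)
        rp = np.sum((est + a) ** 2, axis=-1)
        total += np.minimum(rm, rp)

    k = np.unravel_index(np.argmin(total), total.shape)
    v = vector_to_true(d[k])
    return EstimationResult(v_hat=v, objective=float(total[k]), swapped=False,
                            converged=True, n_iter=int(total.size))
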