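"""Synthetic dual-illumination phantoms and the validation experiment designs.

The generator plays the role of the uniform white-matter blocks used to
validate the reconstruction: a ground-truth orientation field is pushed
through the forward model under the normal and the tilted beam, and
measurement noise is added — wrapped Gaussian (period 180 deg) on the
apparent orientations, because the measured axis angle lives on [-90, 90),
and truncated Gaussian relative noise on the apparent birefringences, which
cannot go negative.

Three experiment designs mirror the physical validations:

* ``wedge`` — the sample rests on inclined wedges: the preset adds to the
  through-plane angle alpha.
* ``tilt_sweep`` — a tilting stage sweeps alpha over a range; an OLS fit of
  mean recovered alpha against the preset should have slope 1.
* ``inplane_rotation`` — the sample rotates in the imaging plane: the preset
  adds to theta while alpha should stay put.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .estimator import EstimatorConfig, MeasurementPairMap, estimate_map
from .geometry import Beam, apparent_maps, axis_from_angles, wrap_theta, wrap_theta_diff

__all__ = ["PhantomSpec", "ExperimentDesign", "simulate_pair_map", "run_experiment"]


@dataclass
class PhantomSpec:
    """Ground truth plus noise model for one synthetic acquisition.

    theta/alpha/dn may be scalars (uniform phantom) or arrays of ``shape``.
    Angles in degrees; noise_theta_deg is the wrapped-Gaussian sigma applied
    independently per beam; noise_dn_rel the relative Gaussian sigma on the
    apparent birefringence (samples truncated at zero).
    """

    shape: tuple
    theta: float | np.ndarray = 0.0
    alpha: float | np.ndarray = 0.0
    dn: float | np.ndarray = 5e-4
    omega_deg: float = 15.0
    noise_theta_deg: float = 0.0
    noise_dn_rel: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_theta_deg < 0 or self.noise_dn_rel < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.omega_deg <= 0:
            raise ValueError("omega_deg must be positive")

    def truth_grids(self):
        th = np.broadcast_to(np.asarray(self.theta, dtype=float), self.shape)
        al = np.broadcast_to(np.asarray(self.alpha, dtype=float), self.shape)
        dn = np.broadcast_to(np.asarray(self.dn, dtype=float), self.shape)
        if np.any(dn < 0):
            raise ValueError("dn must be non-negative")
        return wrap_theta(th), al, dn


def _truth_axes(theta_deg, alpha_deg):
    t = np.deg2rad(theta_deg)
    a = np.deg2rad(alpha_deg)
    return np.stack([np.cos(t) * np.cos(a), np.sin(t) * np.cos(a), np.sin(a)], axis=-1)


def simulate_pair_map(spec: PhantomSpec):
    """Simulate the registered measurement pair map for a phantom.

    Returns (MeasurementPairMap, truth) where truth is a dict with the
    ground-truth theta, alpha, dn grids.  Deterministic for a given seed.
    Pixels whose axis is parallel to the normal beam (theta1 undefined) are
    masked.
    """
    theta, alpha, dn = spec.truth_grids()
    axes = _truth_axes(theta, alpha)
    rng = np.random.default_rng(spec.seed)

    beams = (Beam.normal(), Beam.tilted_y(spec.omega_deg))
    grids = []
    mask = np.ones(spec.shape, dtype=bool)
    for b in beams:
        dn_app, theta_app, defined = apparent_maps(axes, dn, b)
        if spec.noise_theta_deg > 0:
            theta_app = wrap_theta(theta_app
                                   + rng.normal(0.0, spec.noise_theta_deg, spec.shape))
        if spec.noise_dn_rel > 0:
            dn_app = np.maximum(
                0.0, dn_app * (1.0 + rng.normal(0.0, spec.noise_dn_rel, spec.shape)))
        grids.append((dn_app, theta_app))
        if b.tilt_axis == "none":
            mask &= defined

    (dn1, th1), (dn2, th2) = grids
    pair_map = MeasurementPairMap(dn1=dn1, theta1=th1, dn2=dn2, theta2=th2,
                                  omega_deg=spec.omega_deg, mask=mask)
    return pair_map, {"theta": theta, "alpha": alpha, "dn": dn}


@dataclass
class ExperimentDesign:
    """A preset sweep applied to a common base truth."""

    kind: str  # 'wedge' | 'tilt_sweep' | 'inplane_rotation' | 'custom'
    levels: Sequence[float]
    base_theta: float = 0.0
    base_alpha: float = 0.0
    base_dn: float = 5e-4

    def __post_init__(self):
        if len(self.levels) == 0:
            raise ValueError("levels must be non-empty")
        if self.kind not in ("wedge", "tilt_sweep", "inplane_rotation", "custom"):
            raise ValueError(f"unknown design kind {self.kind!r}")


def _circular_mean_theta(values):
    """Mean of axial angles (period 180), degrees in [-90, 90)."""
    ang = np.deg2rad(np.asarray(values) * 2.0)
    m = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float(wrap_theta(np.degrees(m) / 2.0))


def run_experiment(design: ExperimentDesign, spec: PhantomSpec,
                   cfg: EstimatorConfig = EstimatorConfig()) -> dict:
    """Simulate and estimate every level of a validation design.

    For each preset level the base truth is inclined (wedge/tilt_sweep: the
    level adds to alpha) or rotated in-plane (inplane_rotation: the level
    adds to theta), a pair map is simulated from ``spec`` (its theta/alpha
    are overridden by the design's base), and the estimator is run.

    Returns a report dict with per-level mean recovered angles and, for
    tilt sweeps, the OLS slope of mean recovered alpha versus preset.
    """
    levels = list(design.levels)
    mean_theta, mean_alpha, mean_dn = [], [], []
    per_level = []
    for k, level in enumerate(levels):
        if design.kind in ("wedge", "tilt_sweep"):
            th, al = design.base_theta, design.base_alpha + level
        elif design.kind == "inplane_rotation":
            th, al = wrap_theta(design.base_theta + level), design.base_alpha
        else:
            th, al = design.base_theta, design.base_alpha
        level_spec = PhantomSpec(
            shape=spec.shape, theta=th, alpha=al, dn=design.base_dn,
            omega_deg=spec.omega_deg, noise_theta_deg=spec.noise_theta_deg,
            noise_dn_rel=spec.noise_dn_rel, seed=spec.seed + k,
        )
        pair_map, truth = simulate_pair_map(level_spec)
        est = estimate_map(pair_map, cfg)
        m = est.mask
        mean_theta.append(_circular_mean_theta(est.theta[m]))
        mean_alpha.append(float(np.mean(est.alpha[m])))
        mean_dn.append(float(np.mean(est.dn[m])))
        per_level.append({"level": float(level), "truth_theta": float(np.mean(truth["theta"])),
                          "truth_alpha": float(np.mean(truth["alpha"])),
                          "n_valid": int(m.sum())})

    report = {
        "kind": design.kind,
        "levels": [float(v) for v in levels],
        "mean_theta": mean_theta,
        "mean_alpha": mean_alpha,
        "mean_dn": mean_dn,
        "per_level": per_level,
    }
    if design.kind == "tilt_sweep":
        fit = stats.linregress(levels, mean_alpha)
        report["slope"] = float(fit.slope)
        report["intercept"] = float(fit.intercept)
    if design.kind == "inplane_rotation":
        steps = [float(wrap_theta_diff(b, a))
                 for a, b in zip(mean_theta[:-1], mean_theta[1:])]
        report["total_theta_change"] = float(sum(steps))
    return report
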