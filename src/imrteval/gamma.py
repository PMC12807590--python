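"""Gamma-index comparison of 2D dose planes (3%/3 mm, global, 10% threshold).

For each reference point r with dose above the low-dose threshold,

    gamma(r) = min over evaluated positions e of
               sqrt( |r - e|^2 / dist_tol^2  +  (D_e - D_r)^2 / dose_norm^2 ),

with dose_norm = dose_tol% of the global reference maximum. The evaluated
distribution is resampled once onto a global fine lattice (step <=
dist_tol/10) and each reference point searches a window of radius
2 x dist_tol on that lattice; the passing rate is the percentage of
evaluated points with gamma <= 1. Points below the threshold carry NaN and
never enter the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .exceptions import AlignmentError, UndefinedMetricError

_PASS_TOL = 1e-9  # boundary cases (gamma exactly 1) count as passing


@dataclass(frozen=True)
class GammaCriteria:
    """Agreement criteria; defaults are the common clinical 3%/3 mm setting."""

    dose_tol_pct: float = 3.0  # % of global reference maximum
    dist_tol_mm: float = 3.0
    low_dose_threshold_pct: float = 10.0  # % of global reference maximum
    normalization: str = "global"

    def __post_init__(self) -> None:
        if min(self.dose_tol_pct, self.dist_tol_mm, self.low_dose_threshold_pct) <= 0:
            raise ValueError("gamma criteria must be strictly positive")
        if self.normalization != "global":
            raise ValueError("only global normalization is supported")


@dataclass
class DosePlane:
    """2D dose distribution on a regular grid; coordinates in cm, dose in Gy."""

    origin: np.ndarray  # (2,) cm, first point along (u, v)
    spacing: np.ndarray  # (2,) cm
    values: np.ndarray  # (nu, nv) Gy

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or np.any(self.spacing <= 0):
            raise ValueError("DosePlane needs a 2D array and positive spacing")

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.values.shape[axis])


@dataclass
class GammaResult:
    gamma_map: np.ndarray  # reference-shaped; NaN below threshold
    passing_rate: float  # % of evaluated points with gamma <= 1
    n_evaluated: int


def _fine_resample(evaluated: DosePlane, step_cm: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear resampling onto a fine lattice that contains every stored sample.

    The step is rounded down to an integer division of the grid spacing so
    the original lattice is a sub-lattice of the fine one — identical
    distributions on one lattice then compare at distance exactly zero.
    """
    u = evaluated.axis_coords(0)
    v = evaluated.axis_coords(1)
    interp = RegularGridInterpolator((u, v), evaluated.values, method="linear")
    su = evaluated.spacing[0] / np.ceil(evaluated.spacing[0] / step_cm)
    sv = evaluated.spacing[1] / np.ceil(evaluated.spacing[1] / step_cm)
    fu = u[0] + su * np.arange(int(round((u[-1] - u[0]) / su)) + 1)
    fv = v[0] + sv * np.arange(int(round((v[-1] - v[0]) / sv)) + 1)
    fu = np.clip(fu, u[0], u[-1])
    fv = np.clip(fv, v[0], v[-1])
    uu, vv = np.meshgrid(fu, fv, indexing="ij")
    return fu, fv, interp(np.stack([uu.ravel(), vv.ravel()], axis=1)).reshape(uu.shape)


def gamma_index(reference: DosePlane, evaluated: DosePlane,
                criteria: GammaCriteria = GammaCriteria(),
                search_factor: float = 2.0, step_divisor: int = 10) -> GammaResult:
    """Gamma map and passing rate of ``evaluated`` against ``reference``."""
    ref_max = float(reference.values.max())
    if ref_max <= 0:
        raise UndefinedMetricError("reference maximum dose must be positive")

    ru, rv = reference.axis_coords(0), reference.axis_coords(1)
    eu, ev = evaluated.axis_coords(0), evaluated.axis_coords(1)
    if ru[-1] < eu[0] or eu[-1] < ru[0] or rv[-1] < ev[0] or ev[-1] < rv[0]:
        raise AlignmentError("reference and evaluated planes do not overlap")

    dist_tol = criteria.dist_tol_mm / 10.0  # cm
    dose_norm = criteria.dose_tol_pct / 100.0 * ref_max
    threshold = criteria.low_dose_threshold_pct / 100.0 * ref_max
    step = dist_tol / step_divisor
    radius = search_factor * dist_tol

    fu, fv, fine = _fine_resample(evaluated, step)
    su = fu[1] - fu[0] if fu.size > 1 else step
    sv = fv[1] - fv[0] if fv.size > 1 else step
    half_u = int(np.floor(radius / su))
    half_v = int(np.floor(radius / sv))

    gamma_map = np.full(reference.values.shape, np.nan)
    above = np.argwhere(reference.values >= threshold)
    if above.size == 0:
        raise UndefinedMetricError("no reference point reaches the low-dose threshold")

    for i, j in above:
        pu, pv = ru[i], rv[j]
        dref = reference.values[i, j]
        ci = int(round((pu - fu[0]) / su))
        cj = int(round((pv - fv[0]) / sv))
        i0, i1 = max(ci - half_u, 0), min(ci + half_u + 1, fu.size)
        j0, j1 = max(cj - half_v, 0), min(cj + half_v + 1, fv.size)
        if i0 >= i1 or j0 >= j1:
            continue
        du = (fu[i0:i1] - pu)[:, None]
        dv = (fv[j0:j1] - pv)[None, :]
        r2 = (du**2 + dv**2) / dist_tol**2
        d2 = (fine[i0:i1, j0:j1] - dref) ** 2 / dose_norm**2
        gamma_map[i, j] = np.sqrt(np.min(r2 + d2))

    evaluated_pts = np.isfinite(gamma_map)
    n_eval = int(evaluated_pts.sum())
    if n_eval == 0:
        raise UndefinedMetricError("no evaluated points inside the search region")
    passing = np.count_nonzero(gamma_map[evaluated_pts] <= 1.0 + _PASS_TOL)
    return GammaResult(gamma_map, 100.0 * passing / n_eval, n_eval)


def decimate_to_detector(plane: DosePlane, pitch_cm: float = 1.0) -> DosePlane:
    """Down-sample a plane to a detector-array pitch (729-style, 10 mm default).

    Pure decimation on the existing lattice — nearest stored points at the
    detector pitch, no chamber-response modelling.
    """
    stride = max(1, int(round(pitch_cm / plane.spacing[0]))), max(
        1, int(round(pitch_cm / plane.spacing[1]))
    )
    vals = plane.values[:: stride[0], :: stride[1]]
    return DosePlane(plane.origin.copy(), plane.spacing * np.asarray(stride), vals)


def plan_to_phantom_plane(plan, dose_model=None, depth_cm: float = 5.0) -> DosePlane:
    """Compose all beams at gantry 0 onto one plane at phantom depth.

    Stand-in for a verification-plan recalculation: MU-weighted aperture
    fluence of every beam (gantry forced to 0) is summed in the beam's-eye
    view, blurred with the penumbra kernel and attenuated to ``depth_cm``.
    Axes: u = leaf travel, v = leaf stacking (cranio-caudal).
    """
    from .synthetic import DoseModelConfig, beam_fluence_bev

    cfg = dose_model or DoseModelConfig()
    res = cfg.fluence_res_cm
    # cell-centred lattice: leaf-band edges (multiples of 0.5 cm) never
    # coincide with samples, so symmetric apertures yield symmetric planes
    u_axis = np.arange(-20.0 + res / 2, 20.0, res)
    v_axis = np.arange(-20.0 + res / 2, 20.0, res)
    total = np.zeros((u_axis.size, v_axis.size))
    for beam in plan.beams:
        total += beam.beam_mu * beam_fluence_bev(beam, plan.leaf_geometry, u_axis,
                                                 v_axis, cfg)
    from scipy import ndimage

    total = total + cfg.scatter_frac * ndimage.gaussian_filter(
        total, cfg.scatter_sigma_cm / res)
    total *= np.exp(-cfg.mu_cm * depth_cm)
    return DosePlane(np.array([u_axis[0], v_axis[0]]), np.array([res, res]), total)
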