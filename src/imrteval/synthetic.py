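"""Synthetic paired cohort: EF vs jaw-locked IMRT plans with forward dose.

Emulates a paired planning study for an elongated cranio-caudal target
(cervical-supraclavicular plus upper-mediastinal nodal volume, >= 20 cm
long) flanked by lungs, with a posterior spinal cord:

* **EF** (extended field): nine coplanar beams at gantry
  0/25/50/75/160/200/285/310/335 deg, Y-jaws spanning the whole target,
  heavily modulated leaf sequences over the full length.
* **SJL** (segmented jaw-locked): seven anterior-fan beams
  (285/310/335/0/25/50/75 deg) treat the cervical segment with the caudal
  Y-jaw edge 2 cm inferior to the isocenter, and six "butterfly" beams
  (330/350/10/30/160/200 deg) treat the thoracic segment with the cranial
  Y-jaw edge at the isocenter; leaf modulation is confined to each window
  and complementary linear fluence ramps feather the 2-cm overlap.

The forward dose model is deliberately simple and fully documented: per
beam, the MU-weighted aperture fluence (open = 1, leaf-shielded inside the
jaws = MLC transmission) is blurred by a Gaussian penumbra plus a wide
low-amplitude scatter kernel, projected along the gantry direction with
exponential depth attenuation inside an elliptical body contour, summed
over beams, and renormalised so the target D_95% equals 95% of the
prescription. It is a statistical stand-in for a treatment planning system,
not a physics engine.

Every artifact is a pure function of (spec, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .plan_model import Beam, ControlPoint, DoseGrid, LeafGeometry, Plan, StructureMask

EF_ANGLES = (0.0, 25.0, 50.0, 75.0, 160.0, 200.0, 285.0, 310.0, 335.0)
SJL_CERVICAL_ANGLES = (285.0, 310.0, 335.0, 0.0, 25.0, 50.0, 75.0)
SJL_THORACIC_ANGLES = (330.0, 350.0, 10.0, 30.0, 160.0, 200.0)


# ------------------------------------------------------------- configuration


@dataclass(frozen=True)
class DoseModelConfig:
    """Forward-model knobs (all overridable; defaults documented in methods)."""

    mu_cm: float = 0.055  # effective 6-MV attenuation per cm of tissue
    penumbra_sigma_cm: float = 0.4
    scatter_sigma_cm: float = 3.0  # wide low-dose spread kernel
    scatter_frac: float = 0.10
    mlc_transmission: float = 0.02  # leaf-shielded fluence inside the jaws
    fluence_res_cm: float = 0.25
    feather_cm: float = 2.0  # junction overlap / ramp width
    body_semiaxis_x_cm: float = 15.5
    body_semiaxis_y_cm: float = 10.5


@dataclass(frozen=True)
class ModulationConfig:
    """Stochastic leaf-sequence priors for one technique.

    Each control point opens every usable row to its conformal interval,
    retracted from both ends by half-normal draws (``retract_sigma_cm``),
    and occasionally collapsed to a narrow off-centre notch
    (``notch_prob``). ``row_smooth`` correlates the retractions of
    neighbouring rows, producing the smooth leaf fronts of a jaw-locked
    window versus the jagged fronts of a long modulated field.
    """

    n_cp: int
    retract_sigma_cm: float  # half-normal leaf retraction amplitude
    row_smooth: int  # moving-average half-width across rows (0 = uncorrelated)
    notch_prob: float  # chance a row collapses to a narrow notch per CP
    notch_width_cm: tuple[float, float] = (0.6, 1.6)
    margin_cm: float = 0.6  # conformal margin around the projected target


EF_MODULATION = ModulationConfig(n_cp=10, retract_sigma_cm=0.7,
                                 row_smooth=0, notch_prob=0.12)
SJL_MODULATION = ModulationConfig(n_cp=6, retract_sigma_cm=0.25,
                                  row_smooth=3, notch_prob=0.03)


@dataclass(frozen=True)
class GridSpec:
    """Centred voxel lattice: 0.5 cm spacing over a 35 x 25 x 30 cm box."""

    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    shape: tuple[int, int, int] = (70, 50, 60)

    @property
    def origin(self) -> np.ndarray:
        sp = np.asarray(self.spacing)
        sh = np.asarray(self.shape)
        return -(sh - 1) * sp / 2.0

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self):
        return np.meshgrid(*(self.axis_coords(i) for i in range(3)), indexing="ij")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the paired synthetic cohort (40 patients)."""

    n_patients: int = 40
    prescription_gy: float = 50.0
    fractions: int = 25
    modulation: dict = field(default_factory=lambda: {"EF": EF_MODULATION,
                                                      "SJL": SJL_MODULATION})
    dose_model: DoseModelConfig = DoseModelConfig()
    grid: GridSpec = GridSpec()

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a paired cohort needs n_patients >= 2")


# ----------------------------------------------------------------- anatomy


@dataclass
class PatientGeometry:
    """Masks plus the target extent used to place jaw windows.

    The thoracic inlet sits at z = 0 (the isocenter plane); the cervical
    segment is cranial (z > 0), the thoracic segment caudal.
    """

    grid: GridSpec
    masks: dict[str, StructureMask]
    ptv_z_range: tuple[float, float]
    inlet_z: float = 0.0


def _make_mask(grid: GridSpec, name: str, values: np.ndarray) -> StructureMask:
    return StructureMask(name, grid.origin, np.asarray(grid.spacing), values)


def generate_geometry(rng: np.random.Generator, grid: GridSpec | None = None) -> PatientGeometry:
    """Draw one patient's anatomy: elongated PTV, two lungs, posterior cord."""
    grid = grid or GridSpec()
    xx, yy, zz = grid.meshgrid()

    z_high = rng.uniform(10.0, 12.0)
    z_low = rng.uniform(-12.0, -10.0)
    # cervical cross-section is wide and flat (supraclavicular wings); the
    # thoracic one is a tighter tube sitting slightly posterior
    cerv_ax = rng.uniform(3.5, 5.0)
    cerv_ay = rng.uniform(1.5, 2.0)
    thor_ax = rng.uniform(1.8, 2.6)
    thor_ay = rng.uniform(1.5, 2.0)
    blend = np.clip((zz + 1.0) / 2.0, 0.0, 1.0)  # 0 = thoracic, 1 = cervical
    ax = thor_ax + (cerv_ax - thor_ax) * blend
    ay = thor_ay + (cerv_ay - thor_ay) * blend
    yc = 1.0 + (-0.5 - 1.0) * blend
    ptv = ((xx / ax) ** 2 + ((yy - yc) / ay) ** 2 <= 1.0) & (zz >= z_low) & (zz <= z_high)

    ctv = ndimage.binary_erosion(ptv, ndimage.generate_binary_structure(3, 1))
    if not ctv.any():  # pathological draw guard; never hit at default sizes
        ctv = ptv.copy()

    lungs = {}
    for side, sign in (("lung_left", -1.0), ("lung_right", 1.0)):
        cx = sign * rng.uniform(5.5, 6.5)
        cz = rng.uniform(-8.7, -7.3)
        sx = rng.uniform(3.6, 4.4)
        sy = rng.uniform(4.4, 5.2)
        szv = rng.uniform(6.0, 7.0)
        body = ((xx - cx) / sx) ** 2 + ((yy - 0.8) / sy) ** 2 + ((zz - cz) / szv) ** 2 <= 1.0
        lungs[side] = body & (zz < -0.5) & ~ptv

    cord = ((xx / 0.55) ** 2 + ((yy - 3.8) / 0.55) ** 2 <= 1.0) & (zz >= z_low - 2.0)

    masks = {
        "PTV": _make_mask(grid, "PTV", ptv),
        "CTV": _make_mask(grid, "CTV", ctv),
        "lung_left": _make_mask(grid, "lung_left", lungs["lung_left"]),
        "lung_right": _make_mask(grid, "lung_right", lungs["lung_right"]),
        "cord": _make_mask(grid, "cord", cord),
    }
    return PatientGeometry(grid, masks, (float(z_low), float(z_high)))


# ------------------------------------------------------------ plan synthesis


def _bev_u(x: np.ndarray, y: np.ndarray, gantry_deg: float) -> np.ndarray:
    th = np.deg2rad(gantry_deg)
    return x * np.cos(th) - y * np.sin(th)


def _conformal_extents(geometry: PatientGeometry, geom: LeafGeometry,
                       gantry_deg: float, margin: float) -> np.ndarray:
    """Per-leaf-row conformal (u_min, u_max) of the projected PTV; NaN if empty."""
    ptv = geometry.masks["PTV"]
    idx = np.argwhere(ptv.values)
    xyz = ptv.origin[None, :] + idx * ptv.spacing[None, :]
    u = _bev_u(xyz[:, 0], xyz[:, 1], gantry_deg)
    z = xyz[:, 2]
    extents = np.full((geom.n_pairs, 2), np.nan)
    rows = np.searchsorted(geom.boundaries, z, side="right") - 1
    ok = (rows >= 0) & (rows < geom.n_pairs)
    for r in np.unique(rows[ok]):
        sel = u[ok][rows[ok] == r]
        extents[r] = (sel.min() - margin, sel.max() + margin)
    # open margin rows beyond the target's cranio-caudal ends, as conformal
    # planning does, so the field edge penumbra falls outside the target
    filled = np.flatnonzero(np.isfinite(extents[:, 0]))
    centers = geom.centers
    for r in range(geom.n_pairs):
        if np.isfinite(extents[r, 0]) or filled.size == 0:
            continue
        nearest = filled[np.argmin(np.abs(centers[filled] - centers[r]))]
        if abs(centers[nearest] - centers[r]) <= margin + 0.45:
            extents[r] = extents[nearest]
    return extents


def _smooth_rows(noise: np.ndarray, half_width: int) -> np.ndarray:
    if half_width <= 0:
        return noise
    kernel = np.ones(2 * half_width + 1) / (2 * half_width + 1)
    return np.convolve(noise, kernel, mode="same")


def _make_beam(rng: np.random.Generator, gantry_deg: float, jaw_y: tuple[float, float],
               geometry: PatientGeometry, geom: LeafGeometry, mod: ModulationConfig,
               label: str, segment: str | None) -> Beam:
    extents = _conformal_extents(geometry, geom, gantry_deg, mod.margin_cm)
    in_window = (geom.boundaries[1:] > jaw_y[0]) & (geom.boundaries[:-1] < jaw_y[1])
    usable = in_window & np.isfinite(extents[:, 0])
    if not usable.any():
        raise ValueError(f"beam {label}: no target rows inside the jaw window")

    umin = np.nanmin(extents[usable, 0])
    umax = np.nanmax(extents[usable, 1])
    jaw_x = (max(umin - 0.2, -19.9), min(umax + 0.2, 19.9))

    n_cp = mod.n_cp
    mu_weights = rng.dirichlet(np.full(n_cp, 5.0))
    cps = []
    for k in range(n_cp):
        bank_a = np.full(geom.n_pairs, 0.0)
        bank_b = np.full(geom.n_pairs, 0.0)  # parked closed
        retract_a = np.abs(_smooth_rows(
            rng.normal(0.0, mod.retract_sigma_cm, geom.n_pairs), mod.row_smooth))
        retract_b = np.abs(_smooth_rows(
            rng.normal(0.0, mod.retract_sigma_cm, geom.n_pairs), mod.row_smooth))
        for r in np.flatnonzero(usable):
            lo, hi = extents[r]
            left = lo + retract_a[r]
            right = hi - retract_b[r]
            if rng.random() < mod.notch_prob:
                # collapse the row to a narrow off-centre notch
                w = rng.uniform(*mod.notch_width_cm)
                c = rng.uniform(lo + w / 2, hi - w / 2) if hi - lo > w else 0.5 * (lo + hi)
                left, right = c - w / 2, c + w / 2
            left = float(np.clip(left, lo, hi - 0.1))
            right = float(np.clip(right, left + 0.1, hi))
            bank_a[r], bank_b[r] = left, right
        cps.append(ControlPoint(k, float(mu_weights[k]), bank_a, bank_b,
                                jaw_x, jaw_y))
    # posterior beams traverse the cord first; planners keep their weight down
    posterior = 90.0 < (gantry_deg % 360.0) < 270.0
    beam_mu = float(rng.normal(150.0 if posterior else 225.0, 15.0))
    return Beam(gantry_deg, cps, max(beam_mu, 80.0), label, segment)


def generate_plan(rng: np.random.Generator, technique: str,
                  geometry: PatientGeometry, spec: CohortSpec) -> Plan:
    """Synthesize one plan (EF or SJL) for a given anatomy."""
    geom = LeafGeometry.millennium120()
    mod = spec.modulation[technique]
    z_low, z_high = geometry.ptv_z_range
    feather = spec.dose_model.feather_cm
    beams = []
    if technique == "EF":
        jaw_y = (z_low - 0.8, z_high + 0.8)
        for i, ang in enumerate(EF_ANGLES):
            beams.append(_make_beam(rng, ang, jaw_y, geometry, geom, mod,
                                    f"EF{i + 1:02d}", None))
    elif technique == "SJL":
        # cervical window: caudal edge `feather` cm inferior to the isocenter;
        # thoracic window: cranial edge at the isocenter -> 2 cm overlap
        jaw_c = (geometry.inlet_z - feather, z_high + 0.8)
        jaw_t = (z_low - 0.8, geometry.inlet_z)
        for i, ang in enumerate(SJL_CERVICAL_ANGLES):
            beams.append(_make_beam(rng, ang, jaw_c, geometry, geom, mod,
                                    f"C{i + 1:02d}", "PTV-C"))
        for i, ang in enumerate(SJL_THORACIC_ANGLES):
            beams.append(_make_beam(rng, ang, jaw_t, geometry, geom, mod,
                                    f"T{i + 1:02d}", "PTV-T"))
    else:
        raise ValueError(f"unknown technique {technique!r}")
    plan = Plan(beams, spec.prescription_gy, spec.fractions, technique,
                leaf_geometry=geom)
    plan.validate()
    return plan


# ------------------------------------------------------------- forward dose


RAMP_INSET_CM = 0.5  # keeps the jaw-edge penumbra out of the nonzero-ramp zone


def _feather_weight(v_axis: np.ndarray, beam: Beam, feather: float) -> np.ndarray:
    """Complementary linear fluence ramps across the jaw-window overlap.

    The ramps are inset from the window edges so the jaw penumbra acts on an
    already-zero fluence region; the two segments' weights then sum to
    exactly 1 everywhere inside the overlap.
    """
    width = max(feather - 2.0 * RAMP_INSET_CM, 0.2 * feather)
    if beam.segment == "PTV-C":
        edge = beam.control_points[0].jaw_y[0]  # caudal window edge
        return np.clip((v_axis - (edge + RAMP_INSET_CM)) / width, 0.0, 1.0)
    if beam.segment == "PTV-T":
        edge = beam.control_points[0].jaw_y[1]  # cranial window edge
        return np.clip(((edge - RAMP_INSET_CM) - v_axis) / width, 0.0, 1.0)
    return np.ones_like(v_axis)


def beam_fluence_bev(beam: Beam, geom: LeafGeometry, u_axis: np.ndarray,
                     v_axis: np.ndarray, cfg: DoseModelConfig) -> np.ndarray:
    """MU-weighted beam fluence in the beam's-eye view (u = leaf travel, v = z).

    Open aperture contributes 1, leaf-shielded area inside the jaws the MLC
    transmission factor; the map is blurred with the penumbra kernel plus a
    wide scatter kernel and multiplied by the junction feathering ramp.
    """
    res_u = u_axis[1] - u_axis[0]
    res_v = v_axis[1] - v_axis[0]
    flu = np.zeros((u_axis.size, v_axis.size))
    for cp in beam.control_points:
        if cp.mu_weight <= 0:
            continue
        x_lo, x_hi = cp.jaw_x
        y_lo, y_hi = cp.jaw_y
        in_jaw = ((u_axis[:, None] >= x_lo) & (u_axis[:, None] <= x_hi)
                  & (v_axis[None, :] >= y_lo) & (v_axis[None, :] <= y_hi))
        cp_map = np.where(in_jaw, cfg.mlc_transmission, 0.0)
        band = np.searchsorted(geom.boundaries, v_axis, side="right") - 1
        valid = (band >= 0) & (band < geom.n_pairs)
        left = np.where(valid, cp.bank_a[np.clip(band, 0, geom.n_pairs - 1)], 0.0)
        right = np.where(valid, cp.bank_b[np.clip(band, 0, geom.n_pairs - 1)], 0.0)
        open_map = ((u_axis[:, None] >= np.maximum(left, x_lo)[None, :])
                    & (u_axis[:, None] <= np.minimum(right, x_hi)[None, :])
                    & in_jaw & valid[None, :])
        cp_map = np.where(open_map, 1.0, cp_map)
        flu += cp.mu_weight * cp_map
    # feather before transport: the complementary ramps of the two jaw-locked
    # segments then sum to a constant through the blur, leaving no junction dip
    flu = flu * _feather_weight(v_axis, beam, cfg.feather_cm)[None, :]
    return ndimage.gaussian_filter(
        flu, (cfg.penumbra_sigma_cm / res_u, cfg.penumbra_sigma_cm / res_v))


def _axial_depth(grid: GridSpec, gantry_deg: float, cfg: DoseModelConfig):
    """(depth map, inside-body mask) over the axial (x, y) lattice."""
    x = grid.axis_coords(0)[:, None]
    y = grid.axis_coords(1)[None, :]
    th = np.deg2rad(gantry_deg)
    a, b = cfg.body_semiaxis_x_cm, cfg.body_semiaxis_y_cm
    A = (np.sin(th) / a) ** 2 + (np.cos(th) / b) ** 2
    B = 2.0 * (x * np.sin(th) / a**2 + y * np.cos(th) / b**2)
    C = (x / a) ** 2 + (y / b) ** 2 - 1.0
    inside = C <= 0.0
    disc = np.maximum(B**2 - 4.0 * A * C, 0.0)
    s_entry = (-B - np.sqrt(disc)) / (2.0 * A)  # negative: backtrack to skin
    depth = np.where(inside, -s_entry, 0.0)
    return depth, inside


def _raw_beam_dose(beam: Beam, geometry: PatientGeometry,
                   cfg: DoseModelConfig) -> np.ndarray:
    grid = geometry.grid
    geom = LeafGeometry.millennium120()
    res = cfg.fluence_res_cm
    u_axis = np.arange(-20.0, 20.0 + 0.5 * res, res)
    z = grid.axis_coords(2)
    flu = beam_fluence_bev(beam, geom, u_axis, z, cfg)  # v lattice = grid z

    x = grid.axis_coords(0)[:, None]
    y = grid.axis_coords(1)[None, :]
    u_map = _bev_u(x, y, beam.gantry_angle)
    depth, inside = _axial_depth(grid, beam.gantry_angle, cfg)
    attn = np.where(inside, np.exp(-cfg.mu_cm * depth), 0.0)

    dose = np.empty(grid.shape)
    u_flat = u_map.ravel()
    for k in range(z.size):
        dose[:, :, k] = np.interp(u_flat, u_axis, flu[:, k]).reshape(u_map.shape)
    return dose * attn[:, :, None] * beam.beam_mu


def _compensate_junction(total: np.ndarray, geometry: PatientGeometry,
                         cfg: DoseModelConfig) -> np.ndarray:
    """Mild longitudinal rebalancing across the feathered overlap.

    The forward model sums two independently scaled segments whose
    longitudinal dose shapes differ slightly (different gantry sets), which
    a treatment-planning optimizer would iron out by re-weighting beamlet
    fluence across both subfield windows. This emulates that step: the
    slice-mean target dose across the overlap is pulled toward the straight
    line joining its neighbourhood, with the correction capped at +-10% and
    tapered to zero outside the junction band.
    """
    grid = geometry.grid
    ptv = geometry.masks["PTV"].values
    z = grid.axis_coords(2)
    lo = geometry.inlet_z - cfg.feather_cm
    hi = geometry.inlet_z
    prof = np.array([
        total[:, :, k][ptv[:, :, k]].mean() if ptv[:, :, k].any() else np.nan
        for k in range(z.size)
    ])
    kb = int(np.nanargmin(np.abs(z - (lo - 1.5))))
    ka = int(np.nanargmin(np.abs(z - (hi + 1.5))))
    scale = np.ones(z.size)
    band = (z >= z[kb]) & (z <= z[ka]) & np.isfinite(prof)
    ref = np.interp(z[band], [z[kb], z[ka]], [prof[kb], prof[ka]])
    corr = np.clip(ref / prof[band], 0.9, 1.1)
    # full correction inside the overlap, linear taper to the band edges
    w = np.minimum(
        np.clip((z[band] - z[kb]) / max(lo - z[kb], 1e-6), 0.0, 1.0),
        np.clip((z[ka] - z[band]) / max(z[ka] - hi, 1e-6), 0.0, 1.0),
    )
    scale[band] = 1.0 + (corr - 1.0) * w
    return total * scale[None, None, :]


def _flatten_longitudinal(total: np.ndarray, geometry: PatientGeometry,
                          cap: float = 0.1) -> np.ndarray:
    """Optimizer-style longitudinal homogenization for unsegmented plans.

    Pulls the slice-mean target dose toward its median over the target
    span (correction capped at +-``cap``), emulating the fluence
    re-weighting an inverse optimizer applies along a long modulated field.
    Transverse modulation noise is left untouched.
    """
    grid = geometry.grid
    ptv = geometry.masks["PTV"].values
    z = grid.axis_coords(2)
    prof = np.array([
        total[:, :, k][ptv[:, :, k]].mean() if ptv[:, :, k].any() else np.nan
        for k in range(z.size)
    ])
    has = np.isfinite(prof)
    scale = np.ones(z.size)
    ref = np.nanmedian(prof[has])
    scale[has] = np.clip(ref / prof[has], 1.0 - cap, 1.0 + cap)
    return total * scale[None, None, :]


def forward_dose(plan: Plan, geometry: PatientGeometry,
                 cfg: DoseModelConfig | None = None) -> DoseGrid:
    """Deterministic forward dose for a plan on a patient geometry.

    Jaw-locked plans get a per-segment pre-scaling (each segment's mean PTV
    dose in its exclusive longitudinal zone is matched to the prescription)
    so the feathered ramps meet at a common junction level; every plan is
    then globally renormalised so PTV D_95% = 95% of the prescription.
    """
    cfg = cfg or DoseModelConfig()
    grid = geometry.grid
    ptv = geometry.masks["PTV"].values
    z = grid.axis_coords(2)
    rx = plan.prescription_gy

    if plan.technique == "SJL":
        parts = {}
        for seg in ("PTV-C", "PTV-T"):
            seg_dose = np.zeros(grid.shape)
            for beam in plan.beams:
                if beam.segment == seg:
                    seg_dose += _raw_beam_dose(beam, geometry, cfg)
            # match levels in bands just outside the overlap, so the
            # complementary ramps meet at a common junction dose
            if seg == "PTV-C":
                zone = ptv & (z[None, None, :] > geometry.inlet_z + 0.5) \
                           & (z[None, None, :] < geometry.inlet_z + 3.5)
            else:
                lo = geometry.inlet_z - cfg.feather_cm
                zone = ptv & (z[None, None, :] < lo - 0.5) \
                           & (z[None, None, :] > lo - 3.5)
            level = seg_dose[zone].mean()
            parts[seg] = seg_dose * (rx / level)
        total = parts["PTV-C"] + parts["PTV-T"]
    else:
        total = np.zeros(grid.shape)
        for beam in plan.beams:
            total += _raw_beam_dose(beam, geometry, cfg)

    # patient scatter: wide low-amplitude 3D spread of the summed dose (the
    # feathered junction is already continuous, so the blur preserves it)
    sigma_vox = cfg.scatter_sigma_cm / np.asarray(grid.spacing)
    total = total + cfg.scatter_frac * ndimage.gaussian_filter(total, sigma_vox)

    if plan.technique == "SJL":
        total = _compensate_junction(total, geometry, cfg)
    else:
        total = _flatten_longitudinal(total, geometry)

    d95 = np.percentile(total[ptv], 5.0)
    total *= (0.95 * rx) / d95
    return DoseGrid(grid.origin, np.asarray(grid.spacing), total)


def junction_deviation(dose: DoseGrid, geometry: PatientGeometry,
                       cfg: DoseModelConfig | None = None,
                       prescription_gy: float = 50.0) -> float:
    """Max relative junction error (fraction of prescription) across the overlap.

    The longitudinal profile is the mean PTV dose per z-slice; the overlap
    profile is compared against the straight line joining the profile just
    outside the overlap on either side, so a cold or hot junction shows up
    directly as |deviation| / D_p.
    """
    cfg = cfg or DoseModelConfig()
    grid = geometry.grid
    ptv = geometry.masks["PTV"].values
    z = grid.axis_coords(2)
    profile = np.array([
        dose.values[:, :, k][ptv[:, :, k]].mean() if ptv[:, :, k].any() else np.nan
        for k in range(z.size)
    ])
    z_hi = geometry.inlet_z
    z_lo = geometry.inlet_z - cfg.feather_cm
    below = np.nanargmin(np.abs(z - (z_lo - 0.5)))
    above = np.nanargmin(np.abs(z - (z_hi + 0.5)))
    inside = (z >= z_lo) & (z <= z_hi)
    ref = np.interp(z[inside], [z[below], z[above]], [profile[below], profile[above]])
    return float(np.nanmax(np.abs(profile[inside] - ref)) / prescription_gy)


# ------------------------------------------------------------------ cohort


@dataclass
class PatientRecord:
    patient_id: str
    geometry: PatientGeometry
    plans: dict[str, Plan]
    doses: dict[str, DoseGrid]


def generate_patient(seed: int, technique: str,
                     spec: CohortSpec | None = None,
                     geometry: PatientGeometry | None = None):
    """One synthetic patient arm: (Plan, DoseGrid, masks), reproducible from seed.

    Anatomy is drawn from the seed alone so the two techniques of a pair
    share it; plan noise additionally keys on the technique.
    """
    spec = spec or CohortSpec()
    if geometry is None:
        geometry = generate_geometry(
            np.random.default_rng(np.random.SeedSequence([seed, 0])), spec.grid)
    arm = 1 if technique == "EF" else 2
    rng = np.random.default_rng(np.random.SeedSequence([seed, arm]))
    plan = generate_plan(rng, technique, geometry, spec)
    dose = forward_dose(plan, geometry, spec.dose_model)
    return plan, dose, geometry.masks


def generate_cohort(spec: CohortSpec | None = None, seed: int = 20240040) -> list[PatientRecord]:
    """Paired cohort: n anatomy draws, each planned with both techniques."""
    spec = spec or CohortSpec()
    records = []
    for i in range(spec.n_patients):
        patient_seed = int(np.random.default_rng(
            np.random.SeedSequence([seed, i])).integers(0, 2**31 - 1))
        geometry = generate_geometry(
            np.random.default_rng(np.random.SeedSequence([patient_seed, 0])), spec.grid)
        plans, doses = {}, {}
        for tech in ("EF", "SJL"):
            plan, dose, _ = generate_patient(patient_seed, tech, spec, geometry)
            plans[tech], doses[tech] = plan, dose
        records.append(PatientRecord(f"P{i + 1:03d}", geometry, plans, doses))
    return records


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def write_cohort(records: list[PatientRecord], out_dir) -> dict:
    """Write plans (JSON), doses and masks (NRRD) plus a manifest with hashes."""
    from .io import write_grid, write_plan

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"patients": []}
    for rec in records:
        entry = {"id": rec.patient_id, "artifacts": {}}
        for tech in rec.plans:
            pp = out / f"{rec.patient_id}_{tech}_plan.json"
            dp = out / f"{rec.patient_id}_{tech}_dose.nrrd"
            write_plan(rec.plans[tech], pp)
            write_grid(rec.doses[tech], dp)
            entry["artifacts"][f"plan_{tech}"] = pp.name
            entry["artifacts"][f"dose_{tech}"] = dp.name
            entry["artifacts"][f"dose_{tech}_sha256"] = _sha256(rec.doses[tech].values)
        for name, mask in rec.geometry.masks.items():
            mp = out / f"{rec.patient_id}_{name}.nrrd"
            write_grid(mask, mp)
            entry["artifacts"][f"mask_{name}"] = mp.name
        manifest["patients"].append(entry)
    manifest["hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
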