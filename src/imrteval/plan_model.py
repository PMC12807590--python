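"""Data model for IMRT plans, voxel dose grids and structure masks.

Unit conventions, enforced at the boundary so every downstream module may
assume them:

* lengths in cm at the isocenter plane (leaf tips, jaw edges, voxel geometry),
* dose in Gy,
* per-control-point monitor units as dimensionless fractions of the beam MU.

Coordinates follow IEC 61217: leaves travel along X, leaf widths stack along
Y; at gantry/collimator 0 the beam's-eye-view Y axis is the patient's
cranio-caudal axis, so a "longitudinal" jaw window is a Y-jaw window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import AlignmentError, GeometryError

#: leaf-pair gaps narrower than this (cm) are treated as closed everywhere
CLOSURE_TOL_CM = 0.05

_MU_SUM_TOL = 1e-6


@dataclass(frozen=True)
class LeafGeometry:
    """Cross-plane MLC layout: ``n_pairs`` leaf pairs with ``n_pairs + 1``
    strictly increasing band boundaries (cm at isocenter).

    The default is the Varian Millennium-120 layout: 60 pairs spanning
    40 cm, the outer 2 x 10 pairs projecting 1.0 cm and the central 40
    pairs 0.5 cm.
    """

    n_pairs: int
    boundaries: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if b.shape != (self.n_pairs + 1,):
            raise GeometryError(
                f"expected {self.n_pairs + 1} leaf boundaries, got {b.shape}"
            )
        if not np.all(np.diff(b) > 0):
            raise GeometryError("leaf boundaries must be strictly increasing")

    @classmethod
    def millennium120(cls) -> "LeafGeometry":
        widths = np.concatenate([np.full(10, 1.0), np.full(40, 0.5), np.full(10, 1.0)])
        boundaries = np.concatenate([[-20.0], -20.0 + np.cumsum(widths)])
        return cls(60, boundaries, "Millennium-120 (40x0.5 cm central, 20x1.0 cm outer)")

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])


@dataclass
class ControlPoint:
    """One instant of a beam's delivery state.

    ``bank_a`` holds the left (lower-X) leaf tips, ``bank_b`` the right ones;
    ``mu_weight`` is the fraction of the beam's MU delivered at/through this
    control point.
    """

    index: int
    mu_weight: float
    bank_a: np.ndarray
    bank_b: np.ndarray
    jaw_x: tuple[float, float]
    jaw_y: tuple[float, float]

    def __post_init__(self) -> None:
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        self.bank_b = np.asarray(self.bank_b, dtype=float)
        self.jaw_x = (float(self.jaw_x[0]), float(self.jaw_x[1]))
        self.jaw_y = (float(self.jaw_y[0]), float(self.jaw_y[1]))

    def validate(self, geom: LeafGeometry, closure_tol: float = CLOSURE_TOL_CM) -> None:
        if self.bank_a.shape != (geom.n_pairs,) or self.bank_b.shape != (geom.n_pairs,):
            raise GeometryError(
                f"control point {self.index}: expected {geom.n_pairs} leaf "
                f"positions per bank, got {self.bank_a.shape}/{self.bank_b.shape}"
            )
        if self.mu_weight < 0:
            raise GeometryError(f"control point {self.index}: mu_weight < 0")
        overlap = self.bank_a - self.bank_b
        if np.any(overlap > closure_tol):
            i = int(np.argmax(overlap))
            raise GeometryError(
                f"control point {self.index}: bank_a exceeds bank_b by "
                f"{overlap[i]:.3f} cm at pair {i} (tolerance {closure_tol} cm)"
            )
        for name, (lo, hi) in (("jaw_x", self.jaw_x), ("jaw_y", self.jaw_y)):
            if not (lo < hi):
                raise GeometryError(f"control point {self.index}: {name} lo >= hi")
            if abs(lo) > 20.0 + 1e-9 or abs(hi) > 20.0 + 1e-9:
                raise GeometryError(f"control point {self.index}: {name} outside +-20 cm")


@dataclass
class Beam:
    """An ordered control-point sequence at a fixed gantry angle."""

    gantry_angle: float
    control_points: list[ControlPoint]
    beam_mu: float
    label: str = ""
    segment: str | None = None  # "PTV-C" / "PTV-T" for jaw-locked plans

    def validate(self, geom: LeafGeometry) -> None:
        if not self.control_points:
            raise GeometryError(f"beam {self.label!r}: no control points")
        total = sum(cp.mu_weight for cp in self.control_points)
        if abs(total - 1.0) > _MU_SUM_TOL:
            raise GeometryError(
                f"beam {self.label!r}: mu_weights sum to {total}, expected 1"
            )
        for cp in self.control_points:
            cp.validate(geom)


@dataclass
class Plan:
    """A full treatment plan: beams plus prescription context.

    ``technique`` tags the planning strategy: ``"EF"`` (extended-field, one
    long modulated window) or ``"SJL"`` (segmented jaw-locked, two Y-jaw
    windows with a feathered overlap).
    """

    beams: list[Beam]
    prescription_gy: float
    fractions: int
    technique: str
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    leaf_geometry: LeafGeometry = field(default_factory=LeafGeometry.millennium120)

    def validate(self) -> None:
        if self.prescription_gy <= 0:
            raise GeometryError("prescription_gy must be > 0")
        if not self.beams:
            raise GeometryError("plan has no beams")
        for beam in self.beams:
            beam.validate(self.leaf_geometry)
        if self.technique == "SJL":
            if any(b.segment not in ("PTV-C", "PTV-T") for b in self.beams):
                raise GeometryError("SJL plans must label every beam PTV-C or PTV-T")

    @property
    def total_mu(self) -> float:
        return sum(b.beam_mu for b in self.beams)


def _check_grid_fields(origin, spacing, values) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    values = np.asarray(values)
    if origin.shape != (3,) or spacing.shape != (3,):
        raise GeometryError("origin and spacing must be length-3 vectors")
    if values.ndim != 3:
        raise GeometryError("grid values must be a 3D array")
    if np.any(spacing <= 0):
        raise GeometryError("grid spacing must be positive")
    return origin, spacing, values


@dataclass
class DoseGrid:
    """Node-centred voxel dose field: world position = origin + index*spacing.

    ``values`` is indexed ``[ix, iy, iz]`` (x: patient left-right, y:
    anterior-posterior, z: cranio-caudal).
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin, self.spacing, values = _check_grid_fields(
            self.origin, self.spacing, self.values
        )
        self.values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("dose values must be finite")
        if np.any(self.values < 0):
            raise GeometryError("dose values must be non-negative")

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass
class StructureMask:
    """Boolean membership field on the same voxel lattice as its DoseGrid."""

    name: str
    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin, self.spacing, values = _check_grid_fields(
            self.origin, self.spacing, self.values
        )
        self.values = np.asarray(values, dtype=bool)

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_cc(self) -> float:
        return float(self.values.sum()) * self.voxel_volume_cc

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


def check_aligned(dose: DoseGrid, mask: StructureMask, atol: float = 1e-6) -> None:
    """Raise :class:`AlignmentError` unless dose and mask share one lattice."""
    if dose.values.shape != mask.values.shape:
        raise AlignmentError(
            f"shape mismatch: dose {dose.values.shape} vs mask "
            f"{mask.name!r} {mask.values.shape}"
        )
    if not (
        np.allclose(dose.origin, mask.origin, atol=atol)
        and np.allclose(dose.spacing, mask.spacing, atol=atol)
    ):
        raise AlignmentError(f"geometry mismatch between dose and mask {mask.name!r}")
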