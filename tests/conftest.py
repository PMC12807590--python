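"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imrteval import Beam, ControlPoint, LeafGeometry, Plan

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geom() -> LeafGeometry:
    return LeafGeometry.millennium120()


def make_cp(bank_a, bank_b, jaw_x=(-15.0, 15.0), jaw_y=(-15.0, 15.0),
            mu_weight=1.0, index=0, geom=None) -> ControlPoint:
    """Control point with full-length banks; scalars broadcast to 60 pairs."""
    n = (geom.n_pairs if geom is not None else 60)
    bank_a = np.broadcast_to(np.asarray(bank_a, dtype=float), (n,)).copy()
    bank_b = np.broadcast_to(np.asarray(bank_b, dtype=float), (n,)).copy()
    return ControlPoint(index, mu_weight, bank_a, bank_b, jaw_x, jaw_y)


def make_plan(control_points, beam_mu=100.0, gantry=0.0, technique="EF",
              prescription=50.0) -> Plan:
    weights = np.array([cp.mu_weight for cp in control_points], dtype=float)
    weights = weights / weights.sum()
    cps = []
    for i, (cp, w) in enumerate(zip(control_points, weights)):
        cps.append(ControlPoint(i, float(w), cp.bank_a, cp.bank_b, cp.jaw_x, cp.jaw_y))
    plan = Plan([Beam(gantry, cps, beam_mu, "b1")], prescription, 25, technique)
    plan.validate()
    return plan


# ------------------------------------------------------- rasterization oracle

RASTER_CELL_CM = 0.01


def rasterize_aperture(cp: ControlPoint, geom: LeafGeometry,
                       cell: float = RASTER_CELL_CM,
                       closure_tol: float = 0.05):
    """Brute-force raster oracle for aperture area and perimeter.

    Expects every leaf/jaw coordinate to be a multiple of ``cell`` so that
    raster cells are exactly in or out; area is the cell count times the
    cell area and the perimeter is the count of exposed cell edges times the
    cell size.
    """
    x_lo, x_hi = cp.jaw_x
    y_lo, y_hi = cp.jaw_y
    nx = int(round((x_hi - x_lo) / cell))
    ny = int(round((y_hi - y_lo) / cell))
    grid = np.zeros((nx, ny), dtype=bool)
    xs = x_lo + cell * (np.arange(nx) + 0.5)
    ys = y_lo + cell * (np.arange(ny) + 0.5)
    for i in range(geom.n_pairs):
        b_lo = max(geom.boundaries[i], y_lo)
        b_hi = min(geom.boundaries[i + 1], y_hi)
        if b_hi - b_lo <= 0:
            continue
        left = max(cp.bank_a[i], x_lo)
        right = min(cp.bank_b[i], x_hi)
        if right - left < closure_tol:
            continue
        grid |= ((xs[:, None] > left) & (xs[:, None] < right)
                 & (ys[None, :] > b_lo) & (ys[None, :] < b_hi))
    area = grid.sum() * cell * cell
    padded = np.pad(grid, 1)
    edges = (np.abs(np.diff(padded.astype(int), axis=0)).sum()
             + np.abs(np.diff(padded.astype(int), axis=1)).sum())
    return area, edges * cell


def random_snapped_cp(rng: np.random.Generator, geom: LeafGeometry,
                      jaw_x=(-8.0, 8.0), jaw_y=(-6.0, 6.0)) -> ControlPoint:
    """Random aperture with all coordinates snapped to the raster lattice."""
    n = geom.n_pairs
    centers = rng.uniform(jaw_x[0] - 2.0, jaw_x[1] + 2.0, n)
    widths = rng.uniform(0.0, 6.0, n)
    closed = rng.random(n) < 0.3
    widths[closed] = rng.uniform(0.0, 0.04, closed.sum())
    bank_a = np.round(centers - widths / 2, 2)
    bank_b = np.round(centers + widths / 2, 2)
    return make_cp(bank_a, bank_b, jaw_x=jaw_x, jaw_y=jaw_y, geom=geom)
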