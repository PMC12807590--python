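"""DVHs and dosimetric endpoints: V_x, MLD, D_max, D_2%/D_98%, CI, HI, GM.

The DVH is an exact voxel-counting histogram with a fixed 0.05 Gy bin width;
each bin's representative dose is the mean dose of the voxels it holds, so
the DVH-mean equals the exact voxel mean (and EUD with a = 1 equals MLD
exactly). Near-max/near-min doses are read off the cumulative curve by
linear interpolation, matching treatment-planning-system convention rather
than raw voxel percentiles.

Indices:

* CI = V_RI / V_PTV, the volume (anywhere on the grid) receiving at least the
  prescription over the target volume — the literal ratio form, which can
  exceed 1 when prescription dose spills outside the target.
* HI = (D_2% - D_98%) / D_p; 0 means perfectly homogeneous.
* GM = max radial distance of the 50% prescription isodose surface from the
  target centroid minus the equivalent-sphere radius
  R_PTV = (3 V_PTV / 4 pi)^(1/3); smaller GM means a steeper fall-off
  beyond the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .exceptions import EmptyStructureError, UndefinedMetricError
from .plan_model import DoseGrid, StructureMask, check_aligned

DEFAULT_BIN_GY = 0.05


@dataclass
class DVH:
    """Differential DVH: per-bin volume fractions with representative doses."""

    structure: str
    bin_edges: np.ndarray  # (n+1,) Gy
    diff_fraction: np.ndarray  # (n,) sums to 1
    bin_dose: np.ndarray  # (n,) mean voxel dose inside each bin
    total_volume_cc: float
    max_dose: float
    min_dose: float

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """(edges, fraction of volume receiving >= edge); starts at 1, ends at 0."""
        cum = np.concatenate([
            np.cumsum(self.diff_fraction[::-1])[::-1], [0.0]
        ])
        return self.bin_edges, cum

    def volume_at_dose(self, dose_gy: float) -> float:
        """Fraction of the structure receiving at least ``dose_gy`` (linear interp)."""
        edges, cum = self.cumulative()
        if dose_gy <= edges[0]:
            return 1.0
        if dose_gy >= edges[-1]:
            return 0.0
        return float(np.interp(dose_gy, edges, cum))

    def dose_at_volume(self, fraction: float) -> float:
        """Dose D such that ``fraction`` of the volume receives >= D."""
        if not 0.0 < fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        edges, cum = self.cumulative()
        # cum is non-increasing in dose; invert by flipping
        return float(np.interp(fraction, cum[::-1], edges[::-1]))

    @property
    def mean_dose(self) -> float:
        return float(np.sum(self.diff_fraction * self.bin_dose))


def compute_dvh(dose: DoseGrid, mask: StructureMask,
                bin_width: float = DEFAULT_BIN_GY) -> DVH:
    """Exact voxel-counting DVH of ``dose`` inside ``mask``."""
    check_aligned(dose, mask)
    voxels = dose.values[mask.values]
    if voxels.size == 0:
        raise EmptyStructureError(f"structure {mask.name!r} has no voxels")
    top = float(voxels.max())
    n_bins = max(1, int(np.ceil((top + 0.5 * bin_width) / bin_width)))
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(voxels, bins=edges)
    sums, _ = np.histogram(voxels, bins=edges, weights=voxels)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        bin_dose = np.where(counts > 0, sums / np.maximum(counts, 1), centers)
    return DVH(
        structure=mask.name,
        bin_edges=edges,
        diff_fraction=counts / voxels.size,
        bin_dose=bin_dose,
        total_volume_cc=mask.volume_cc,
        max_dose=top,
        min_dose=float(voxels.min()),
    )


def dvh_metrics(dvh: DVH, thresholds_gy=(5, 10, 13, 15, 20, 30)) -> dict:
    """V_x (%), MLD (Gy), D_max, D_2% and D_98% from a DVH."""
    out = {f"V_{t:g}": 100.0 * dvh.volume_at_dose(float(t)) for t in thresholds_gy}
    out["MLD"] = dvh.mean_dose
    out["D_max"] = dvh.max_dose
    out["D_2"] = dvh.dose_at_volume(0.02)
    out["D_98"] = dvh.dose_at_volume(0.98)
    return out


def conformity_index(dose: DoseGrid, ptv: StructureMask, prescription_gy: float) -> float:
    """CI = V_RI / V_PTV with V_RI measured over the whole dose grid."""
    check_aligned(dose, ptv)
    if prescription_gy <= 0:
        raise ValueError("prescription_gy must be > 0")
    v_ptv = ptv.volume_cc
    if v_ptv <= 0:
        raise EmptyStructureError(f"PTV {ptv.name!r} is empty")
    v_ri = float(np.count_nonzero(dose.values >= prescription_gy)) * dose.voxel_volume_cc
    return v_ri / v_ptv


def homogeneity_index(d2: float, d98: float, prescription_gy: float) -> float:
    """HI = (D_2% - D_98%) / D_p."""
    if prescription_gy <= 0:
        raise ValueError("prescription_gy must be > 0")
    return (d2 - d98) / prescription_gy


def equivalent_radius(volume_cc: float) -> float:
    """Radius (cm) of the sphere with the given volume."""
    return float((3.0 * volume_cc / (4.0 * np.pi)) ** (1.0 / 3.0))


def _surface_voxels(field: np.ndarray) -> np.ndarray:
    """Boolean surface of a voxel set (members with a non-member face neighbour)."""
    eroded = ndimage.binary_erosion(field, structure=ndimage.generate_binary_structure(3, 1),
                                    border_value=0)
    return field & ~eroded


def _world_coords(mask_like, index_array: np.ndarray) -> np.ndarray:
    return mask_like.origin[None, :] + index_array * mask_like.spacing[None, :]


def gradient_measure(dose: DoseGrid, ptv: StructureMask,
                     prescription_gy: float) -> tuple[float, float]:
    """(GM, R_PTV) in cm from the 50% prescription isodose surface.

    GM = max over 50%-isodose surface voxels of the Euclidean distance to the
    PTV centroid, minus R_PTV; roughly 0 when the 50% surface hugs the target
    and growing as the fall-off stretches out.
    """
    check_aligned(dose, ptv)
    if ptv.volume_cc <= 0:
        raise EmptyStructureError(f"PTV {ptv.name!r} is empty")
    region = dose.values >= 0.5 * prescription_gy
    if not region.any():
        raise UndefinedMetricError("50% prescription isodose surface does not exist")
    surf_idx = np.argwhere(_surface_voxels(region))
    surf_xyz = _world_coords(dose, surf_idx)
    ptv_idx = np.argwhere(ptv.values)
    centroid = _world_coords(ptv, ptv_idx).mean(axis=0)
    max_radial = float(np.linalg.norm(surf_xyz - centroid[None, :], axis=1).max())
    r_ptv = equivalent_radius(ptv.volume_cc)
    return max_radial - r_ptv, r_ptv


def surface_distance_stats(a: StructureMask | np.ndarray, b: StructureMask | np.ndarray,
                           spacing=None, origin=None) -> dict:
    """One-sided surface distances between two voxel sets (QA helper).

    Returns max/mean of nearest-neighbour distances from surface(a) to
    surface(b), computed with a KD-tree in world units.
    """
    def _surface_points(m):
        if isinstance(m, StructureMask):
            return _world_coords(m, np.argwhere(_surface_voxels(m.values)))
        idx = np.argwhere(_surface_voxels(np.asarray(m, dtype=bool)))
        return np.asarray(origin)[None, :] + idx * np.asarray(spacing)[None, :]

    pa, pb = _surface_points(a), _surface_points(b)
    if pa.size == 0 or pb.size == 0:
        raise EmptyStructureError("surface distance needs two nonempty surfaces")
    d, _ = cKDTree(pb).query(pa)
    return {"max": float(d.max()), "mean": float(d.mean())}


def target_metrics(dose: DoseGrid, ptv: StructureMask, prescription_gy: float,
                   bin_width: float = DEFAULT_BIN_GY) -> dict:
    """All PTV endpoints in one pass: D_2%, D_98%, CI, HI, GM, R_PTV, V_RI."""
    dvh = compute_dvh(dose, ptv, bin_width)
    d2 = dvh.dose_at_volume(0.02)
    d98 = dvh.dose_at_volume(0.98)
    gm, r_ptv = gradient_measure(dose, ptv, prescription_gy)
    ci = conformity_index(dose, ptv, prescription_gy)
    return {
        "D_2": d2,
        "D_98": d98,
        "CI": ci,
        "HI": homogeneity_index(d2, d98, prescription_gy),
        "GM": gm,
        "R_PTV": r_ptv,
        "V_RI": ci * ptv.volume_cc,
    }
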