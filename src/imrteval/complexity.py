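"""Plan-complexity metrics: edge-area metric (EAM) and modulation complexity score (MCS).

EAM is the isoperimetric irregularity of one aperture,

    EAM_i = P_i^2 / (4 pi A_i),

equal to 1 for a disc and 4/pi for any square; higher values mean smaller,
more serrated apertures and hence greater delivery risk. The plan-level value
is the MU-weighted mean over all apertures with positive MU and nonzero area.

MCS combines aperture-area variability (AAV: how much of the beam's maximum
opening each control point uses) and leaf-sequence variability (LSV: how
smoothly neighbouring leaves within a bank line up), averaged over adjacent
control-point intervals and MU-weighted:

    MCS = sum_i MU_i * (AAV_{i-1}+AAV_i)/2 * (LSV_{i-1}+LSV_i)/2 / sum_i MU_i.

Both factors live in [0, 1], so MCS does too; 1 is the simplest deliverable
plan (one static open field), values near 0 indicate heavy modulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aperture import Aperture, build_aperture
from .exceptions import UndefinedMetricError
from .plan_model import Beam, ControlPoint, LeafGeometry, Plan

_EPS = 1e-12


def eam_aperture(ap: Aperture) -> float:
    """EAM of a single aperture; raises for empty apertures (callers filter)."""
    if ap.area <= 0.0:
        raise UndefinedMetricError("EAM undefined for a zero-area aperture")
    return ap.perimeter**2 / (4.0 * math.pi * ap.area)


def in_jaw_pairs(cp: ControlPoint, geom: LeafGeometry) -> np.ndarray:
    """Indices of leaf pairs whose band intersects the Y-jaw window.

    Same row set an aperture uses before closure filtering, so AAV/LSV and
    EAM agree on which leaves count.
    """
    y_lo, y_hi = cp.jaw_y
    lo = np.maximum(geom.boundaries[:-1], y_lo)
    hi = np.minimum(geom.boundaries[1:], y_hi)
    return np.flatnonzero(hi - lo > _EPS)


def _beam_max_openings(beam: Beam, geom: LeafGeometry) -> np.ndarray:
    """Per-pair maximum positive leaf gap attained anywhere in the beam."""
    gaps = np.stack(
        [np.clip(cp.bank_b - cp.bank_a, 0.0, None) for cp in beam.control_points]
    )
    return gaps.max(axis=0)


def aav(cp: ControlPoint, beam: Beam, geom: LeafGeometry | None = None) -> float:
    """Aperture-area variability of one control point relative to its beam.

    Ratio of the summed in-jaw leaf gaps to the summed per-pair maxima over
    the beam's whole control-point sequence; 0 when the beam never opens.
    """
    geom = geom or LeafGeometry.millennium120()
    idx = in_jaw_pairs(cp, geom)
    if idx.size == 0:
        return 0.0
    max_open = _beam_max_openings(beam, geom)[idx]
    denom = float(max_open.sum())
    if denom <= _EPS:
        return 0.0
    gaps = np.clip(cp.bank_b[idx] - cp.bank_a[idx], 0.0, None)
    return float(gaps.sum() / denom)


def _bank_lsv(pos: np.ndarray) -> float:
    n = pos.size
    if n < 2:
        return 1.0  # no adjacent differences to penalise
    pos_max = float(pos.max() - pos.min())
    if pos_max <= _EPS:
        return 1.0  # perfectly aligned bank
    diffs = np.abs(np.diff(pos))
    return float(np.sum(pos_max - diffs) / ((n - 1) * pos_max))


def lsv(cp: ControlPoint, geom: LeafGeometry | None = None) -> float:
    """Leaf-sequence variability: product of the two banks' smoothness factors."""
    geom = geom or LeafGeometry.millennium120()
    idx = in_jaw_pairs(cp, geom)
    return _bank_lsv(cp.bank_a[idx]) * _bank_lsv(cp.bank_b[idx])


def _beam_mcs(beam: Beam, geom: LeafGeometry) -> float:
    aavs = [aav(cp, beam, geom) for cp in beam.control_points]
    lsvs = [lsv(cp, geom) for cp in beam.control_points]
    num = 0.0
    den = 0.0
    for i, cp in enumerate(beam.control_points):
        # first control point pairs with itself so sum(MU_i) is conserved
        j = max(i - 1, 0)
        num += cp.mu_weight * 0.5 * (aavs[j] + aavs[i]) * 0.5 * (lsvs[j] + lsvs[i])
        den += cp.mu_weight
    return num / den if den > _EPS else 0.0


def mcs(plan: Plan) -> float:
    """Plan MCS: MU-weighted pooling of per-beam scores (beam_mu weights)."""
    geom = plan.leaf_geometry
    total_mu = sum(b.beam_mu for b in plan.beams)
    if total_mu <= _EPS:
        return 0.0
    return sum(b.beam_mu * _beam_mcs(b, geom) for b in plan.beams) / total_mu


@dataclass
class ComplexityResult:
    """Plan-level complexity summary with per-CP, per-beam and per-segment detail."""

    eam_plan: float
    mcs: float
    per_cp: list[dict] = field(default_factory=list)
    per_beam: dict[str, dict] = field(default_factory=dict)
    per_segment: dict[str, dict] = field(default_factory=dict)


def eam_plan(plan: Plan) -> float:
    """MU-weighted plan EAM over all nonempty, positive-MU apertures."""
    return compute_complexity(plan).eam_plan


def compute_complexity(plan: Plan) -> ComplexityResult:
    """EAM and MCS for a plan, with per-beam and per-segment aggregates.

    Zero-MU control points and empty apertures contribute to neither sum
    (they deliver no dose); an all-empty plan has no defined EAM.
    """
    geom = plan.leaf_geometry
    per_cp: list[dict] = []
    eam_num = 0.0
    eam_den = 0.0
    seg_acc: dict[str, dict] = {}
    beam_acc: dict[str, dict] = {}

    for beam in plan.beams:
        label = beam.label or f"g{beam.gantry_angle:g}"
        b_num = b_den = 0.0
        for cp in beam.control_points:
            mu_i = cp.mu_weight * beam.beam_mu
            ap = build_aperture(cp, geom)
            rec = {
                "beam": label,
                "segment": beam.segment,
                "cp": cp.index,
                "mu": mu_i,
                "area": ap.area,
                "perimeter": ap.perimeter,
                "aav": aav(cp, beam, geom),
                "lsv": lsv(cp, geom),
                "eam": None,
            }
            if mu_i > _EPS and not ap.is_empty:
                rec["eam"] = eam_aperture(ap)
                eam_num += mu_i * rec["eam"]
                eam_den += mu_i
                b_num += mu_i * rec["eam"]
                b_den += mu_i
            per_cp.append(rec)
        beam_acc[label] = {
            "eam": b_num / b_den if b_den > _EPS else float("nan"),
            "mcs": _beam_mcs(beam, geom),
            "mu": beam.beam_mu,
        }
        seg = beam.segment or "all"
        acc = seg_acc.setdefault(seg, {"eam_num": 0.0, "eam_den": 0.0,
                                       "mcs_num": 0.0, "mu": 0.0})
        acc["eam_num"] += b_num
        acc["eam_den"] += b_den
        acc["mcs_num"] += beam.beam_mu * beam_acc[label]["mcs"]
        acc["mu"] += beam.beam_mu

    if eam_den <= _EPS:
        raise UndefinedMetricError("plan EAM undefined: every aperture is empty")

    per_segment = {
        seg: {
            "eam": acc["eam_num"] / acc["eam_den"] if acc["eam_den"] > _EPS else float("nan"),
            "mcs": acc["mcs_num"] / acc["mu"] if acc["mu"] > _EPS else float("nan"),
            "mu": acc["mu"],
        }
        for seg, acc in seg_acc.items()
    }
    return ComplexityResult(
        eam_plan=eam_num / eam_den,
        mcs=mcs(plan),
        per_cp=per_cp,
        per_beam=beam_acc,
        per_segment=per_segment,
    )
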