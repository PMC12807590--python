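"""Interchange IO: JSON plan schema, NRRD voxel grids, DICOM-RT adapters.

The JSON plan schema is the canonical interchange format::

    {
      "prescription_gy": 50.0, "fractions": 25, "technique": "EF",
      "isocenter": [0, 0, 0],
      "beams": [
        {"gantry_deg": 0.0, "beam_mu": 230.0, "label": "b01",
         "segment": null,
         "control_points": [
            {"mu_weight": 0.25, "bank_a": [...60...], "bank_b": [...60...],
             "jaw_x": [-10, 10], "jaw_y": [-12, 12]}, ...]}, ...]
    }

DICOM-RT Plan / Dose files are normalised into the same in-memory model by
thin :mod:`pydicom` adapters; DICOM is never used internally.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import SimpleITK as sitk

from .exceptions import GeometryError, PlanSchemaError
from .plan_model import Beam, ControlPoint, DoseGrid, LeafGeometry, Plan, StructureMask

PathLike = Union[str, Path]


# ---------------------------------------------------------------- plan schema


def _require(obj: dict, key: str, ctx: str):
    if key not in obj:
        raise PlanSchemaError(f"{ctx}: missing field {key!r}")
    return obj[key]


def plan_to_dict(plan: Plan) -> dict:
    return {
        "prescription_gy": plan.prescription_gy,
        "fractions": plan.fractions,
        "technique": plan.technique,
        "isocenter": list(plan.isocenter),
        "beams": [
            {
                "gantry_deg": beam.gantry_angle,
                "beam_mu": beam.beam_mu,
                "label": beam.label,
                "segment": beam.segment,
                "control_points": [
                    {
                        "mu_weight": cp.mu_weight,
                        "bank_a": cp.bank_a.tolist(),
                        "bank_b": cp.bank_b.tolist(),
                        "jaw_x": list(cp.jaw_x),
                        "jaw_y": list(cp.jaw_y),
                    }
                    for cp in beam.control_points
                ],
            }
            for beam in plan.beams
        ],
    }


def plan_from_dict(doc: dict, geom: LeafGeometry | None = None) -> Plan:
    geom = geom or LeafGeometry.millennium120()
    beams = []
    for bi, bdoc in enumerate(_require(doc, "beams", "plan")):
        ctx = f"beams[{bi}]"
        cps = []
        for ci, cdoc in enumerate(_require(bdoc, "control_points", ctx)):
            cctx = f"{ctx}.control_points[{ci}]"
            cps.append(
                ControlPoint(
                    index=ci,
                    mu_weight=float(_require(cdoc, "mu_weight", cctx)),
                    bank_a=np.asarray(_require(cdoc, "bank_a", cctx), dtype=float),
                    bank_b=np.asarray(_require(cdoc, "bank_b", cctx), dtype=float),
                    jaw_x=tuple(_require(cdoc, "jaw_x", cctx)),
                    jaw_y=tuple(_require(cdoc, "jaw_y", cctx)),
                )
            )
        beams.append(
            Beam(
                gantry_angle=float(_require(bdoc, "gantry_deg", ctx)),
                control_points=cps,
                beam_mu=float(_require(bdoc, "beam_mu", ctx)),
                label=str(bdoc.get("label", f"beam{bi}")),
                segment=bdoc.get("segment"),
            )
        )
    plan = Plan(
        beams=beams,
        prescription_gy=float(_require(doc, "prescription_gy", "plan")),
        fractions=int(_require(doc, "fractions", "plan")),
        technique=str(_require(doc, "technique", "plan")),
        isocenter=tuple(doc.get("isocenter", (0.0, 0.0, 0.0))),
        leaf_geometry=geom,
    )
    plan.validate()
    return plan


def write_plan(plan: Plan, path: PathLike) -> None:
    Path(path).write_text(json.dumps(plan_to_dict(plan)))


def read_plan(path: PathLike, format: str = "plan-schema",
              geom: LeafGeometry | None = None) -> Plan:
    """Read a plan from the JSON schema or from a DICOM-RT Plan file."""
    if format == "plan-schema":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise PlanSchemaError(f"{path}: not valid JSON ({exc})") from exc
        return plan_from_dict(doc, geom)
    if format == "dicom-rt":
        return plan_from_dicom(path, geom)
    raise ValueError(f"unknown plan format {format!r}")


# --------------------------------------------------------------- voxel grids


def _to_sitk(origin: np.ndarray, spacing: np.ndarray, values: np.ndarray) -> sitk.Image:
    # our arrays are [ix, iy, iz]; SimpleITK expects [iz, iy, ix] buffers
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(values, (2, 1, 0))))
    img.SetOrigin(tuple(float(v) for v in origin))
    img.SetSpacing(tuple(float(v) for v in spacing))
    return img


def write_grid(grid: DoseGrid | StructureMask, path: PathLike) -> None:
    """Write a dose grid (float64) or structure mask (uint8) as NRRD."""
    if isinstance(grid, StructureMask):
        img = _to_sitk(grid.origin, grid.spacing, grid.values.astype(np.uint8))
    else:
        img = _to_sitk(grid.origin, grid.spacing, grid.values.astype(np.float64))
    sitk.WriteImage(img, str(path), useCompression=True)


def read_grid(path: PathLike, as_mask: bool = False, name: str = "") -> DoseGrid | StructureMask:
    img = sitk.ReadImage(str(path))
    values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    origin = np.asarray(img.GetOrigin(), dtype=float)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if as_mask:
        return StructureMask(name or Path(path).stem, origin, spacing, values.astype(bool))
    return DoseGrid(origin, spacing, values.astype(float))


# ------------------------------------------------------------- DICOM adapters


def plan_from_dicom(source, geom: LeafGeometry | None = None) -> Plan:
    """Normalise a DICOM-RT Plan (path or pydicom Dataset) into a :class:`Plan`.

    Leaf/jaw positions are converted mm -> cm at isocenter; cumulative
    meterset weights become per-interval fractional MU on the closing control
    point of each interval.
    """
    import pydicom

    ds = source if hasattr(source, "BeamSequence") else pydicom.dcmread(source)
    geom = geom or LeafGeometry.millennium120()

    metersets = {}
    for frac in getattr(ds, "FractionGroupSequence", []):
        for ref in getattr(frac, "ReferencedBeamSequence", []):
            metersets[int(ref.ReferencedBeamNumber)] = float(
                getattr(ref, "BeamMeterset", 0.0)
            )

    beams = []
    for beam_ds in ds.BeamSequence:
        jaw_x = jaw_y = None
        bank_a = bank_b = None
        gantry = 0.0
        raw_cps = []  # (cumulative_weight, bank_a, bank_b, jaw_x, jaw_y)
        for cp_ds in beam_ds.ControlPointSequence:
            gantry = float(getattr(cp_ds, "GantryAngle", gantry))
            for dev in getattr(cp_ds, "BeamLimitingDevicePositionSequence", []):
                pos = np.asarray(dev.LeafJawPositions, dtype=float) / 10.0
                kind = dev.RTBeamLimitingDeviceType
                if kind in ("X", "ASYMX"):
                    jaw_x = (pos[0], pos[1])
                elif kind in ("Y", "ASYMY"):
                    jaw_y = (pos[0], pos[1])
                elif kind in ("MLCX", "MLCY"):
                    n = pos.size // 2
                    if n != geom.n_pairs:
                        raise GeometryError(
                            f"beam {beam_ds.BeamNumber}: {n} leaf pairs, "
                            f"expected {geom.n_pairs}"
                        )
                    bank_a, bank_b = pos[:n].copy(), pos[n:].copy()
            if jaw_x is None or jaw_y is None or bank_a is None:
                raise PlanSchemaError(
                    f"beam {beam_ds.BeamNumber}: first control point lacks "
                    "jaw or MLC positions"
                )
            raw_cps.append(
                (float(cp_ds.CumulativeMetersetWeight), bank_a, bank_b, jaw_x, jaw_y)
            )
        final = raw_cps[-1][0] or 1.0
        cps = []
        if len(raw_cps) == 1:
            cum, ba, bb, jx, jy = raw_cps[0]
            cps.append(ControlPoint(0, 1.0, ba, bb, jx, jy))
        else:
            for i in range(1, len(raw_cps)):
                prev_cum = raw_cps[i - 1][0]
                cum, ba, bb, jx, jy = raw_cps[i]
                cps.append(ControlPoint(i - 1, (cum - prev_cum) / final, ba, bb, jx, jy))
        beam_number = int(getattr(beam_ds, "BeamNumber", len(beams) + 1))
        beams.append(
            Beam(
                gantry_angle=gantry,
                control_points=cps,
                beam_mu=metersets.get(beam_number, 1.0),
                label=str(getattr(beam_ds, "BeamName", f"beam{beam_number}")),
            )
        )

    rx = 50.0
    n_fx = 25
    for frac in getattr(ds, "FractionGroupSequence", []):
        n_fx = int(getattr(frac, "NumberOfFractionsPlanned", n_fx))
    for ref in getattr(ds, "DoseReferenceSequence", []):
        rx = float(getattr(ref, "TargetPrescriptionDose", rx))
    plan = Plan(beams=beams, prescription_gy=rx, fractions=n_fx,
                technique=str(getattr(ds, "RTPlanLabel", "EF"))[:16] or "EF",
                leaf_geometry=geom)
    for beam in plan.beams:  # schema-level validation, MU sums included
        beam.validate(geom)
    return plan


def dose_from_dicom(source) -> DoseGrid:
    """Normalise a DICOM-RT Dose (path or pydicom Dataset) into a DoseGrid."""
    import pydicom

    ds = source if hasattr(source, "DoseGridScaling") else pydicom.dcmread(source)
    scale = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(float) * scale  # [frame, row, col]
    ipp = np.asarray(ds.ImagePositionPatient, dtype=float) / 10.0
    dr, dc = (float(v) / 10.0 for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float) / 10.0
    dz = float(offsets[1] - offsets[0]) if offsets.size > 1 else 1.0
    # frame axis -> z, row -> y, col -> x; reorder to [ix, iy, iz]
    vals = np.transpose(values, (2, 1, 0))
    return DoseGrid(origin=np.array([ipp[0], ipp[1], ipp[2] + offsets[0]]),
                    spacing=np.array([dc, dr, dz]), values=vals)
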