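"""End-to-end plan evaluation and paired-cohort analysis.

``evaluate_plan`` turns one (plan, dose, masks) triple into the full metric
record: complexity (EAM, MCS), target dosimetry (D_2%, D_98%, CI, HI, GM),
per-lung DVH metrics (MLD, V_5..V_30), cord D_max, and EUD-based TCP/NTCP.
``run_cohort`` maps it over a synthetic paired cohort and hands the
long-format table to :func:`imrteval.stats.summarize`.
"""

from __future__ import annotations

import pandas as pd

from .complexity import compute_complexity
from .dose import compute_dvh, dvh_metrics, target_metrics
from .plan_model import DoseGrid, Plan, StructureMask
from .radiobiology import (CORD_MYELOPATHY, LUNG_PNEUMONITIS, TUMOR_ESOPHAGUS,
                           ntcp_from_dvh, tcp_from_dvh)
from .stats import summarize
from .synthetic import CohortSpec, PatientRecord, generate_cohort

LUNG_THRESHOLDS = (5, 10, 13, 15, 20, 30)


def evaluate_plan(plan: Plan, dose: DoseGrid,
                  masks: dict[str, StructureMask]) -> dict[str, float]:
    """All reported endpoints for one plan as a flat {metric: value} record.

    Probabilities (TCP/NTCP) are returned in percent; V_x in percent of the
    organ volume; doses in Gy; GM in cm.
    """
    out: dict[str, float] = {}

    cx = compute_complexity(plan)
    out["EAM"] = cx.eam_plan
    out["MCS"] = cx.mcs

    tm = target_metrics(dose, masks["PTV"], plan.prescription_gy)
    out.update({k: tm[k] for k in ("D_2", "D_98", "CI", "HI", "GM")})

    for side in ("lung_left", "lung_right"):
        dvh = compute_dvh(dose, masks[side])
        m = dvh_metrics(dvh, LUNG_THRESHOLDS)
        out[f"{side}_MLD"] = m["MLD"]
        for t in LUNG_THRESHOLDS:
            out[f"{side}_V_{t}"] = m[f"V_{t}"]
        out[f"NTCP_{side}"] = 100.0 * ntcp_from_dvh(dvh, LUNG_PNEUMONITIS)

    cord_dvh = compute_dvh(dose, masks["cord"])
    out["cord_D_max"] = cord_dvh.max_dose
    out["NTCP_cord"] = 100.0 * ntcp_from_dvh(cord_dvh, CORD_MYELOPATHY)

    for target in ("PTV", "CTV"):
        if target in masks:
            out[f"TCP_{target}"] = 100.0 * tcp_from_dvh(
                compute_dvh(dose, masks[target]), TUMOR_ESOPHAGUS)
    return out


def cohort_table(records: list[PatientRecord]) -> pd.DataFrame:
    """Long-format paired table: one row per (patient, metric) with both arms."""
    rows = []
    for rec in records:
        arms = {
            tech: evaluate_plan(rec.plans[tech], rec.doses[tech], rec.geometry.masks)
            for tech in ("EF", "SJL")
        }
        for metric in arms["EF"]:
            rows.append({
                "patient": rec.patient_id,
                "metric": metric,
                "EF": arms["EF"][metric],
                "SJL": arms["SJL"][metric],
            })
    return pd.DataFrame(rows)


def run_cohort(spec: CohortSpec | None = None, seed: int = 20240040,
               records: list[PatientRecord] | None = None):
    """Generate (or reuse) a paired cohort and produce the comparison table.

    Returns ``(records, paired_table, summary)`` where ``summary`` has one
    Wilcoxon comparison row per metric.
    """
    if records is None:
        records = generate_cohort(spec, seed)
    table = cohort_table(records)
    return records, table, summarize(table)
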