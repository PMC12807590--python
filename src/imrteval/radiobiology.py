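"""EUD-based logistic TCP/NTCP models.

The equivalent uniform dose is the generalized power mean of the DVH,

    EUD = (sum_i v_i D_i^a)^(1/a),

with the tissue exponent ``a`` large-negative for tumors (cold spots
dominate) and positive for parallel/serial organs at risk. Response
probabilities use the standard logistic (Niemierko) form

    TCP  = 1 / (1 + (TCD50/EUD)^(4*gamma50))
    NTCP = 1 / (1 + (TD50/EUD)^(4*gamma50)),

so a uniform dose equal to (T)D50 yields exactly 50%. Physical DVH doses are
used directly — the model carries no fractionation (alpha/beta) correction.

Shipped parameter sets (esophageal tumor; lung pneumonitis; cord myelopathy):

    ==================  =======  ========  =====
    endpoint            D50/Gy   gamma50     a
    ==================  =======  ========  =====
    tumor control        49.09     2.16     -8
    lung                 34.0      0.9       3
    spinal cord          68.6      1.9      13
    ==================  =======  ========  =====
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose import DVH

#: floor (Gy) applied to zero-dose bins when a < 0, where D^a diverges
ZERO_DOSE_FLOOR_GY = 0.01


@dataclass(frozen=True)
class RadiobioParams:
    """Dose-response parameters for one endpoint."""

    d50: float  # TCD50 (tumor) or TD50 (OAR), Gy
    gamma50: float  # normalized slope at the 50% point
    a: float  # volume-effect exponent of the EUD power mean
    endpoint: str = ""

    def __post_init__(self) -> None:
        if self.d50 <= 0 or self.gamma50 <= 0 or self.a == 0:
            raise ValueError("require d50 > 0, gamma50 > 0, a != 0")


TUMOR_ESOPHAGUS = RadiobioParams(49.09, 2.16, -8, "esophageal tumor control")
LUNG_PNEUMONITIS = RadiobioParams(34.0, 0.9, 3, "radiation pneumonitis")
CORD_MYELOPATHY = RadiobioParams(68.6, 1.9, 13, "cord myelopathy")

PARAMETER_SETS = {
    "tumor": TUMOR_ESOPHAGUS,
    "lung": LUNG_PNEUMONITIS,
    "cord": CORD_MYELOPATHY,
}


def eud(dvh: DVH, a: float, zero_dose_floor: float = ZERO_DOSE_FLOOR_GY) -> float:
    """Generalized-mean EUD of a DVH with exponent ``a``."""
    if a == 0:
        raise ValueError("a must be nonzero")
    v = dvh.diff_fraction
    d = dvh.bin_dose.astype(float)
    keep = v > 0
    v, d = v[keep], d[keep]
    if a < 0:
        # D^a diverges at zero dose; the floor is configurable and recorded
        d = np.maximum(d, zero_dose_floor)
    s = float(np.sum(v * np.power(d, a)))
    return float(s ** (1.0 / a))


def _logistic(eud_gy: float, params: RadiobioParams) -> float:
    if eud_gy <= 0:
        raise ValueError("EUD must be positive")
    return 1.0 / (1.0 + (params.d50 / eud_gy) ** (4.0 * params.gamma50))


def tcp(eud_gy: float, params: RadiobioParams = TUMOR_ESOPHAGUS) -> float:
    """Tumor control probability in (0, 1) for a target EUD."""
    return _logistic(eud_gy, params)


def ntcp(eud_gy: float, params: RadiobioParams) -> float:
    """Normal-tissue complication probability in (0, 1) for an OAR EUD."""
    return _logistic(eud_gy, params)


def tcp_from_dvh(dvh: DVH, params: RadiobioParams = TUMOR_ESOPHAGUS) -> float:
    return tcp(eud(dvh, params.a), params)


def ntcp_from_dvh(dvh: DVH, params: RadiobioParams) -> float:
    return ntcp(eud(dvh, params.a), params)
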