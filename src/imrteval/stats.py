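"""Paired Wilcoxon signed-rank testing and cohort summary tables.

The test drops zero differences before ranking (Wilcoxon's original
treatment) and assigns midranks to tied magnitudes. For n <= 25 retained
pairs the two-tailed p-value comes from the exact permutation distribution
of the positive-rank sum, built by generating-function convolution over the
doubled midranks (doubling makes them integers, so ties cost nothing);
larger samples use the normal approximation with tie and continuity
corrections. Raw p-values are reported without multiplicity correction, and
significance is flagged at two thresholds (0.01 primary, 0.05 secondary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError

EXACT_MAX_N = 25


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # positive-rank sum W+
    p_value: float  # two-tailed
    n_used: int  # pairs retained after zero-difference removal
    method: str  # "exact" or "normal"


def _exact_two_tailed(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-tailed p for W+ given doubled midranks and doubled statistic."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(x, y=None) -> WilcoxonResult:
    """Two-tailed paired Wilcoxon signed-rank test.

    ``x`` may be the paired differences directly, or the first sample with
    ``y`` the second (differences are x - y).
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n < 2:
        raise DegenerateDataError(
            "signed-rank test needs >= 2 nonzero paired differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_MAX_N:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        w2 = int(np.rint(2.0 * w_plus))
        return WilcoxonResult(w_plus, _exact_two_tailed(ranks2, w2), n, "exact")

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    diff = w_plus - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)  # continuity-corrected
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, "normal")


#: metric -> report grouping, mirroring the complexity / target / OAR /
#: radiobiological table layout
METRIC_GROUPS = {
    "EAM": "complexity", "MCS": "complexity",
    "D_2": "target", "D_98": "target", "CI": "target", "HI": "target",
    "GM": "target",
    "TCP_PTV": "radiobiology", "TCP_CTV": "radiobiology",
    "NTCP_lung_left": "radiobiology", "NTCP_lung_right": "radiobiology",
    "NTCP_cord": "radiobiology",
}


def _metric_group(metric: str) -> str:
    if metric in METRIC_GROUPS:
        return METRIC_GROUPS[metric]
    if metric.startswith(("lung_", "cord_")):
        return "oar"
    return "other"


def summarize(cohort: pd.DataFrame, alpha: float = 0.01,
              secondary_alpha: float = 0.05) -> pd.DataFrame:
    """One comparison row per metric from a paired long-format cohort table.

    ``cohort`` needs columns ``patient``, ``metric``, ``EF``, ``SJL``.
    Each row reports mean +- std per arm (n-1 denominator), the paired mean
    difference (SJL - EF), the Wilcoxon two-tailed p, and significance flags.
    Metrics whose differences are all zero get p = NaN and a degenerate flag.
    """
    for col in ("patient", "metric", "EF", "SJL"):
        if col not in cohort.columns:
            raise DegenerateDataError(f"cohort table lacks required column {col!r}")
    rows = []
    for metric, sub in cohort.groupby("metric", sort=False):
        if sub[["EF", "SJL"]].isna().any().any() or len(sub) < 2:
            raise DegenerateDataError(f"metric {metric!r}: incomplete pairing")
        ef = sub["EF"].to_numpy()
        sjl = sub["SJL"].to_numpy()
        try:
            res = wilcoxon_signed_rank(sjl, ef)
            p, method = res.p_value, res.method
        except DegenerateDataError:  # all-zero or < 2 nonzero differences
            p, method = float("nan"), "degenerate"
        rows.append({
            "group": _metric_group(metric),
            "metric": metric,
            "n": len(sub),
            "SJL_mean": sjl.mean(), "SJL_std": sjl.std(ddof=1),
            "EF_mean": ef.mean(), "EF_std": ef.std(ddof=1),
            "difference": sjl.mean() - ef.mean(),
            "p_value": p,
            "method": method,
            f"significant_{alpha:g}": bool(p < alpha) if p == p else False,
            f"significant_{secondary_alpha:g}": bool(p < secondary_alpha) if p == p else False,
        })
    return pd.DataFrame(rows)
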