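"""Group-wise distribution parameters for the simulated STEMI cohort.

The cohort simulator is parameterised from the published group summaries of
a 40-patient hyper-acute CMR study, stratified by the 1400 ms mean-T1
threshold into a "low" (< 1400 ms) and a "high" (>= 1400 ms) severity
group. Mean +/- SD rows become Normal distributions, median (IQR) rows
become (zero-inflated) log-normals, and incidence rows become Bernoulli
rates; lesion-extent rows share their zero mass with the corresponding
incidence row.

Group sizes differ by timepoint in the source cohort (dropout and image
quality): 24/15 subjects at the hyper-acute scan, 17/13 at 24 h and 16/13
at 6 months. The simulator generates complete data for every subject and
exposes the hyper-acute sizes as its default.

Two quantities have no published distribution and are synthetic choices,
flagged as such: the per-group mean T1 of the area-at-risk (truncated
normals on either side of 1400 ms) and the troponin value (log-normal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

__all__ = [
    "Normal",
    "MedianIqr",
    "Rate",
    "TruncNormal",
    "GroupRow",
    "GROUP_SIZES",
    "COVARIATES",
    "METRICS",
    "LINKED_INCIDENCE",
    "PERCENT_COLUMNS",
    "T1_CUTOFF_MS",
    "LARGE_INFARCT_CUTOFF_PCT",
]

T1_CUTOFF_MS = 1400.0
LARGE_INFARCT_CUTOFF_PCT = 9.5

GROUP_SIZES = {"hyperacute": (24, 15), "acute_24h": (17, 13), "followup_6m": (16, 13)}


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float


@dataclass(frozen=True)
class TruncNormal:
    """Normal truncated to [lo, hi); sampled by bounded resampling."""

    mean: float
    sd: float
    lo: float = -float("inf")
    hi: float = float("inf")


@dataclass(frozen=True)
class MedianIqr:
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class Rate:
    p: float


Dist = Union[Normal, TruncNormal, MedianIqr, Rate]


@dataclass(frozen=True)
class GroupRow:
    low: Dist
    high: Dist


def _row(low: Dist, high: Dist) -> GroupRow:
    return GroupRow(low=low, high=high)


# --- clinical / procedural covariates (constant across timepoints) ---------

COVARIATES: dict[str, GroupRow] = {
    "age_yr": _row(Normal(61, 12), Normal(62, 10)),
    "male": _row(Rate(0.75), Rate(0.93)),
    "bsa_m2": _row(Normal(2.04, 0.19), Normal(2.10, 0.22)),
    "hypertension": _row(Rate(0.46), Rate(0.27)),
    "dyslipidaemia": _row(Rate(0.33), Rate(0.26)),
    "smoking": _row(Rate(0.33), Rate(0.33)),
    "diabetes": _row(Rate(0.13), Rate(0.0)),
    "ischaemia_time_min": _row(MedianIqr(166, 148, 269), MedianIqr(229, 182, 352)),
    "door_to_balloon_min": _row(MedianIqr(24, 14, 38), MedianIqr(31, 24, 66)),
    "systolic_bp_mmhg": _row(Normal(130, 25), Normal(118, 29)),
    "diastolic_bp_mmhg": _row(Normal(73, 15), Normal(73, 18)),
    "anterior_infarct": _row(Rate(0.21), Rate(0.40)),
    "thrombus_large": _row(Rate(0.42), Rate(0.53)),
    "thrombectomy": _row(Rate(0.58), Rate(0.53)),
    "gp2b3a": _row(Rate(0.13), Rate(0.20)),
    "stent_length_mm": _row(Normal(34, 15), Normal(26, 8)),
    "stent_diameter_mm": _row(MedianIqr(3.5, 3.1, 4.0), MedianIqr(3.5, 3.0, 4.0)),
    "timi3": _row(Rate(0.79), Rate(0.60)),
    "mbg23": _row(Rate(0.67), Rate(0.53)),
    "st_resolution": _row(Rate(0.21), Rate(0.27)),
    # synthetic: no published distribution (high-sensitivity troponin, ng/L)
    "troponin": _row(MedianIqr(2000, 700, 5500), MedianIqr(2000, 700, 5500)),
}

# --- imaging metrics by timepoint ------------------------------------------

METRICS: dict[str, GroupRow] = {
    # hyper-acute (synthetic severity distribution; truncated at the 1400 ms split)
    "aar_mean_t1_ms": _row(
        TruncNormal(1340, 40, hi=T1_CUTOFF_MS), TruncNormal(1460, 50, lo=T1_CUTOFF_MS)
    ),
    "aar_pct_lv": _row(Normal(34, 6), Normal(48, 12)),
    # acute, 24 h
    "edv_ml_24h": _row(Normal(154, 34), Normal(184, 30)),
    "esv_ml_24h": _row(Normal(80, 33), Normal(99, 26)),
    "ef_pct_24h": _row(Normal(49, 11), Normal(46, 10)),
    "lge_pct_24h": _row(Normal(18, 10), Normal(33, 14)),
    "mvo_pct_lv": _row(MedianIqr(0.0, 0.0, 3.0), MedianIqr(4.0, 0.5, 9.5)),
    "imh_area_mm2": _row(MedianIqr(0.0, 0.0, 1.40), MedianIqr(0.76, 0.0, 4.21)),
    # follow-up, 6 months
    "edv_ml_6m": _row(Normal(159, 26), Normal(197, 49)),
    "esv_ml_6m": _row(Normal(74, 19), Normal(99, 40)),
    "ef_pct_6m": _row(Normal(53, 9), Normal(51, 8)),
    "msi_pct": _row(MedianIqr(71, 47, 90), MedianIqr(45, 37, 54)),
    "final_infarct_pct": _row(Normal(12, 9), Normal(27, 9)),
}

#: lesion-extent columns whose zero mass comes from a published incidence
#: (p_zero = 1 - incidence), per group (low, high)
LINKED_INCIDENCE: dict[str, tuple[float, float]] = {
    "mvo_pct_lv": (0.40, 0.85),
    "imh_area_mm2": (0.40, 0.69),
}

#: columns clipped to the [0, 100] percentage range after sampling
PERCENT_COLUMNS = (
    "aar_pct_lv",
    "ef_pct_24h",
    "lge_pct_24h",
    "mvo_pct_lv",
    "ef_pct_6m",
    "msi_pct",
    "final_infarct_pct",
)
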