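"""Per-subject scalar metrics from masks and maps.

"% of LV mass" is an area ratio: lesion pixel area summed over the
acquired slices divided by myocardial pixel area over the same slices,
assuming uniform tissue density and slice thickness. Only the targeted
short-axis slices enter the denominator.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .core import MyoMask, ParametricMap, mask_area
from .study_params import LARGE_INFARCT_CUTOFF_PCT, T1_CUTOFF_MS

__all__ = [
    "extent_pct_lv",
    "mean_t1_of_aar",
    "imh_extent_mm2",
    "compute_msi",
    "classify_t1_group",
    "classify_large_infarct",
]

log = logging.getLogger(__name__)


def _as_list(x) -> list:
    if isinstance(x, (list, tuple)):
        return list(x)
    return [x]


def _spacings(spacing, n: int) -> list[tuple[float, float]]:
    if isinstance(spacing, tuple) and np.isscalar(spacing[0]):
        return [spacing] * n
    spacing = list(spacing)
    if len(spacing) != n:
        raise ValueError("one pixel spacing per slice required")
    return spacing


def extent_pct_lv(lesion, myo, pixel_spacing=(1.0, 1.0)) -> float:
    """Lesion extent as % of the myocardium over the imaged slices.

    ``lesion`` and ``myo`` are masks or per-slice lists of masks;
    ``pixel_spacing`` is one ``(row_mm, col_mm)`` pair or one per slice.
    """
    lesions, myos = _as_list(lesion), _as_list(myo)
    if len(lesions) != len(myos):
        raise ValueError("lesion and myocardium slice counts differ")
    spacings = _spacings(pixel_spacing, len(myos))
    lesion_area = sum(mask_area(m, s) for m, s in zip(lesions, spacings))
    myo_area = sum(mask_area(m, s) for m, s in zip(myos, spacings))
    if myo_area == 0:
        raise ValueError("empty myocardium: %LV undefined")
    return 100.0 * lesion_area / myo_area


def mean_t1_of_aar(t1, aar) -> float:
    """Mean T1 (ms) over all AAR pixels pooled across slices.

    This is the severity metric: the pixelwise average over the delineated
    oedematous area, with no exclusion of any low-T1 core the mask happens
    to contain.
    """
    maps, masks = _as_list(t1), _as_list(aar)
    if len(maps) != len(masks):
        raise ValueError("map and mask slice counts differ")
    values = []
    for m, a in zip(maps, masks):
        vals = m.values if isinstance(m, ParametricMap) else np.asarray(m, dtype=float)
        grid = a.grid if isinstance(a, MyoMask) else np.asarray(a, dtype=bool)
        values.append(vals[grid])
    pooled = np.concatenate(values) if values else np.array([])
    if pooled.size == 0:
        raise ValueError("empty AAR: mean T1 undefined")
    return float(pooled.mean())


def imh_extent_mm2(imh, pixel_spacing=(1.0, 1.0)) -> float:
    """Total haemorrhage area in mm^2, summed over slices."""
    masks = _as_list(imh)
    spacings = _spacings(pixel_spacing, len(masks))
    return float(sum(mask_area(m, s) for m, s in zip(masks, spacings)))


def compute_msi(oedema_pct_24h: float, infarct_pct_6m: float) -> float:
    """Myocardial salvage index (%) from 24 h oedema and 6-month infarct.

    ``100 x (oedema - infarct) / oedema``. A negative index (infarct larger
    than the earlier oedema) is allowed but logged, since it usually marks
    infarct expansion or an oedema underestimate.
    """
    if not (0.0 <= oedema_pct_24h <= 100.0 and 0.0 <= infarct_pct_6m <= 100.0):
        raise ValueError("extents must be percentages in [0, 100]")
    if oedema_pct_24h == 0:
        raise ValueError("oedema extent is 0: salvage index undefined")
    msi = 100.0 * (oedema_pct_24h - infarct_pct_6m) / oedema_pct_24h
    if msi < 0:
        log.warning("negative salvage index %.1f%%: infarct exceeds oedema", msi)
    return msi


def classify_t1_group(mean_t1: float, cutoff: float = T1_CUTOFF_MS) -> str:
    """Severity group from the mean T1 of the AAR: HIGH iff >= cutoff (ties HIGH)."""
    if not mean_t1 > 0:
        raise ValueError("mean T1 must be positive")
    return "HIGH" if mean_t1 >= cutoff else "LOW"


def classify_large_infarct(final_lge_pct: float, cutoff: float = LARGE_INFARCT_CUTOFF_PCT) -> bool:
    """Large final infarct iff the 6-month LGE extent strictly exceeds 9.5 %LV."""
    if not 0.0 <= final_lge_pct <= 100.0:
        raise ValueError("infarct extent must be a percentage in [0, 100]")
    return final_lge_pct > cutoff
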