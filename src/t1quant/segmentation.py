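"""Threshold-based delineation of oedema, infarct, no-reflow and haemorrhage.

All operators work on a single co-registered short-axis slice and are fully
deterministic. The reference statistics come from a remote myocardial ROI
placed 180 degrees opposite the injured sector:

* area-at-risk (AAR) on native T1: pixels strictly above
  ``remote_mean + 2 x remote_SD`` (sample SD, n-1 denominator);
* infarct (LGE): signal intensity strictly above ``remote_mean + 5 x SD``,
  with enclosed hypointense no-reflow (MVO) cores added back;
* MVO: connected hypointense components (SI strictly below
  ``remote_mean + 2 x SD``) whose every myocardial neighbour belongs to the
  supra-threshold LGE mask — an automated, deterministic surrogate for the
  manual delineation of dark cores inside the enhanced region;
* haemorrhage (IMH) on T2*: connected components darker than the AAR
  periphery by 2 SD *and* with a mean T2* below 20 ms (dual criterion).

Tie-breaking is fixed: hyperintense rules use strict ``>``, hypointense
rules strict ``<``, so pixels exactly at a threshold are never lesion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import (
    AngularSector,
    MaskRole,
    MyoMask,
    ParametricMap,
    assert_lesion_invariants,
    centroid_of,
    opposite_angle,
    pixel_angles,
)

__all__ = [
    "RemoteStats",
    "SegmentationResult",
    "place_remote_roi",
    "segment_aar",
    "segment_lge",
    "segment_mvo",
    "segment_imh",
    "segment_study",
]

_CROSS = ndimage.generate_binary_structure(2, 1)   # 4-connectivity
_SQUARE = ndimage.generate_binary_structure(2, 2)  # 8-connectivity


@dataclass(frozen=True)
class RemoteStats:
    """Mean and sample SD (n-1) of a map over the remote reference ROI."""

    mean: float
    sd: float
    n: int

    def threshold(self, multiplier: float) -> float:
        return self.mean + multiplier * self.sd


def _grid(mask) -> np.ndarray:
    return mask.grid if isinstance(mask, MyoMask) else np.asarray(mask, dtype=bool)


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, ParametricMap) else np.asarray(m, dtype=float)


def remote_stats(values, roi) -> RemoteStats:
    roi = _grid(roi)
    sample = _values(values)[roi]
    if sample.size < 2:
        raise ValueError("remote ROI must contain at least 2 pixels")
    return RemoteStats(
        mean=float(np.mean(sample)), sd=float(np.std(sample, ddof=1)), n=int(sample.size)
    )


def place_remote_roi(
    myo,
    injured_center: float,
    width: float = 60.0,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> MyoMask:
    """Transmural remote-reference sector 180 degrees opposite the injury.

    The sector of the given angular ``width`` is centred at
    ``opposite_angle(injured_center)`` about the centroid of the myocardial
    ring. ``width`` of 360 degenerates to the whole ring and is warned
    about.
    """
    myo_grid = _grid(myo)
    if not 0.0 < width <= 360.0:
        raise ValueError("ROI width must be in (0, 360] degrees")
    if width == 360.0:
        warnings.warn("remote ROI width 360 degrees covers the entire ring", stacklevel=2)
    center = centroid_of(myo_grid)
    sector = AngularSector(opposite_angle(injured_center), width)
    angles = pixel_angles(myo_grid.shape, center, pixel_spacing)
    roi = myo_grid & sector.contains(angles)
    if not roi.any():
        raise ValueError("remote ROI is empty (degenerate myocardial ring)")
    return MyoMask(roi, MaskRole.REMOTE_ROI)


def _ring_holes(mask: np.ndarray, myo: np.ndarray) -> np.ndarray:
    """Myocardial pixels topologically enclosed by ``mask`` within the ring.

    The LV cavity (the non-myocardial region enclosed by the ring) counts
    as part of the enclosure, so a subendocardial pocket walled in by
    ``mask`` and the cavity is a hole; the remote myocardium, which reaches
    the border-connected outside of the ring, never is. Holes are computed
    with 4-connected background flooding.
    """
    outside = ~ndimage.binary_fill_holes(myo, structure=_CROSS)
    cavity = ~myo & ~outside
    enclosing = mask | cavity
    filled = ndimage.binary_fill_holes(enclosing, structure=_CROSS)
    return filled & ~enclosing & myo


def _remove_small_islands(mask: np.ndarray, min_px: int) -> np.ndarray:
    if min_px <= 1:
        return mask
    labels, n = ndimage.label(mask, structure=_CROSS)
    keep = np.zeros_like(mask)
    for lbl in range(1, n + 1):
        comp = labels == lbl
        if comp.sum() >= min_px:
            keep |= comp
    return keep


def segment_aar(
    t1,
    myo,
    roi,
    multiplier: float = 2.0,
    *,
    fill_holes: bool = False,
    min_island_px: int = 0,
) -> tuple[MyoMask, float]:
    """Delineate the oedematous area-at-risk on a native T1 map.

    The threshold is ``remote_mean + multiplier x remote_SD`` over the
    reference ROI; the AAR is every myocardial pixel strictly above it,
    excluding the reference sector itself (the remote ROI is disjoint from
    the AAR by definition). With ``fill_holes`` enabled, hypointense cores
    completely enclosed by the AAR (a "step-down" no-reflow core) are added
    back into the mask.

    Returns ``(mask, threshold_ms)``.
    """
    myo_grid, roi_grid = _grid(myo), _grid(roi)
    if np.any(roi_grid & ~myo_grid):
        raise ValueError("remote ROI must be a subset of the myocardium")
    stats = remote_stats(t1, roi_grid)
    thr = stats.threshold(multiplier)
    aar = myo_grid & ~roi_grid & (_values(t1) > thr)
    aar = _remove_small_islands(aar, min_island_px)
    if fill_holes and aar.any():
        aar = aar | _ring_holes(aar, myo_grid)
    return MyoMask(aar, MaskRole.AAR), thr


def segment_mvo(
    lge_si,
    myo,
    lge_initial,
    roi_stats: RemoteStats,
    multiplier: float = 2.0,
) -> MyoMask:
    """Hypointense no-reflow cores enclosed by the supra-threshold LGE mask.

    Enclosure is topological: the pocket must be a planar hole of the
    supra-threshold mask together with the LV cavity, so a subendocardial
    core counts as enclosed while the remote myocardium (which reaches the
    outside of the ring) never does. Within the enclosed pockets, pixels
    with signal strictly below ``remote_mean + multiplier x SD`` are MVO.
    An empty mask is a valid result.
    """
    myo_grid = _grid(myo)
    lge_grid = _grid(lge_initial)
    holes = _ring_holes(lge_grid, myo_grid)
    mvo = holes & (_values(lge_si) < roi_stats.threshold(multiplier))
    return MyoMask(mvo, MaskRole.MVO)


def segment_lge(
    lge_si,
    myo,
    roi,
    multiplier: float = 5.0,
    *,
    include_mvo: bool = True,
    mvo_multiplier: float = 2.0,
    min_island_px: int = 0,
) -> tuple[MyoMask, float, MyoMask]:
    """Delineate the enhanced (infarcted) region on the LGE signal map.

    The supra-threshold mask uses ``remote_mean + multiplier x SD``; when
    ``include_mvo`` is set (the default), enclosed hypointense cores found
    by :func:`segment_mvo` are merged into the final mask, since a
    no-reflow core is infarcted tissue despite its low signal.

    Returns ``(final_lge_mask, threshold_si, mvo_mask)``.
    """
    myo_grid, roi_grid = _grid(myo), _grid(roi)
    if np.any(roi_grid & ~myo_grid):
        raise ValueError("remote ROI must be a subset of the myocardium")
    stats = remote_stats(lge_si, roi_grid)
    thr = stats.threshold(multiplier)
    initial = myo_grid & (_values(lge_si) > thr)
    initial = _remove_small_islands(initial, min_island_px)
    if include_mvo:
        mvo = segment_mvo(lge_si, myo_grid, initial, stats, mvo_multiplier)
    else:
        mvo = MyoMask(np.zeros_like(myo_grid), MaskRole.MVO)
    final = initial | mvo.grid
    return MyoMask(final, MaskRole.LGE), thr, mvo


def segment_imh(
    t2star,
    aar,
    *,
    t2star_cutoff: float = 20.0,
    multiplier: float = 2.0,
) -> tuple[MyoMask, Optional[float]]:
    """Intramyocardial haemorrhage on the T2* map (dual criterion).

    The periphery of the oedematous region is the 1-pixel morphological
    inner boundary of the AAR (4-connected erosion). Candidate components
    are AAR pixels with T2* strictly below
    ``periphery_mean - multiplier x periphery_SD``; a component qualifies
    as haemorrhage only if its mean T2* is below ``t2star_cutoff`` (20 ms).

    Returns ``(mask, core_mean_t2star)``; the core mean is ``None`` when no
    component qualifies.
    """
    aar_grid = _grid(aar)
    if not aar_grid.any():
        raise ValueError("AAR mask is empty; haemorrhage search undefined")
    vals = _values(t2star)
    periphery = aar_grid & ~ndimage.binary_erosion(aar_grid, structure=_CROSS)
    psample = vals[periphery]
    if psample.size < 2:
        raise ValueError("AAR periphery has fewer than 2 pixels")
    thr = float(np.mean(psample)) - multiplier * float(np.std(psample, ddof=1))
    candidate = aar_grid & (vals < thr)
    out = np.zeros_like(aar_grid)
    labels, n = ndimage.label(candidate, structure=_CROSS)
    for lbl in range(1, n + 1):
        comp = labels == lbl
        if float(vals[comp].mean()) < t2star_cutoff:
            out |= comp
    mask = MyoMask(out, MaskRole.IMH)
    core_mean = float(vals[out].mean()) if out.any() else None
    return mask, core_mean


@dataclass(frozen=True)
class SegmentationResult:
    """All masks and provenance from one slice's segmentation."""

    remote_roi: MyoMask
    aar: MyoMask
    aar_threshold_ms: float
    lge: MyoMask
    lge_threshold_si: float
    mvo: MyoMask
    imh: MyoMask
    imh_core_mean_t2star: Optional[float]
    provenance: dict = field(default_factory=dict)


def segment_study(
    t1: ParametricMap,
    t2star: ParametricMap,
    lge_si: ParametricMap,
    myo,
    injured_center: float,
    roi_width: float = 60.0,
    *,
    aar_multiplier: float = 2.0,
    lge_multiplier: float = 5.0,
    mvo_multiplier: float = 2.0,
    imh_multiplier: float = 2.0,
    imh_t2star_cutoff: float = 20.0,
    fill_aar_holes: bool = False,
    min_island_px: int = 0,
) -> SegmentationResult:
    """Run the full single-slice segmentation chain and check invariants."""
    for m in (t2star, lge_si):
        if m.shape != t1.shape:
            raise ValueError("maps must share one grid")
    myo_grid = _grid(myo)
    if myo_grid.shape != t1.shape:
        raise ValueError("myocardium mask shape does not match the maps")

    roi = place_remote_roi(myo_grid, injured_center, roi_width, t1.pixel_spacing)
    aar_raw, aar_thr = segment_aar(
        t1, myo_grid, roi, aar_multiplier,
        fill_holes=False, min_island_px=min_island_px,
    )
    # the injured region including any enclosed low-T1 core: a no-reflow
    # "step-down" punches a hole in the raw 2SD mask, but haemorrhage lives
    # inside that core, so the IMH search always uses the filled region
    aar_filled = MyoMask(aar_raw.grid | _ring_holes(aar_raw.grid, myo_grid), MaskRole.AAR)
    aar = aar_filled if fill_aar_holes else aar_raw
    lge, lge_thr, mvo = segment_lge(
        lge_si, myo_grid, roi, lge_multiplier,
        mvo_multiplier=mvo_multiplier, min_island_px=min_island_px,
    )
    imh, imh_core_mean = segment_imh(
        t2star, aar_filled, t2star_cutoff=imh_t2star_cutoff, multiplier=imh_multiplier
    )

    t1_stats = remote_stats(t1, roi)
    si_stats = remote_stats(lge_si, roi)
    result = SegmentationResult(
        remote_roi=roi,
        aar=aar,
        aar_threshold_ms=aar_thr,
        lge=lge,
        lge_threshold_si=lge_thr,
        mvo=mvo,
        imh=imh,
        imh_core_mean_t2star=imh_core_mean,
        provenance={
            "remote_t1": {"mean": t1_stats.mean, "sd": t1_stats.sd, "n": t1_stats.n},
            "remote_lge_si": {"mean": si_stats.mean, "sd": si_stats.sd, "n": si_stats.n},
            "injured_center_deg": injured_center,
            "roi_width_deg": roi_width,
            "aar_multiplier": aar_multiplier,
            "lge_multiplier": lge_multiplier,
            "mvo_multiplier": mvo_multiplier,
            "imh_multiplier": imh_multiplier,
            "imh_t2star_cutoff_ms": imh_t2star_cutoff,
            "fill_aar_holes": fill_aar_holes,
            "min_island_px": min_island_px,
        },
    )
    assert_lesion_invariants(myo_grid, remote_roi=roi, aar=aar, lge=lge, mvo=mvo)
    # the haemorrhage subset invariant holds against the filled injured region
    assert_lesion_invariants(myo_grid, aar=aar_filled, imh=imh)
    return result
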