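"""Geometric primitives and shared containers for short-axis parametric maps.

Conventions used throughout the package
---------------------------------------
* Images are 2-D ``(row, col)`` grids, 0-based, pixel-centre coordinates.
* Angles are degrees in ``[0, 360)``, measured about the myocardial
  centroid from the +col axis toward the +row axis.
* Physical distances are millimetres; anisotropic pixel spacing is applied
  before computing radii and angles, so sectors and annuli are circular in
  physical space, not in index space.
* Areas are ``count(true) x row_mm x col_mm`` (mm^2); "% of LV mass" is an
  area ratio under a uniform-density, uniform-slice-thickness assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MapKind",
    "MaskRole",
    "Timepoint",
    "ParametricMap",
    "MyoMask",
    "AngularSector",
    "opposite_angle",
    "angular_difference",
    "pixel_angles",
    "pixel_radii",
    "centroid_of",
    "mask_area",
    "assert_lesion_invariants",
]


class MapKind(str, Enum):
    """Which quantity a parametric map holds."""

    T1 = "T1"          # longitudinal relaxation time, ms
    T2STAR = "T2STAR"  # effective transverse relaxation time, ms
    LGE_SI = "LGE_SI"  # late gadolinium enhancement signal intensity, a.u.


class MaskRole(str, Enum):
    MYOCARDIUM = "MYOCARDIUM"
    REMOTE_ROI = "REMOTE_ROI"
    AAR = "AAR"
    LGE = "LGE"
    MVO = "MVO"
    IMH = "IMH"


class Timepoint(str, Enum):
    HYPERACUTE = "HYPERACUTE"    # within 3 h of reperfusion
    ACUTE_24H = "ACUTE_24H"
    FOLLOWUP_6M = "FOLLOWUP_6M"


@dataclass(frozen=True)
class ParametricMap:
    """A single 2-D quantitative map with its pixel geometry.

    Parameters
    ----------
    values
        2-D float array. T1 and T2* are in milliseconds, LGE signal
        intensity is in arbitrary units.
    pixel_spacing
        ``(row_mm, col_mm)``, both strictly positive.
    slice_thickness
        Slice thickness in mm, strictly positive.
    kind
        What the map measures (:class:`MapKind`).
    slice_index
        Position of this slice in its short-axis stack (0-based).
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    kind: MapKind
    slice_index: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("map values must be a non-empty 2-D grid")
        if not np.all(np.isfinite(values)):
            raise ValueError("map values must be finite")
        object.__setattr__(self, "values", values)
        rs, cs = self.pixel_spacing
        if not (rs > 0 and cs > 0):
            raise ValueError("pixel_spacing must be strictly positive")
        if not self.slice_thickness > 0:
            raise ValueError("slice_thickness must be strictly positive")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])


@dataclass(frozen=True)
class MyoMask:
    """A boolean mask on the myocardial grid, tagged with its role."""

    grid: np.ndarray
    role: MaskRole

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.dtype != bool:
            grid = grid.astype(bool)
        if grid.ndim != 2 or grid.size == 0:
            raise ValueError("mask grid must be a non-empty 2-D boolean grid")
        object.__setattr__(self, "grid", grid)

    @property
    def n_pixels(self) -> int:
        return int(self.grid.sum())

    def centroid(self) -> tuple[float, float]:
        return centroid_of(self.grid)

    def area_mm2(self, pixel_spacing: tuple[float, float]) -> float:
        return mask_area(self, pixel_spacing)


def opposite_angle(a: float) -> float:
    """Angle 180 degrees opposite ``a`` (the remote-reference direction).

    ``a`` must lie in ``[0, 360)``; the result does too.
    """
    if not 0.0 <= a < 360.0:
        raise ValueError(f"angle must be in [0, 360), got {a!r}")
    return (a + 180.0) % 360.0


def angular_difference(a, b):
    """Smallest absolute angular distance between ``a`` and ``b`` in degrees."""
    return np.abs((np.asarray(a, dtype=float) - b + 180.0) % 360.0 - 180.0)


@dataclass(frozen=True)
class AngularSector:
    """An angular sector about the myocardial centroid.

    ``center_angle`` in ``[0, 360)`` degrees, ``width`` in ``(0, 360]``
    degrees. Membership is inclusive at both edges.
    """

    center_angle: float
    width: float
    transmural: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.center_angle < 360.0:
            raise ValueError("center_angle must be in [0, 360)")
        if not 0.0 < self.width <= 360.0:
            raise ValueError("width must be in (0, 360]")

    def contains(self, angles) -> np.ndarray:
        if self.width == 360.0:
            return np.ones(np.shape(angles), dtype=bool)
        return angular_difference(angles, self.center_angle) <= self.width / 2.0

    def opposite(self) -> "AngularSector":
        return AngularSector(opposite_angle(self.center_angle), self.width, self.transmural)


def pixel_angles(
    shape: tuple[int, int],
    center: tuple[float, float],
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Per-pixel angle (degrees in [0, 360)) about ``center``.

    Angles are measured from the +col axis toward the +row axis in
    physical (mm) coordinates.
    """
    rr, cc = np.indices(shape, dtype=float)
    dr = (rr - center[0]) * pixel_spacing[0]
    dc = (cc - center[1]) * pixel_spacing[1]
    return np.degrees(np.arctan2(dr, dc)) % 360.0


def pixel_radii(
    shape: tuple[int, int],
    center: tuple[float, float],
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Per-pixel physical distance (mm) from ``center``."""
    rr, cc = np.indices(shape, dtype=float)
    dr = (rr - center[0]) * pixel_spacing[0]
    dc = (cc - center[1]) * pixel_spacing[1]
    return np.hypot(dr, dc)


def centroid_of(mask: np.ndarray) -> tuple[float, float]:
    """Centroid (row, col) of the true pixels of ``mask``."""
    grid = mask.grid if isinstance(mask, MyoMask) else np.asarray(mask, dtype=bool)
    idx = np.argwhere(grid)
    if idx.size == 0:
        raise ValueError("cannot take the centroid of an empty mask")
    r, c = idx.mean(axis=0)
    return float(r), float(c)


def mask_area(mask, pixel_spacing: tuple[float, float]) -> float:
    """Area of a mask in mm^2: ``count(true) x row_mm x col_mm``."""
    grid = mask.grid if isinstance(mask, MyoMask) else np.asarray(mask, dtype=bool)
    rs, cs = pixel_spacing
    if not (rs > 0 and cs > 0):
        raise ValueError("pixel_spacing must be strictly positive")
    return float(grid.sum()) * float(rs) * float(cs)


def _as_grid(mask) -> np.ndarray:
    return mask.grid if isinstance(mask, MyoMask) else np.asarray(mask, dtype=bool)


def assert_lesion_invariants(
    myocardium,
    *,
    remote_roi=None,
    aar=None,
    lge=None,
    mvo=None,
    imh=None,
) -> None:
    """Raise ``AssertionError`` unless the mask set-inclusion invariants hold.

    Every lesion/ROI mask must be a subset of the myocardium; MVO must be
    inside the LGE region; IMH inside the AAR; the remote reference ROI must
    be disjoint from the AAR.
    """
    myo = _as_grid(myocardium)
    named = {"remote_roi": remote_roi, "aar": aar, "lge": lge, "mvo": mvo, "imh": imh}
    for name, mask in named.items():
        if mask is None:
            continue
        grid = _as_grid(mask)
        if grid.shape != myo.shape:
            raise AssertionError(f"{name} mask shape {grid.shape} != myocardium {myo.shape}")
        if np.any(grid & ~myo):
            raise AssertionError(f"{name} mask is not a subset of the myocardium")
    if mvo is not None and lge is not None and np.any(_as_grid(mvo) & ~_as_grid(lge)):
        raise AssertionError("MVO mask is not a subset of the LGE mask")
    if imh is not None and aar is not None and np.any(_as_grid(imh) & ~_as_grid(aar)):
        raise AssertionError("IMH mask is not a subset of the AAR mask")
    if remote_roi is not None and aar is not None and np.any(_as_grid(remote_roi) & _as_grid(aar)):
        raise AssertionError("remote ROI overlaps the AAR")
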