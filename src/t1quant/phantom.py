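"""Digital short-axis left-ventricular phantoms with known ground truth.

The phantom is an annular myocardial ring on a rectangular grid. An injured
angular sector carries elevated native T1 (oedema); inside it an optional
infarct sub-region carries elevated LGE signal, an optional subendocardial
microvascular-obstruction (MVO) core carries a "step-down" in T1 and
hypointense LGE signal, and an optional haemorrhage (IMH) core carries a
low T2*. Independent Gaussian noise of configurable standard deviation is
added to each map. Ground-truth masks for every compartment are returned,
so downstream segmentation can be scored pixel by pixel.

Default tissue values follow the conditions exercised throughout the test
suite: remote T1 1200 ms with an oedema elevation of +300 ms and 30 ms
noise; remote T2* 35 ms with haemorrhage cores below 20 ms; LGE signal 100
(remote) vs 300 (infarct) with 10 a.u. noise. The default injured sector is
144 degrees wide — about 40 % of the ring, matching the typical acute
area-at-risk burden. The default grid uses the 0.9 mm reconstructed
in-plane resolution of ShMOLLI T1 maps, which sets a realistic pixel count
for the myocardial ring and the remote reference ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .core import (
    AngularSector,
    MapKind,
    MaskRole,
    MyoMask,
    ParametricMap,
    assert_lesion_invariants,
    pixel_angles,
    pixel_radii,
)

__all__ = [
    "RegionSpec",
    "MvoCoreSpec",
    "ImhCoreSpec",
    "NoiseSpec",
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
]


@dataclass(frozen=True)
class RegionSpec:
    """A sub-region of the injured sector.

    ``sector_fraction`` scales the angular width relative to the injured
    sector (same centre); ``radial_range`` bounds the region in wall-depth
    fractions, 0 at the endocardium and 1 at the epicardium.
    """

    sector_fraction: float = 1.0
    radial_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.sector_fraction <= 1.0:
            raise ValueError("sector_fraction must be in (0, 1]")
        lo, hi = self.radial_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("radial_range must satisfy 0 <= lo < hi <= 1")


@dataclass(frozen=True)
class MvoCoreSpec(RegionSpec):
    """Subendocardial no-reflow core: T1 step-down, hypointense LGE signal."""

    sector_fraction: float = 0.5
    radial_range: tuple[float, float] = (0.0, 0.4)
    t1_offset: float = -250.0   # ms, relative to the oedematous T1 (negative)
    lge_si_low: float = 80.0    # a.u., below the remote signal

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.t1_offset >= 0:
            raise ValueError("MVO t1_offset must be negative (a step-down)")


@dataclass(frozen=True)
class ImhCoreSpec(RegionSpec):
    """Intramyocardial haemorrhage core: low T2*."""

    sector_fraction: float = 0.4
    radial_range: tuple[float, float] = (0.25, 0.6)
    t2star_core: float = 12.0  # ms, must be < 20 to satisfy the IMH criterion

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.t2star_core < 20.0:
            raise ValueError("IMH core T2* must be < 20 ms")


@dataclass(frozen=True)
class NoiseSpec:
    """Per-map Gaussian noise standard deviations (native map units)."""

    t1: float = 30.0
    t2star: float = 2.0
    lge_si: float = 10.0

    def __post_init__(self) -> None:
        if min(self.t1, self.t2star, self.lge_si) < 0:
            raise ValueError("noise SDs must be >= 0")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PhantomSpec:
    grid_size: tuple[int, int] = (96, 96)
    pixel_spacing: tuple[float, float] = (0.9, 0.9)
    slice_thickness: float = 8.0
    center: Optional[tuple[float, float]] = None  # defaults to the grid centre
    endo_radius: float = 22.0  # mm
    epi_radius: float = 32.0   # mm
    aar_sector: AngularSector = field(default_factory=lambda: AngularSector(90.0, 144.0))
    remote_t1: float = 1200.0
    aar_delta_t1: float = 300.0
    infarct_region: Optional[RegionSpec] = field(
        default_factory=lambda: RegionSpec(sector_fraction=1.0, radial_range=(0.0, 0.7))
    )
    mvo_core: Optional[MvoCoreSpec] = None
    imh_core: Optional[ImhCoreSpec] = None
    remote_t2star: float = 35.0
    lge_si_remote: float = 100.0
    lge_si_infarct: float = 300.0
    noise_sd: NoiseSpec = field(default_factory=NoiseSpec)
    slice_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.endo_radius < self.epi_radius:
            raise ValueError("radii must satisfy 0 < endo_radius < epi_radius")
        rows, cols = self.grid_size
        if rows < 8 or cols < 8:
            raise ValueError("grid_size too small for an annulus")

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        rows, cols = self.grid_size
        return ((rows - 1) / 2.0, (cols - 1) / 2.0)


@dataclass(frozen=True)
class Phantom:
    """Generated maps plus ground-truth masks."""

    t1: ParametricMap
    t2star: ParametricMap
    lge_si: ParametricMap
    myocardium: MyoMask
    truth_aar: MyoMask
    truth_lge: MyoMask
    truth_mvo: MyoMask
    truth_imh: MyoMask
    spec: PhantomSpec

    @property
    def center(self) -> tuple[float, float]:
        return self.spec.resolved_center()


def _sub_sector(parent: AngularSector, fraction: float) -> AngularSector:
    return AngularSector(parent.center_angle, parent.width * fraction, parent.transmural)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build one short-axis phantom slice from ``spec``.

    The construction is fully deterministic given ``spec.seed``: noise
    fields are drawn from ``numpy.random.default_rng(seed)`` in the fixed
    order T1, T2*, LGE.
    """
    center = spec.resolved_center()
    radii = pixel_radii(spec.grid_size, center, spec.pixel_spacing)
    angles = pixel_angles(spec.grid_size, center, spec.pixel_spacing)

    myo = (radii >= spec.endo_radius) & (radii <= spec.epi_radius)
    if not myo.any():
        raise ValueError("annulus does not intersect the grid")
    wall = (radii - spec.endo_radius) / (spec.epi_radius - spec.endo_radius)

    aar = myo & spec.aar_sector.contains(angles)

    def region_mask(region: RegionSpec) -> np.ndarray:
        sector = _sub_sector(spec.aar_sector, region.sector_fraction)
        lo, hi = region.radial_range
        return aar & sector.contains(angles) & (wall >= lo) & (wall <= hi)

    infarct = region_mask(spec.infarct_region) if spec.infarct_region is not None else np.zeros_like(myo)
    mvo = region_mask(spec.mvo_core) if spec.mvo_core is not None else np.zeros_like(myo)
    imh = region_mask(spec.imh_core) if spec.imh_core is not None else np.zeros_like(myo)

    if np.any(mvo & ~infarct):
        raise ValueError("MVO core must lie inside the infarct region")
    truth_lge = infarct | mvo

    t1 = np.full(spec.grid_size, spec.remote_t1, dtype=float)
    t1[aar] += spec.aar_delta_t1
    if spec.mvo_core is not None:
        t1[mvo] += spec.mvo_core.t1_offset

    t2star = np.full(spec.grid_size, spec.remote_t2star, dtype=float)
    if spec.imh_core is not None:
        t2star[imh] = spec.imh_core.t2star_core

    lge = np.full(spec.grid_size, spec.lge_si_remote, dtype=float)
    lge[infarct] = spec.lge_si_infarct
    if spec.mvo_core is not None:
        lge[mvo] = spec.mvo_core.lge_si_low

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd.t1 > 0:
        t1 = t1 + rng.normal(0.0, spec.noise_sd.t1, spec.grid_size)
    if spec.noise_sd.t2star > 0:
        t2star = t2star + rng.normal(0.0, spec.noise_sd.t2star, spec.grid_size)
    if spec.noise_sd.lge_si > 0:
        lge = lge + rng.normal(0.0, spec.noise_sd.lge_si, spec.grid_size)

    def pmap(values: np.ndarray, kind: MapKind) -> ParametricMap:
        return ParametricMap(
            values=values,
            pixel_spacing=spec.pixel_spacing,
            slice_thickness=spec.slice_thickness,
            kind=kind,
            slice_index=spec.slice_index,
        )

    phantom = Phantom(
        t1=pmap(t1, MapKind.T1),
        t2star=pmap(t2star, MapKind.T2STAR),
        lge_si=pmap(lge, MapKind.LGE_SI),
        myocardium=MyoMask(myo, MaskRole.MYOCARDIUM),
        truth_aar=MyoMask(aar, MaskRole.AAR),
        truth_lge=MyoMask(truth_lge, MaskRole.LGE),
        truth_mvo=MyoMask(mvo, MaskRole.MVO),
        truth_imh=MyoMask(imh, MaskRole.IMH),
        spec=spec,
    )
    assert_lesion_invariants(
        phantom.myocardium,
        aar=phantom.truth_aar,
        lge=phantom.truth_lge,
        mvo=phantom.truth_mvo,
        imh=phantom.truth_imh,
    )
    return phantom
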