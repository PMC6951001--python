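"""NIfTI / CSV / YAML readers and writers and the pipeline driver.

Maps and masks travel as NIfTI-1 (one 3-D stack per map kind, slice axis
last; masks as uint8 {0,1}); pixel spacing and slice thickness live in the
header zooms, the map kind in a JSON sidecar next to the file. Cohort
tables are plain CSV. ``run_pipeline`` chains simulation, segmentation,
quantification and statistics from a single config mapping and emits a
deterministic JSON-able report stamped with the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import MapKind, MaskRole, MyoMask, ParametricMap
from .cohort import CohortSimSpec, generate_cohort
from .phantom import (
    AngularSector,
    ImhCoreSpec,
    MvoCoreSpec,
    NoiseSpec,
    Phantom,
    PhantomSpec,
    RegionSpec,
    generate_phantom,
)
from .quantify import (
    classify_large_infarct,
    classify_t1_group,
    extent_pct_lv,
    imh_extent_mm2,
    mean_t1_of_aar,
)
from .segmentation import SegmentationResult, segment_study
from .stats import CohortAnalysis

log = logging.getLogger(__name__)

__all__ = [
    "read_map",
    "write_map",
    "read_mask",
    "write_mask",
    "read_cohort",
    "write_cohort",
    "load_config",
    "config_hash",
    "phantom_spec_from_dict",
    "run_pipeline",
]


def _affine(spacing: tuple[float, float], thickness: float) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], thickness, 1.0])


def write_map(maps: ParametricMap | Sequence[ParametricMap], path) -> Path:
    """Write one map or a slice stack to NIfTI-1 plus a JSON sidecar."""
    path = Path(path)
    stack = [maps] if isinstance(maps, ParametricMap) else sorted(maps, key=lambda m: m.slice_index)
    kinds = {m.kind for m in stack}
    if len(kinds) != 1:
        raise ValueError("all slices in a stack must share a map kind")
    data = np.stack([m.values for m in stack], axis=-1)
    img = nib.Nifti1Image(data, _affine(stack[0].pixel_spacing, stack[0].slice_thickness))
    img.header.set_zooms((*stack[0].pixel_spacing, stack[0].slice_thickness))
    nib.save(img, path)
    sidecar = {"kind": stack[0].kind.value, "slice_thickness_mm": stack[0].slice_thickness}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json")


def read_map(path, kind: MapKind | str | None = None) -> list[ParametricMap]:
    """Read a NIfTI map file into one :class:`ParametricMap` per slice.

    The kind comes from the JSON sidecar unless given explicitly; 2-D files
    yield a single slice, 3-D stacks one map per slice (axis last).
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    if len(zooms) < 2 or zooms[0] <= 0 or zooms[1] <= 0:
        raise ValueError(f"{path}: missing or invalid pixel spacing")
    spacing = (float(zooms[0]), float(zooms[1]))
    thickness = float(zooms[2]) if len(zooms) > 2 and zooms[2] > 0 else 1.0

    if kind is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"{path}: map kind unknown (no sidecar, no explicit kind)")
        meta = json.loads(sidecar.read_text())
        kind = meta["kind"]
        thickness = float(meta.get("slice_thickness_mm", thickness))
    kind = MapKind(kind)

    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D map or 3-D stack")
    return [
        ParametricMap(data[..., i], spacing, thickness, kind, slice_index=i)
        for i in range(data.shape[-1])
    ]


def write_mask(mask: MyoMask | Sequence[MyoMask], path, pixel_spacing=(1.0, 1.0), slice_thickness=1.0) -> Path:
    path = Path(path)
    stack = [mask] if isinstance(mask, MyoMask) else list(mask)
    data = np.stack([m.grid.astype(np.uint8) for m in stack], axis=-1)
    img = nib.Nifti1Image(data, _affine(pixel_spacing, slice_thickness))
    img.header.set_zooms((*pixel_spacing, slice_thickness))
    nib.save(img, path)
    return path


def read_mask(path, role: MaskRole | str) -> list[MyoMask]:
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 2:
        data = data[..., None]
    return [MyoMask(data[..., i] > 0, MaskRole(role)) for i in range(data.shape[-1])]


def write_cohort(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# config -> spec adapters
# ---------------------------------------------------------------------------

def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    if "aar_sector" in d:
        d["aar_sector"] = AngularSector(**d["aar_sector"])
    if "infarct_region" in d and d["infarct_region"] is not None:
        d["infarct_region"] = RegionSpec(**d["infarct_region"])
    if d.get("mvo_core") is not None:
        d["mvo_core"] = MvoCoreSpec(**d["mvo_core"])
    if d.get("imh_core") is not None:
        d["imh_core"] = ImhCoreSpec(**d["imh_core"])
    if "noise_sd" in d:
        d["noise_sd"] = NoiseSpec(**d["noise_sd"])
    for key in ("grid_size", "pixel_spacing", "center"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)


def cohort_spec_from_dict(d: dict) -> CohortSimSpec:
    allowed = {"n_low", "n_high", "seed"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unsupported cohort spec keys: {sorted(unknown)}")
    return CohortSimSpec(**d)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _quantify_slice(phantom: Phantom, seg: SegmentationResult) -> dict:
    spacing = phantom.t1.pixel_spacing
    aar_pct = extent_pct_lv(seg.aar, phantom.myocardium, spacing)
    mean_t1 = mean_t1_of_aar(phantom.t1, seg.aar) if seg.aar.grid.any() else None
    metrics = {
        "aar_pct_lv": aar_pct,
        "aar_mean_t1_ms": mean_t1,
        "lge_pct_lv": extent_pct_lv(seg.lge, phantom.myocardium, spacing),
        "mvo_pct_lv": extent_pct_lv(seg.mvo, phantom.myocardium, spacing),
        "mvo_present": bool(seg.mvo.grid.any()),
        "imh_area_mm2": imh_extent_mm2(seg.imh, spacing),
        "imh_present": bool(seg.imh.grid.any()),
        "imh_core_mean_t2star_ms": seg.imh_core_mean_t2star,
    }
    if mean_t1 is not None:
        metrics["t1_group"] = classify_t1_group(mean_t1)
    return metrics


def run_pipeline(config: dict) -> dict:
    """Run simulate -> segment -> quantify -> analyze per the config mapping.

    Recognised top-level keys: ``seed``, ``phantom`` (phantom spec mapping,
    optional ``injured_center``/``roi_width``/segmentation flags under
    ``segmentation``), ``cohort`` (cohort sim spec) and ``stats`` (keys
    passed to :class:`~t1quant.stats.CohortAnalysis`). Every stage's
    thresholds and provenance are embedded in the returned report, which is
    deterministic for a fixed config.
    """
    report: dict = {
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
        "stages": {},
    }
    seed = config.get("seed", 0)

    if "phantom" in config:
        block = dict(config["phantom"])
        seg_flags = block.pop("segmentation", {})
        injured = block.pop("injured_center", None)
        roi_width = block.pop("roi_width", 60.0)
        block.setdefault("seed", seed)
        spec = phantom_spec_from_dict(block)
        phantom = generate_phantom(spec)
        if injured is None:
            injured = spec.aar_sector.center_angle
        seg = segment_study(
            phantom.t1, phantom.t2star, phantom.lge_si, phantom.myocardium,
            injured_center=injured, roi_width=roi_width, **seg_flags,
        )
        log.info(
            "segmented phantom: AAR thr %.1f ms, LGE thr %.1f, %d AAR px",
            seg.aar_threshold_ms, seg.lge_threshold_si, seg.aar.n_pixels,
        )
        report["stages"]["phantom"] = {
            "seed": spec.seed,
            "segmentation": seg.provenance
            | {
                "aar_threshold_ms": seg.aar_threshold_ms,
                "lge_threshold_si": seg.lge_threshold_si,
            },
            "metrics": _quantify_slice(phantom, seg),
        }

    cohort_df = None
    if "cohort" in config:
        block = dict(config["cohort"])
        block.setdefault("seed", seed)
        cohort_df = generate_cohort(cohort_spec_from_dict(block))
        report["stages"]["cohort"] = {
            "n": len(cohort_df),
            "n_low": int((cohort_df["t1_group"] == "LOW").sum()),
            "n_high": int((cohort_df["t1_group"] == "HIGH").sum()),
            "seed": block["seed"],
        }

    if "stats" in config:
        if cohort_df is None:
            raise ValueError("stats stage requires a cohort stage (or an input table)")
        stats_kwargs = dict(config["stats"] or {})
        results = CohortAnalysis(cohort_df, **stats_kwargs).fit()
        report["stages"]["stats"] = results.to_dict()

    return report
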