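"""Simulated per-subject cohort tables with known generating parameters.

``generate_cohort`` draws one row per subject with the imaging metrics and
clinical covariates of the study cohort, stratified by the 1400 ms mean-T1
severity group. Variables are drawn independently within a group (no
published correlation structure exists); an optional Gaussian-copula hook
can impose rank correlation between chosen continuous columns but is off
by default.

Hard row-level constraints are enforced by bounded resampling rather than
post-hoc editing wherever the constraint is distributional (MVO extent may
not exceed the LGE extent; mean T1 must fall on its group's side of
1400 ms); percentage columns are clipped to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import study_params as sp
from .distributions import ZeroInflatedLogNormal, fit_zi_lognormal

__all__ = ["CohortSimSpec", "generate_cohort", "cohort_to_long"]

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class CohortSimSpec:
    """Configuration of the cohort simulator.

    ``n_low``/``n_high`` are the group sizes (defaults: the hyper-acute
    cohort, 24 vs 15). ``variables`` maps column names to per-group
    distributions; by default the published table parameters are used.
    ``copula_corr`` optionally lists ``(col_a, col_b, rho)`` rank
    correlations imposed via a Gaussian copula within each group.
    """

    n_low: int = 24
    n_high: int = 15
    seed: int = 0
    variables: Mapping[str, sp.GroupRow] = field(
        default_factory=lambda: {**sp.COVARIATES, **sp.METRICS}
    )
    linked_incidence: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(sp.LINKED_INCIDENCE)
    )
    copula_corr: Sequence[tuple[str, str, float]] = ()

    def __post_init__(self) -> None:
        if self.n_low < 0 or self.n_high < 0 or self.n_low + self.n_high == 0:
            raise ValueError("group sizes must be non-negative and not both zero")


def _ziln_for(name: str, dist: sp.MedianIqr, p_zero: float) -> ZeroInflatedLogNormal:
    if p_zero > 0 or dist.q1 <= 0 or dist.median <= 0:
        return ZeroInflatedLogNormal.from_overall_quantiles(
            p_zero, dist.median, dist.q1, dist.q3
        )
    return fit_zi_lognormal(p_zero, dist.median, dist.q1, dist.q3)


def _draw(name: str, dist, n: int, rng: np.random.Generator, p_zero: float) -> np.ndarray:
    if isinstance(dist, sp.Normal):
        return rng.normal(dist.mean, dist.sd, n)
    if isinstance(dist, sp.TruncNormal):
        x = rng.normal(dist.mean, dist.sd, n)
        for _ in range(_MAX_RESAMPLE):
            bad = (x < dist.lo) | (x >= dist.hi)
            if not bad.any():
                return x
            x[bad] = rng.normal(dist.mean, dist.sd, int(bad.sum()))
        raise RuntimeError(f"resampling budget exhausted for {name}")
    if isinstance(dist, sp.Rate):
        return (rng.random(n) < dist.p).astype(bool)
    if isinstance(dist, sp.MedianIqr):
        return _ziln_for(name, dist, p_zero).rvs(n, rng)
    raise TypeError(f"unsupported distribution for {name}: {dist!r}")


def _apply_copula(
    df: pd.DataFrame, pairs: Sequence[tuple[str, str, float]], rng: np.random.Generator
) -> None:
    # Reorders column b within the group so that (a, b) attain the Gaussian
    # copula's rank correlation; marginals are untouched.
    from scipy import stats

    for col_a, col_b, rho in pairs:
        n = len(df)
        z_a = stats.rankdata(df[col_a]) / (n + 1)
        z = stats.norm.ppf(z_a)
        z_b = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        order = np.argsort(np.argsort(z_b))
        df[col_b] = np.sort(df[col_b].to_numpy())[order]


def generate_cohort(spec: CohortSimSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate a cohort table; one row per subject (wide format).

    Returns a DataFrame with ``subject_id``, ``t1_group`` ("LOW"/"HIGH"),
    every configured metric and covariate, plus the derived ``mvo_present``,
    ``imh_present``, ``mean_bp_mmhg`` and ``large_infarct`` columns. The
    generating parameters are stored in ``df.attrs["ground_truth"]``.
    """
    if spec is None:
        spec = CohortSimSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    frames = []
    for group, n in (("LOW", spec.n_low), ("HIGH", spec.n_high)):
        if n == 0:
            continue
        cols: dict[str, np.ndarray] = {}
        for name, row in spec.variables.items():
            dist = row.low if group == "LOW" else row.high
            p_zero = 0.0
            if name in spec.linked_incidence:
                inc = spec.linked_incidence[name][0 if group == "LOW" else 1]
                p_zero = 1.0 - inc
            cols[name] = _draw(name, dist, n, rng, p_zero)
        df = pd.DataFrame(cols)
        df.insert(0, "t1_group", group)

        # clip percentages first so the extent constraint below is feasible
        for col in sp.PERCENT_COLUMNS:
            if col in df:
                df[col] = df[col].clip(0.0, 100.0)

        # constraint: MVO extent cannot exceed the LGE extent (both %LV)
        if "mvo_pct_lv" in df and "lge_pct_24h" in df:
            row = spec.variables["mvo_pct_lv"]
            dist = row.low if group == "LOW" else row.high
            p_zero = 1.0 - spec.linked_incidence["mvo_pct_lv"][0 if group == "LOW" else 1]
            for _ in range(_MAX_RESAMPLE):
                bad = df["mvo_pct_lv"].to_numpy() > df["lge_pct_24h"].to_numpy()
                if not bad.any():
                    break
                fresh = np.clip(_draw("mvo_pct_lv", dist, int(bad.sum()), rng, p_zero), 0.0, 100.0)
                df.loc[bad, "mvo_pct_lv"] = fresh
            else:
                raise RuntimeError("could not satisfy mvo_pct_lv <= lge_pct_24h")

        if spec.copula_corr:
            _apply_copula(df, spec.copula_corr, rng)
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i + 1:03d}" for i in range(len(out))])
    if "mvo_pct_lv" in out:
        out["mvo_present"] = out["mvo_pct_lv"] > 0
    if "imh_area_mm2" in out:
        out["imh_present"] = out["imh_area_mm2"] > 0
    if {"systolic_bp_mmhg", "diastolic_bp_mmhg"} <= set(out.columns):
        out["mean_bp_mmhg"] = (
            out["diastolic_bp_mmhg"]
            + (out["systolic_bp_mmhg"] - out["diastolic_bp_mmhg"]) / 3.0
        )
    if "final_infarct_pct" in out:
        out["large_infarct"] = out["final_infarct_pct"] > sp.LARGE_INFARCT_CUTOFF_PCT

    out.attrs["ground_truth"] = {
        "n_low": spec.n_low,
        "n_high": spec.n_high,
        "seed": spec.seed if seed is None else seed,
        "variables": {
            name: {"low": repr(row.low), "high": repr(row.high)}
            for name, row in spec.variables.items()
        },
        "linked_incidence": dict(spec.linked_incidence),
    }
    return out


_TIMEPOINT_SUFFIX = {"_24h": "ACUTE_24H", "_6m": "FOLLOWUP_6M"}


def cohort_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Reshape a wide cohort table to one row per (subject, timepoint)."""
    records = []
    metric_cols = [c for c in df.columns if any(c.endswith(s) for s in _TIMEPOINT_SUFFIX)]
    hyper_cols = ["aar_mean_t1_ms", "aar_pct_lv"]
    fu_extra = ["msi_pct", "final_infarct_pct", "large_infarct"]
    for _, row in df.iterrows():
        base = {"subject_id": row["subject_id"], "t1_group": row["t1_group"]}
        rec = dict(base, timepoint="HYPERACUTE")
        for c in hyper_cols:
            if c in df.columns:
                rec[c] = row[c]
        records.append(rec)
        for suffix, tp in _TIMEPOINT_SUFFIX.items():
            rec = dict(base, timepoint=tp)
            for c in metric_cols:
                if c.endswith(suffix):
                    rec[c.removesuffix(suffix)] = row[c]
            if tp == "ACUTE_24H":
                for c in ("mvo_pct_lv", "mvo_present", "imh_area_mm2", "imh_present"):
                    if c in df.columns:
                        rec[c] = row[c]
            if tp == "FOLLOWUP_6M":
                for c in fu_extra:
                    if c in df.columns:
                        rec[c] = row[c]
            records.append(rec)
    return pd.DataFrame.from_records(records)
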