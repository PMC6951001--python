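"""Cohort statistics: test routing, screening, regression and ROC analysis.

The layer reproduces a conventional clinical-imaging analysis plan:

* group comparisons routed by a per-group Shapiro-Wilk normality test at
  alpha = 0.05 (both normal -> two-sample t-test, else Mann-Whitney U);
  categorical variables use chi-squared unless an expected cell is below 5,
  then Fisher's exact test;
* a univariate screen (simple linear regression, p < 0.05) selects the
  covariates entered into the multivariate model;
* ordinary least squares of an outcome on the mean T1 of the area-at-risk
  scaled to a per-10-ms effect, adjusted for the screened covariates, with
  variance-inflation-factor collinearity flags;
* ROC analysis with the rank (Mann-Whitney) AUC, a normal-approximation
  p-value against AUC = 0.5, and the Youden-optimal threshold under the
  ``score >= threshold`` positivity rule.

No multiple-testing correction is applied anywhere in this layer.
The unequal-variance (Welch) t-test is the default; ``pooled=True``
restores the classic pooled-variance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "RocResult",
    "route_and_compare",
    "univariate_screen",
    "multivariate_t1_model",
    "roc_analysis",
    "diagnostic_metrics",
    "CohortAnalysis",
    "CohortAnalysisResults",
]

ALPHA = 0.05

#: covariates screened for entry into the multivariate models
DEFAULT_CANDIDATES = [
    "age_yr",
    "male",
    "diabetes",
    "hypertension",
    "mean_bp_mmhg",
    "anterior_infarct",
    "stent_length_mm",
    "stent_diameter_mm",
    "gp2b3a",
    "timi3",
    "mbg23",
    "thrombus_large",
    "st_resolution",
    "ischaemia_time_min",
    "door_to_balloon_min",
    "troponin",
]


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_used: str  # T_TEST | MANN_WHITNEY | CHI_SQ | FISHER
    group_summaries: dict
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _split_two_groups(values, labels):
    values = np.asarray(values)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    parts = [values[labels == g] for g in groups]
    if any(len(p) == 0 for p in parts):
        raise ValueError("a group is empty")
    return groups, parts


def _is_normal(sample: np.ndarray) -> bool:
    if len(sample) < 3 or np.ptp(sample) == 0:
        return False  # Shapiro-Wilk undefined; route non-parametrically
    return sps.shapiro(sample).pvalue > ALPHA


def _summary_mean_sd(x):
    return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0, "n": len(x)}


def _summary_median_iqr(x):
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": len(x)}


def route_and_compare(
    values,
    group_labels,
    variable_kind: str = "continuous",
    *,
    variable: str = "",
    pooled: bool = False,
) -> GroupComparison:
    """Compare a variable between two groups with routed test selection.

    ``variable_kind`` is ``"continuous"`` or ``"categorical"``. Continuous
    routing: Shapiro-Wilk per group at alpha 0.05; both non-rejected ->
    two-sample t-test (Welch by default), otherwise Mann-Whitney U.
    Categorical: chi-squared on the contingency table unless any expected
    cell count is below 5, then Fisher's exact test. Two identical constant
    samples compare equal with p = 1 by convention.
    """
    groups, (a, b) = _split_two_groups(values, group_labels)

    if variable_kind == "continuous":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("continuous comparison needs >= 2 observations per group")
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            summaries = {str(groups[0]): _summary_median_iqr(a), str(groups[1]): _summary_median_iqr(b)}
            return GroupComparison(variable, "MANN_WHITNEY", summaries, 0.0, 1.0)
        if _is_normal(a) and _is_normal(b):
            res = sps.ttest_ind(a, b, equal_var=pooled)
            summaries = {str(groups[0]): _summary_mean_sd(a), str(groups[1]): _summary_mean_sd(b)}
            return GroupComparison(variable, "T_TEST", summaries, float(res.statistic), float(res.pvalue))
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        summaries = {str(groups[0]): _summary_median_iqr(a), str(groups[1]): _summary_median_iqr(b)}
        return GroupComparison(variable, "MANN_WHITNEY", summaries, float(res.statistic), float(res.pvalue))

    if variable_kind == "categorical":
        table = pd.crosstab(pd.Series(np.asarray(values)), pd.Series(np.asarray(group_labels))).to_numpy()
        if table.shape[0] < 2:
            # variable constant: no association by convention
            return GroupComparison(variable, "CHI_SQ", {"table": table.tolist()}, 0.0, 1.0)
        chi2 = sps.chi2_contingency(table)
        summaries = {"table": table.tolist()}
        if np.any(chi2.expected_freq < 5):
            if table.shape != (2, 2):
                raise ValueError("Fisher routing implemented for 2x2 tables only")
            res = sps.fisher_exact(table)
            return GroupComparison(variable, "FISHER", summaries, float(res.statistic), float(res.pvalue))
        return GroupComparison(variable, "CHI_SQ", summaries, float(chi2.statistic), float(chi2.pvalue))

    raise ValueError(f"unknown variable_kind {variable_kind!r}")


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    predictor: str
    scale: str          # e.g. "per 10 ms"
    beta: float
    ci95: tuple[float, float]
    p_value: float
    adjusted_for: tuple[str, ...]
    vif: dict = field(default_factory=dict)
    collinearity_flags: tuple[str, ...] = ()
    n: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.beta <= hi:
            raise ValueError("beta outside its own confidence interval")


def univariate_screen(
    cohort: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str] | None = None,
    alpha: float = ALPHA,
) -> list[str]:
    """Simple linear regression of the outcome on each candidate; keep p < alpha.

    Constant candidates are excluded with a warning. Boolean covariates are
    coded 0/1.
    """
    if candidates is None:
        candidates = [c for c in DEFAULT_CANDIDATES if c in cohort.columns]
    selected = []
    y = cohort[outcome].astype(float).to_numpy()
    for name in candidates:
        x = cohort[name].astype(float).to_numpy()
        if np.ptp(x) == 0:
            warnings.warn(f"candidate {name!r} is constant; excluded from the screen",
                          stacklevel=2)
            continue
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        if fit.pvalues[1] < alpha:
            selected.append(name)
    return selected


def _design_matrix(cohort: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    X = cohort[list(columns)].astype(float)
    return sm.add_constant(X)


def multivariate_t1_model(
    cohort: pd.DataFrame,
    outcome: str,
    selected: Sequence[str] = (),
    *,
    t1_column: str = "aar_mean_t1_ms",
    include_aar: bool = False,
    scale_ms: float = 10.0,
    vif_flag: float = 5.0,
) -> RegressionResult:
    """OLS of ``outcome`` on mean T1 (per ``scale_ms`` ms) plus covariates.

    The T1 predictor is divided by ``scale_ms`` so the reported beta is the
    change in outcome per 10 ms of T1. ``include_aar`` additionally adjusts
    for the extent of injury (``aar_pct_lv``). A singular design raises a
    ``ValueError`` naming the collinear columns; variance inflation factors
    above ``vif_flag`` are reported as flags.
    """
    predictors = list(dict.fromkeys(selected))
    if include_aar and "aar_pct_lv" not in predictors:
        predictors.append("aar_pct_lv")

    work = cohort.copy()
    t1_scaled = f"{t1_column}_per{int(scale_ms)}ms"
    work[t1_scaled] = work[t1_column].astype(float) / scale_ms
    columns = [t1_scaled] + predictors
    if len(work) <= len(columns) + 2:
        raise ValueError("too few rows for the requested model")

    X = _design_matrix(work, columns)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns via tiny R diagonal in a pivoted QR
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"singular design matrix; collinear columns: {bad or list(X.columns)}")

    y = work[outcome].astype(float)
    fit = sm.OLS(y, X).fit()

    vif = {}
    flags = []
    if X.shape[1] > 2:
        arr = X.to_numpy()
        for i, col in enumerate(X.columns):
            if col == "const":
                continue
            v = float(variance_inflation_factor(arr, i))
            vif[col] = v
            if v > vif_flag:
                flags.append(col)

    lo, hi = fit.conf_int().loc[t1_scaled]
    return RegressionResult(
        outcome=outcome,
        predictor=t1_column,
        scale=f"per {scale_ms:g} ms",
        beta=float(fit.params[t1_scaled]),
        ci95=(float(lo), float(hi)),
        p_value=float(fit.pvalues[t1_scaled]),
        adjusted_for=tuple(predictors),
        vif=vif,
        collinearity_flags=tuple(flags),
        n=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_p: float
    optimal_threshold: float
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    n_pos: int
    n_neg: int
    thresholds: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    fpr: np.ndarray = field(repr=False, default=None)

    def plot(self, ax=None):
        """ROC curve with the chosen operating point marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = np.argsort(self.fpr)
        ax.plot(np.r_[0, self.fpr[order], 1], np.r_[0, self.tpr[order], 1], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.plot(1 - self.specificity, self.sensitivity, "o", color="C3")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"AUC = {self.auc:.2f} (p = {self.auc_p:.3g})")
        return ax


def diagnostic_metrics(scores, labels, threshold: float) -> dict:
    """Sensitivity/specificity/PPV/NPV at ``score >= threshold`` positive.

    Ratios with a zero denominator are reported as ``None`` (absent), never
    as 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))

    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def roc_analysis(scores, labels) -> RocResult:
    """Rank-based AUC, its normal-approximation p-value, Youden threshold.

    The AUC is the tie-corrected Mann-Whitney probability that a positive
    outranks a negative; its p-value tests AUC = 0.5 through the normal
    approximation to the U statistic with the tie-adjusted variance. The
    operating threshold maximises Youden's J = sensitivity + specificity - 1
    over the observed scores (ties resolved toward the lowest threshold),
    with ``score >= threshold`` counted positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    ranks = sps.rankdata(scores)
    u = float(ranks[labels].sum()) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    n = n_pos + n_neg
    _, counts = np.unique(scores, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n_pos * n_neg / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        auc_p = 1.0
    else:
        z = (u - n_pos * n_neg / 2.0) / np.sqrt(var_u)
        auc_p = float(2.0 * sps.norm.sf(abs(z)))

    candidates = np.unique(scores)  # ascending
    best_j, best_thr, best_metrics = -np.inf, candidates[0], None
    for thr in candidates:
        m = diagnostic_metrics(scores, labels, thr)
        j = (m["sensitivity"] or 0.0) + (m["specificity"] or 0.0) - 1.0
        if j > best_j:  # strict: ties keep the lowest threshold
            best_j, best_thr, best_metrics = j, float(thr), m

    curve = [diagnostic_metrics(scores, labels, t) for t in candidates]
    tpr = np.array([c["sensitivity"] for c in curve], dtype=float)
    fpr = np.array([1.0 - c["specificity"] for c in curve], dtype=float)

    return RocResult(
        auc=float(auc),
        auc_p=auc_p,
        optimal_threshold=best_thr,
        sensitivity=best_metrics["sensitivity"],
        specificity=best_metrics["specificity"],
        ppv=best_metrics["ppv"],
        npv=best_metrics["npv"],
        n_pos=n_pos,
        n_neg=n_neg,
        thresholds=candidates,
        tpr=tpr,
        fpr=fpr,
    )


# ---------------------------------------------------------------------------
# model-style front end
# ---------------------------------------------------------------------------

class CohortAnalysis:
    """Cohort-level analysis of T1 severity against an imaging outcome.

    A statsmodels-style front end: construct from a cohort table, call
    :meth:`fit`, read the results object. ``fit`` runs (1) group
    comparisons of every requested variable between the T1 severity groups,
    (2) the univariate covariate screen for the outcome, (3) the
    multivariate per-10-ms T1 model and (4) ROC analysis of mean T1 against
    the large-infarct endpoint when present.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        outcome: str = "final_infarct_pct",
        *,
        group_column: str = "t1_group",
        t1_column: str = "aar_mean_t1_ms",
        compare: Sequence[str] | None = None,
        candidates: Sequence[str] | None = None,
        include_aar: bool = True,
        pooled_t: bool = False,
    ) -> None:
        self.cohort = cohort
        self.outcome = outcome
        self.group_column = group_column
        self.t1_column = t1_column
        self.compare = compare
        self.candidates = candidates
        self.include_aar = include_aar
        self.pooled_t = pooled_t

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CohortAnalysis":
        return cls(pd.read_csv(path), **kwargs)

    def _comparison_variables(self) -> list[tuple[str, str]]:
        if self.compare is not None:
            out = []
            for name in self.compare:
                kind = "categorical" if self.cohort[name].dtype == bool else "continuous"
                out.append((name, kind))
            return out
        out = []
        skip = {self.group_column, "subject_id"}
        for name, dtype in self.cohort.dtypes.items():
            if name in skip:
                continue
            if dtype == bool:
                out.append((name, "categorical"))
            elif np.issubdtype(dtype, np.number):
                out.append((name, "continuous"))
        return out

    def fit(self) -> "CohortAnalysisResults":
        df = self.cohort
        labels = df[self.group_column].to_numpy()

        comparisons = {}
        for name, kind in self._comparison_variables():
            try:
                comparisons[name] = route_and_compare(
                    df[name].to_numpy(), labels, kind, variable=name, pooled=self.pooled_t
                )
            except ValueError:
                continue  # e.g. a group too small for this variable

        selected = univariate_screen(df, self.outcome, self.candidates)
        regression = multivariate_t1_model(
            df, self.outcome, selected,
            t1_column=self.t1_column, include_aar=self.include_aar,
        )

        roc = None
        if "large_infarct" in df.columns:
            lab = df["large_infarct"].astype(bool).to_numpy()
            if 0 < lab.sum() < len(lab):
                roc = roc_analysis(df[self.t1_column].to_numpy(), lab)

        return CohortAnalysisResults(
            model=self, comparisons=comparisons, selected=selected,
            regression=regression, roc=roc,
        )


@dataclass(frozen=True)
class CohortAnalysisResults:
    model: CohortAnalysis
    comparisons: dict
    selected: list
    regression: RegressionResult
    roc: Optional[RocResult]

    def comparison_table(self) -> pd.DataFrame:
        rows = []
        for name, c in self.comparisons.items():
            rows.append({"variable": name, "test": c.test_used,
                         "statistic": c.statistic, "p_value": c.p_value})
        return pd.DataFrame(rows).set_index("variable")

    def summary(self) -> str:
        reg = self.regression
        lines = [
            "Cohort analysis of hyper-acute T1 severity",
            "=" * 58,
            f"outcome: {reg.outcome}   n = {reg.n}",
            "",
            "Group comparisons (t1_group LOW vs HIGH)",
            self.comparison_table().to_string(float_format=lambda v: f"{v:.4g}"),
            "",
            f"univariate screen (p < {ALPHA}): {list(self.selected) or 'none'}",
            (
                f"mean T1 {reg.scale}: beta = {reg.beta:.3f} "
                f"(95% CI {reg.ci95[0]:.3f} to {reg.ci95[1]:.3f}), p = {reg.p_value:.4g}"
            ),
            f"adjusted for: {list(reg.adjusted_for) or 'none'}",
        ]
        if reg.collinearity_flags:
            lines.append(f"VIF > 5: {list(reg.collinearity_flags)}")
        if self.roc is not None:
            r = self.roc
            ppv = "absent" if r.ppv is None else f"{r.ppv:.2f}"
            npv = "absent" if r.npv is None else f"{r.npv:.2f}"
            lines += [
                "",
                "ROC: mean T1 vs large final infarct",
                (
                    f"AUC = {r.auc:.2f} (p = {r.auc_p:.4g}); optimal threshold "
                    f"{r.optimal_threshold:.0f} ms; sens {r.sensitivity:.2f}, "
                    f"spec {r.specificity:.2f}, PPV {ppv}, NPV {npv}"
                ),
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable report."""
        out = {
            "outcome": self.regression.outcome,
            "selected_covariates": list(self.selected),
            "regression": {
                "beta_per_10ms": self.regression.beta,
                "ci95": list(self.regression.ci95),
                "p_value": self.regression.p_value,
                "adjusted_for": list(self.regression.adjusted_for),
                "vif": self.regression.vif,
                "collinearity_flags": list(self.regression.collinearity_flags),
                "n": self.regression.n,
            },
            "comparisons": {
                name: {
                    "test": c.test_used,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "summaries": c.group_summaries,
                }
                for name, c in self.comparisons.items()
            },
        }
        if self.roc is not None:
            r = self.roc
            out["roc"] = {
                "auc": r.auc, "auc_p": r.auc_p,
                "optimal_threshold": r.optimal_threshold,
                "sensitivity": r.sensitivity, "specificity": r.specificity,
                "ppv": r.ppv, "npv": r.npv, "n_pos": r.n_pos, "n_neg": r.n_neg,
            }
        return out
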