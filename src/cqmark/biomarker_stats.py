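"""Differential expression, age-adjusted ROC, stratified tests and the
hemolysis-threshold sweep.

Group comparisons use two-sample t-tests on dCq (Welch by default, a
pooled-variance variant by flag) with the signed fold-change
convention common in qPCR tables: an abundance log2 difference Delta
maps to ``2**Delta`` when cases are up and ``-2**(-Delta)`` when down,
so |fold change| >= 1 always and e.g. an abundance ratio of 0.58 is
printed as -1.73.  Benjamini-Hochberg q-values are reported alongside
raw p-values but significance is gated on raw p < alpha (single-panel
candidate testing, not genome-wide discovery).

Diagnostic performance is scored with a logistic model
``group ~ expression + age`` (age is a confounder whenever the groups
differ in age); AUC is the rank-based (Mann-Whitney) area of the
fitted probabilities and sensitivity/specificity are reported at the
Youden-optimal threshold, with the operating rule tagged in the
result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .normalization import ExpressionMatrix, SCHEME_PROFILING
from .quality_control import CorrelationResult, filter_by_hemolysis

__all__ = [
    "differential_expression",
    "signed_fold_change",
    "two_sample_ttest",
    "roc_with_age",
    "RocResult",
    "stratified_comparisons",
    "correlate",
    "hemolysis_sweep",
]

CASE = "endometriosis"
CONTROL = "control"


def signed_fold_change(delta_log2) -> np.ndarray | float:
    """Signed fold change from an abundance log2 difference.

    ``2**delta`` for delta >= 0, ``-2**(-delta)`` otherwise; exact
    ties map to +1.  Vectorized.
    """
    d = np.asarray(delta_log2, float)
    out = np.where(d >= 0, 2.0**d, -(2.0 ** (-d)))
    return out if out.ndim else float(out)


def two_sample_ttest(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch unless ``equal_var``).

    Degenerate inputs (zero spread in both groups) yield p = 1 when
    the means agree and p = 0 when they differ — the data are then not
    noisy, just categorical.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        return np.nan, np.nan
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):
        p = 1.0 if np.mean(x) == np.mean(y) else 0.0
        t = 0.0 if p == 1.0 else np.inf
    return t, p


def differential_expression(
    matrix: ExpressionMatrix,
    groups: pd.Series,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-assay case-vs-control test on dCq with signed fold changes.

    The abundance log2 difference honors the matrix's scheme: on the
    profiling convention (higher dCq = more abundant) it is case mean
    minus control mean; on the validation convention the sign flips.
    Assays with fewer than 2 detected values in either group get NaN
    statistics.  Returns one row per assay with p, BH q, fold change
    and group means, sorted by assay id for determinism.
    """
    values = matrix.values
    groups = pd.Series(groups).reindex(values.index)
    case = values.loc[groups == CASE]
    ctrl = values.loc[groups == CONTROL]

    n_case = case.notna().sum(axis=0)
    n_ctrl = ctrl.notna().sum(axis=0)
    ok = (n_case >= 2) & (n_ctrl >= 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            case.to_numpy(), ctrl.to_numpy(),
            equal_var=equal_var, nan_policy="omit", axis=0,
        )
        pvals = np.asarray(res.pvalue, float)

    mean_case = case.mean(axis=0).to_numpy()
    mean_ctrl = ctrl.mean(axis=0).to_numpy()
    diff = mean_case - mean_ctrl
    # zero-spread degenerate columns: equal means -> p 1, else p 0
    nanp = np.isnan(pvals) & ok.to_numpy()
    pvals[nanp] = np.where(diff[nanp] == 0, 1.0, 0.0)
    pvals[~ok.to_numpy()] = np.nan

    sign = 1.0 if matrix.scheme == SCHEME_PROFILING else -1.0
    delta = sign * diff  # abundance log2 difference, case vs control

    out = pd.DataFrame(
        {
            "assay_id": values.columns,
            "mean_control": mean_ctrl,
            "mean_case": mean_case,
            "n_control": n_ctrl.to_numpy(),
            "n_case": n_case.to_numpy(),
            "delta_log2": delta,
            "fold_change": signed_fold_change(delta),
            "p_value": pvals,
            "scheme": matrix.scheme,
        }
    )
    tested = out["p_value"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(
            out.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    out["q_value"] = q
    out["significant"] = out["p_value"] < alpha  # gate on raw p
    return out.sort_values("assay_id", kind="mergesort").reset_index(drop=True)


@dataclass
class RocResult:
    """Age-adjusted diagnostic summary for one marker."""

    assay_id: str
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    coefficients: dict
    operating_rule: str = "youden"
    separation_warning: bool = False
    n_control: int = 0
    n_case: int = 0


def roc_with_age(
    expression: pd.Series,
    age: pd.Series,
    groups: pd.Series,
    assay_id: str = "",
) -> RocResult:
    """Logistic ``group ~ expression + age`` score and its ROC summary.

    The score is the fitted case probability; AUC is its rank-based
    area (equivalent to the Mann-Whitney statistic, tie-corrected) and
    the reported sensitivity/specificity sit at the Youden-optimal
    probability threshold.  Perfect separation yields AUC 1.0 with the
    coefficients flagged as non-identified.
    """
    df = pd.DataFrame(
        {"expression": expression, "age": age, "group": pd.Series(groups)}
    ).dropna()
    y = (df["group"] == CASE).astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both groups must be nonempty")
    X = sm.add_constant(df[["expression", "age"]].to_numpy(float))

    separation = False
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = np.asarray(fit.params)
            if not fit.mle_retvals.get("converged", True):
                separation = True
        except (PerfectSeparationError, np.linalg.LinAlgError):
            # separated data: the MLE diverges; a weakly ridge-penalized
            # fit still yields a monotone (rank-preserving) score
            separation = True
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(C=1e6, max_iter=1000).fit(X[:, 1:], y)
            params = np.r_[lr.intercept_, lr.coef_.ravel()]
    score = 1.0 / (1.0 + np.exp(-(X @ params)))

    auc = float(roc_auc_score(y, score))
    fpr, tpr, thr = roc_curve(y, score)
    j = np.argmax(tpr - fpr)
    if auc == 1.0:
        separation = separation or True
    coeffs = {
        "intercept": float(params[0]),
        "expression": float(params[1]),
        "age": float(params[2]),
    }
    return RocResult(
        assay_id=assay_id,
        auc=auc,
        sensitivity=float(tpr[j]),
        specificity=float(1.0 - fpr[j]),
        threshold=float(thr[j]),
        coefficients=coeffs,
        separation_warning=bool(separation),
        n_control=int((y == 0).sum()),
        n_case=int((y == 1).sum()),
    )


def correlate(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value.

    Pairs with missing values are dropped; a constant vector or fewer
    than 3 pairs makes r undefined (NaN with reason) rather than
    raising.
    """
    x = pd.Series(np.asarray(x, float))
    y = pd.Series(np.asarray(y, float))
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(), y[ok].to_numpy()
    if len(x) < 3:
        return CorrelationResult(np.nan, np.nan, len(x), "fewer than 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, len(x), "constant vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x))


def stratified_comparisons(
    expression: pd.Series,
    samples: pd.DataFrame,
    min_stratum: int = 5,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Stage- and menstrual-phase-stratified tests for one marker.

    Runs control vs each ASRM stage and stage III vs IV (t-tests), a
    one-way ANOVA across menstrual phases within controls, and the
    proliferative-vs-secretory t-test.  Strata smaller than
    ``min_stratum`` are skipped with the reason recorded — small-stage
    comparisons are underpowered and misleading rather than merely
    imprecise.
    """
    df = samples.set_index("sample_id").join(expression.rename("value"))
    df = df.dropna(subset=["value"])
    rows = []

    def subset(mask):
        return df.loc[mask, "value"].to_numpy()

    ctrl = subset(df["group"] == CONTROL)
    stage_values = {
        s: subset((df["group"] == CASE) & (df["stage"] == s))
        for s in ["I", "II", "III", "IV"]
    }
    for s, vals in stage_values.items():
        if len(vals) < min_stratum:
            rows.append(
                dict(comparison=f"control_vs_stage_{s}", n1=len(ctrl), n2=len(vals),
                     p_value=np.nan, skipped=f"stage {s} has {len(vals)} samples "
                     f"(< {min_stratum})")
            )
            continue
        _, p = two_sample_ttest(ctrl, vals, equal_var=equal_var)
        rows.append(
            dict(comparison=f"control_vs_stage_{s}", n1=len(ctrl), n2=len(vals),
                 p_value=p, skipped=None)
        )
    v3, v4 = stage_values["III"], stage_values["IV"]
    if len(v3) >= min_stratum and len(v4) >= min_stratum:
        _, p = two_sample_ttest(v3, v4, equal_var=equal_var)
        rows.append(dict(comparison="stage_III_vs_IV", n1=len(v3), n2=len(v4),
                         p_value=p, skipped=None))
    else:
        rows.append(dict(comparison="stage_III_vs_IV", n1=len(v3), n2=len(v4),
                         p_value=np.nan, skipped="a stage stratum is too small"))

    # menstrual phase within controls
    phases = ["proliferative", "secretory", "unknown"]
    phase_values = {
        p_: subset((df["group"] == CONTROL) & (df["phase"] == p_)) for p_ in phases
    }
    present = {p_: v for p_, v in phase_values.items() if len(v) >= 2}
    if len(present) >= 2:
        _, p = stats.f_oneway(*present.values())
        rows.append(dict(comparison="phase_anova_controls",
                         n1=sum(len(v) for v in present.values()), n2=0,
                         p_value=float(p), skipped=None))
    else:
        rows.append(dict(comparison="phase_anova_controls", n1=0, n2=0,
                         p_value=np.nan, skipped="fewer than 2 phases with n >= 2"))
    pro, sec = phase_values["proliferative"], phase_values["secretory"]
    if len(pro) >= 2 and len(sec) >= 2:
        _, p = two_sample_ttest(pro, sec, equal_var=equal_var)
        rows.append(dict(comparison="proliferative_vs_secretory",
                         n1=len(pro), n2=len(sec), p_value=p, skipped=None))
    else:
        rows.append(dict(comparison="proliferative_vs_secretory",
                         n1=len(pro), n2=len(sec), p_value=np.nan,
                         skipped="a phase stratum is too small"))
    return pd.DataFrame(rows)


def hemolysis_sweep(
    expression: pd.Series,
    reports: pd.DataFrame,
    samples: pd.DataFrame,
    thresholds,
    assay_id: str = "",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Re-run the biomarker analysis under successive hemolysis filters.

    For each delta-Cq threshold t (descending; ``inf`` means no
    filter): retain samples with delta Cq <= t, then recompute the
    between-group t-test on the marker's dCq, the Pearson correlation
    of dCq with delta Cq, and the age-adjusted AUC.  A threshold
    leaving fewer than 2 samples in a group yields an undefined row.
    """
    thresholds = list(thresholds)
    if any(
        t1 < t2 for t1, t2 in zip(thresholds, thresholds[1:])
    ):
        raise ValueError("thresholds must be sorted descending")
    meta = samples.set_index("sample_id")
    delta = reports.set_index("sample_id")["delta_cq"]

    rows = []
    for t in thresholds:
        retained = filter_by_hemolysis(reports, threshold=t)
        sub = expression.reindex(retained).dropna()
        grp = meta.loc[sub.index, "group"]
        n_ctrl = int((grp == CONTROL).sum())
        n_case = int((grp == CASE).sum())
        if n_ctrl < 2 or n_case < 2:
            rows.append(dict(threshold=t, n_control=n_ctrl, n_case=n_case,
                             p_value=np.nan, r=np.nan, r_p=np.nan, auc=np.nan,
                             defined=False))
            continue
        _, p = two_sample_ttest(
            sub[grp == CASE], sub[grp == CONTROL], equal_var=equal_var
        )
        corr = correlate(sub.to_numpy(), delta.reindex(sub.index).to_numpy())
        roc = roc_with_age(
            sub, meta.loc[sub.index, "age"], grp, assay_id=assay_id
        )
        rows.append(dict(threshold=t, n_control=n_ctrl, n_case=n_case,
                         p_value=p, r=corr.r, r_p=corr.p, auc=roc.auc,
                         defined=True))
    return pd.DataFrame(rows)
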