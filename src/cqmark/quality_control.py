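"""Technical QC: hemolysis scoring and spike-in constancy checks.

Serum miRNA work is vulnerable to erythrocyte lysis: miR-451a is
highly erythrocyte-enriched so its Cq falls as hemolysis rises, while
miR-23a-3p is serum-stable.  The hemolysis score is therefore

    delta Cq = mean Cq(miR-23a-3p) - mean Cq(miR-451a)

with larger values indicating more contamination; samples are retained
when delta Cq <= threshold (default 9, inclusive).  Oxy-hemoglobin
absorbance at 414 nm is an orthogonal readout of the same phenomenon
and is used correlatively, not as a filter.

Spike-ins (extraction, RT, interplate) are added in fixed amounts and
must show neither a group difference nor excess spread; a failing
spike-in means a technical, not biological, signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .plate_model import assays_with_role

__all__ = [
    "hemolysis_delta_cq",
    "filter_by_hemolysis",
    "spike_in_check",
    "hemolysis_method_agreement",
    "CorrelationResult",
]

DEFAULT_HEMOLYSIS_THRESHOLD = 9.0


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided p-value and sample size.

    ``r`` is NaN (with ``reason`` set) when the correlation is
    undefined — fewer than 3 paired observations or a constant vector.
    """

    r: float
    p: float
    n: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r)


def hemolysis_delta_cq(
    collapsed: pd.DataFrame,
    assays: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample hemolysis report: delta Cq, absorbance, pass reason.

    Requires exactly one assay with role hemolysis_stable and one with
    hemolysis_erythrocyte.  Samples in which either member of the pair
    is missing or undetected get an undefined delta with an explicit
    reason.  Detection status is honored when the table carries a
    ``detected`` column.
    """
    stable = assays_with_role(assays, "hemolysis_stable")
    eryth = assays_with_role(assays, "hemolysis_erythrocyte")
    if len(stable) != 1 or len(eryth) != 1:
        raise ValueError(
            "hemolysis QC needs exactly one hemolysis_stable and one "
            f"hemolysis_erythrocyte assay; found {stable} / {eryth}"
        )
    stable, eryth = stable[0], eryth[0]

    df = collapsed.copy()
    if "detected" in df.columns:
        df.loc[~df["detected"], "cq"] = np.nan
    pair = (
        df[df["assay_id"].isin([stable, eryth])]
        .pivot_table(index="sample_id", columns="assay_id", values="cq")
        .reindex(columns=[stable, eryth])
    )
    all_samples = sorted(df["sample_id"].unique())
    pair = pair.reindex(all_samples)

    report = pd.DataFrame({"sample_id": all_samples})
    report["delta_cq"] = (pair[stable] - pair[eryth]).to_numpy()
    reasons = []
    for s in all_samples:
        missing = [a for a in (stable, eryth) if pd.isna(pair.loc[s, a])]
        reasons.append(
            None if not missing else "undetected/missing: " + ", ".join(missing)
        )
    report["reason"] = reasons
    if samples is not None and "absorbance_414" in samples.columns:
        report = report.merge(
            samples[["sample_id", "absorbance_414"]], on="sample_id", how="left"
        )
    else:
        report["absorbance_414"] = np.nan
    return report


def filter_by_hemolysis(
    reports: pd.DataFrame,
    threshold: float = DEFAULT_HEMOLYSIS_THRESHOLD,
) -> list:
    """Sample ids whose hemolysis delta Cq is <= threshold (inclusive).

    Samples with undefined delta are excluded; ``threshold=inf``
    retains every sample with a defined delta.
    """
    ok = reports["delta_cq"].notna() & (reports["delta_cq"] <= threshold)
    return sorted(reports.loc[ok, "sample_id"])


def spike_in_check(
    collapsed: pd.DataFrame,
    assays: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    sd_limit: float = 1.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-spike-in constancy summary across the two study groups.

    A spike-in passes when its between-group t-test p >= alpha *and*
    its pooled SD <= sd_limit cycles.  Identical values everywhere are
    a pass (no evidence of a group difference; p reported as 1).
    Emits a ``missing_plates`` column listing plates a spike-in was
    absent from (warning-level, not a failure by itself).
    """
    spikes = sorted(
        set(assays_with_role(assays, "spike_in_isolation"))
        | set(assays_with_role(assays, "spike_in_rt"))
        | set(assays_with_role(assays, "interplate_calibrator"))
    )
    group_of = samples.set_index("sample_id")["group"]
    plates = sorted(collapsed["plate_id"].unique())

    rows = []
    for assay in spikes:
        sub = collapsed[(collapsed["assay_id"] == assay) & collapsed["cq"].notna()]
        vals = sub.set_index("sample_id")["cq"]
        groups = group_of.reindex(vals.index)
        x = vals[groups == "control"].to_numpy()
        y = vals[groups == "endometriosis"].to_numpy()
        missing_plates = sorted(set(plates) - set(sub["plate_id"].unique()))
        if len(x) < 2 or len(y) < 2:
            rows.append(
                dict(
                    assay_id=assay, mean_control=np.nan, mean_case=np.nan,
                    sd_control=np.nan, sd_case=np.nan, pooled_sd=np.nan,
                    p_value=np.nan, passed=False,
                    missing_plates=";".join(missing_plates),
                )
            )
            continue
        pooled_sd = float(np.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0))
        if np.ptp(np.r_[x, y]) == 0:
            p = 1.0  # no spread at all: no evidence of a group difference
        else:
            p = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
            if np.isnan(p):
                p = 1.0 if np.mean(x) == np.mean(y) else 0.0
        rows.append(
            dict(
                assay_id=assay,
                mean_control=float(np.mean(x)), mean_case=float(np.mean(y)),
                sd_control=float(np.std(x, ddof=1)), sd_case=float(np.std(y, ddof=1)),
                pooled_sd=pooled_sd,
                p_value=p,
                passed=bool(p >= alpha and pooled_sd <= sd_limit),
                missing_plates=";".join(missing_plates),
            )
        )
    return pd.DataFrame(rows)


def hemolysis_method_agreement(reports: pd.DataFrame) -> CorrelationResult:
    """Pearson agreement between 414 nm absorbance and delta Cq.

    Both metrics track the same latent hemolysis level, so they should
    correlate positively in a sound dataset.
    """
    sub = reports.dropna(subset=["delta_cq", "absorbance_414"])
    x = sub["absorbance_414"].to_numpy(float)
    y = sub["delta_cq"].to_numpy(float)
    if len(sub) < 3:
        return CorrelationResult(np.nan, np.nan, len(sub), "fewer than 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, len(sub), "constant vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(sub))
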