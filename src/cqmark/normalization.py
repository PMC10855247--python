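"""Interplate calibration and the two dCq normalization schemes.

Two conventions coexist in miRNA qPCR work and deliberately keep
opposite signs here, with the scheme tag travelling with the matrix so
downstream fold-change code can branch on it:

* profiling / global-mean: ``dCq = global mean Cq - assay Cq`` over the
  assays detected in every sample; *higher* dCq = more abundant.
* validation / reference: ``dCq = assay Cq - mean(reference Cq)``;
  *lower* dCq = more abundant, and relative expression is ``2**-dCq``
  (comparative-Cq method).

Both schemes cancel any per-sample additive shift (RNA content), which
is what makes them meaningful for serum input without a fixed RNA mass.
Interplate calibration subtracts, from every well of a plate, the
plate's calibrator-mean deviation from the global calibrator mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_model import assays_with_role, to_wide

__all__ = [
    "ExpressionMatrix",
    "interplate_calibrate",
    "normalize_global_mean",
    "normalize_reference",
]

SCHEME_PROFILING = "profiling_global_mean"
SCHEME_VALIDATION = "validation_reference"


@dataclass
class ExpressionMatrix:
    """Normalized expression values (samples x assays) with provenance.

    ``values`` holds dCq on the log2 scale under the sign convention of
    ``scheme``; ``relative_expression`` (= 2**-dCq) is populated for
    the validation scheme only.  ``excluded_samples`` maps dropped
    sample ids to the reason for exclusion.
    """

    values: pd.DataFrame
    scheme: str
    relative_expression: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)
    excluded_samples: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scheme not in (SCHEME_PROFILING, SCHEME_VALIDATION):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == SCHEME_VALIDATION and self.relative_expression is None:
            self.relative_expression = 2.0 ** (-self.values)

    @property
    def higher_is_more_abundant(self) -> bool:
        return self.scheme == SCHEME_PROFILING


def interplate_calibrate(
    collapsed: pd.DataFrame,
    calibrator_assay: str | None = None,
    assays: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Remove per-plate offsets using the interplate calibrator.

    The calibration factor of plate b is ``mean calibrator Cq on b -
    global mean calibrator Cq`` (global mean over all calibrator
    wells); every Cq on plate b is shifted by ``-factor_b``.  After
    calibration each plate's calibrator mean equals the global mean,
    and the well-count-weighted factors sum to zero.

    Returns the calibrated table and the per-plate factors.
    """
    if calibrator_assay is None:
        if assays is None:
            raise ValueError("need calibrator_assay or assay metadata")
        cal = assays_with_role(assays, "interplate_calibrator")
        if len(cal) != 1:
            raise ValueError(
                f"expected exactly one interplate calibrator, found {cal}"
            )
        calibrator_assay = cal[0]

    cal_rows = collapsed[
        (collapsed["assay_id"] == calibrator_assay) & collapsed["cq"].notna()
    ]
    plates = sorted(collapsed["plate_id"].unique())
    missing = sorted(set(plates) - set(cal_rows["plate_id"].unique()))
    if missing:
        raise ValueError(
            f"interplate calibrator {calibrator_assay!r} missing on plate(s) {missing}"
        )
    global_mean = cal_rows["cq"].mean()
    factors = cal_rows.groupby("plate_id")["cq"].mean() - global_mean
    factors.name = "calibration_factor"

    out = collapsed.copy()
    out["cq"] = out["cq"] - out["plate_id"].map(factors)
    return out, factors.sort_index()


def normalize_global_mean(
    calibrated: pd.DataFrame, assays: pd.DataFrame
) -> ExpressionMatrix:
    """Profiling-scheme normalization against the per-sample global mean.

    The global mean of sample j is taken over the *common set*: target
    assays detected in every sample.  ``dCq_ij = global_mean_j - Cq_ij``
    for every detected target assay (also those outside the common
    set); technical controls are excluded throughout.
    """
    wide = to_wide(calibrated)
    targets = [a for a in assays_with_role(assays, "target") if a in wide.columns]
    wide = wide[targets]
    common = wide.columns[wide.notna().all(axis=0)]
    if len(common) == 0:
        raise ValueError(
            "no target assay is detected in every sample; relax the detection "
            "limit or restrict the sample set"
        )
    global_mean = wide[common].mean(axis=1)
    dcq = wide.rsub(global_mean, axis=0)  # global mean - Cq
    return ExpressionMatrix(
        values=dcq,
        scheme=SCHEME_PROFILING,
        provenance={
            "common_detected_assays": list(common),
            "n_common": int(len(common)),
        },
    )


def normalize_reference(
    calibrated: pd.DataFrame,
    reference_assays: list[str],
    assays: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Validation-scheme normalization against reference miRNAs.

    ``dCq_ij = Cq_ij - mean(reference Cq in sample j)`` and relative
    expression ``2**-dCq``.  Samples in which any reference assay is
    undetected are excluded (with reason) rather than imputed.
    """
    if not reference_assays:
        raise ValueError("need at least one reference assay")
    wide = to_wide(calibrated)
    missing = sorted(set(reference_assays) - set(wide.columns))
    if missing:
        raise ValueError(f"reference assay(s) not in table: {missing}")

    ref = wide[list(reference_assays)]
    ok = ref.notna().all(axis=1)
    excluded = {
        s: "reference assay undetected: "
        + ", ".join(ref.columns[ref.loc[s].isna()])
        for s in wide.index[~ok]
    }
    wide = wide.loc[ok]
    ref_mean = wide[list(reference_assays)].mean(axis=1)

    if assays is not None:
        targets = [a for a in assays_with_role(assays, "target") if a in wide.columns]
        value_cols = targets
    else:
        value_cols = [c for c in wide.columns]
    dcq = wide[value_cols].sub(ref_mean, axis=0)  # Cq - reference mean
    return ExpressionMatrix(
        values=dcq,
        scheme=SCHEME_VALIDATION,
        provenance={"reference_assays": list(reference_assays)},
        excluded_samples=excluded,
    )
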