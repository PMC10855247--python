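"""Data model and I/O for raw RT-qPCR quantification-cycle (Cq) plates.

A qPCR run produces one Cq value per well; panels measure each
(sample, assay) in technical duplicate, possibly split across plates.
This module holds the long-format replicate table, sample and assay
metadata, replicate collapsing with discordance flags, and the
detection-limit censoring rule (Cq above the limit is treated as below
the assay's detection level and masked from downstream analysis, not
deleted from the raw table).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CqTable",
    "Dialect",
    "ASSAY_ROLES",
    "read_cq_table",
    "write_cq_table",
    "read_sample_metadata",
    "read_assay_metadata",
    "collapse_replicates",
    "apply_detection_limit",
    "to_wide",
    "assays_with_role",
]

#: Recognized assay roles.  An assay may carry several (e.g. a hemolysis
#: marker that is also a panel target).
ASSAY_ROLES = frozenset(
    {
        "target",
        "spike_in_isolation",
        "spike_in_rt",
        "interplate_calibrator",
        "hemolysis_stable",
        "hemolysis_erythrocyte",
        "reference_candidate",
        "reference",
    }
)

KEY_COLUMNS = ["sample_id", "assay_id", "plate_id", "replicate"]
CQ_COLUMNS = KEY_COLUMNS + ["cq"]

#: Default detection limit in cycles: Cq strictly greater than this is
#: considered below the assay's detection level.
DEFAULT_DETECTION_LIMIT = 35.0


@dataclass(frozen=True)
class Dialect:
    """Parsing dialect for instrument-exported Cq tables.

    ``columns`` maps canonical field names to the column names found in
    the file; ``undetermined`` is the set of cell values that encode an
    undetermined (no-amplification) well.
    """

    sep: str = ","
    columns: dict = field(
        default_factory=lambda: {c: c for c in CQ_COLUMNS}
    )
    undetermined: frozenset = frozenset({"Undetermined", "NA", ""})

    @classmethod
    def from_yaml(cls, path) -> "Dialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "sep" in raw:
            kwargs["sep"] = raw["sep"]
        if "columns" in raw:
            cols = dict({c: c for c in CQ_COLUMNS}, **raw["columns"])
            kwargs["columns"] = cols
        if "undetermined" in raw:
            kwargs["undetermined"] = frozenset(raw["undetermined"])
        return cls(**kwargs)


@dataclass
class CqTable:
    """Replicate-level Cq observations plus the detection limit.

    ``data`` has columns sample_id, assay_id, plate_id, replicate
    (positive int) and cq (float, NaN encodes an undetermined well).
    """

    data: pd.DataFrame
    detection_limit: float = DEFAULT_DETECTION_LIMIT

    def __post_init__(self) -> None:
        self.data = _validate_observations(self.data)
        if not self.detection_limit > 0:
            raise ValueError("detection_limit must be positive")

    @property
    def n_observations(self) -> int:
        return len(self.data)

    def with_detection_limit(self, limit: float) -> "CqTable":
        return replace(self, data=self.data.copy(), detection_limit=limit)


def _validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")
    df = df.loc[:, CQ_COLUMNS].copy()
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise ValueError("replicate indices must be positive")
    df["cq"] = pd.to_numeric(df["cq"], errors="raise").astype(float)
    present = df["cq"].dropna()
    if (present <= 0).any() or np.isinf(present).any():
        bad = present[(present <= 0) | np.isinf(present)]
        raise ValueError(f"Cq values must be finite and positive; got {bad.tolist()[:5]}")
    dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        key = df.loc[dup, KEY_COLUMNS].iloc[0].tolist()
        raise ValueError(
            f"duplicate (sample, assay, plate, replicate) key: {tuple(key)}"
        )
    return df.reset_index(drop=True)


def read_cq_table(
    path,
    dialect: Dialect | None = None,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
) -> CqTable:
    """Read a long-format delimited Cq table.

    Undetermined wells must use one of the sentinels declared in the
    dialect; any other non-numeric cell is a hard error reported with
    its line number (1-based, counting the header as line 1).
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    colmap = {v: k for k, v in dialect.columns.items()}
    raw = raw.rename(columns=colmap)
    missing = [c for c in CQ_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    cq_str = raw["cq"].str.strip()
    is_undet = cq_str.isin(dialect.undetermined)
    cq = pd.to_numeric(cq_str.where(~is_undet, other=np.nan), errors="coerce")
    bad = ~is_undet & cq.isna()
    if bad.any():
        lines = (raw.index[bad] + 2).tolist()  # +2: header line + 1-based
        vals = cq_str[bad].unique().tolist()
        raise ValueError(
            f"{path}: unknown Cq sentinel(s) {vals[:5]} on line(s) {lines[:10]}"
        )
    df = raw[KEY_COLUMNS].copy()
    df["cq"] = cq
    try:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer replicate column: {exc}") from exc
    return CqTable(df, detection_limit=detection_limit)


def write_cq_table(table: CqTable, path, dialect: Dialect | None = None) -> None:
    """Write a CqTable back to delimited text (round-trip safe).

    Undetermined wells are written with the dialect's first sentinel
    (sorted for determinism); Cq values use repr-precision so that a
    write/read cycle is bit-exact on the text representation.
    """
    dialect = dialect or Dialect()
    sentinel = sorted(dialect.undetermined)[-1] or "Undetermined"
    out = table.data.copy()
    out["cq"] = out["cq"].map(lambda v: sentinel if pd.isna(v) else repr(float(v)))
    out = out.rename(columns=dialect.columns)
    out.to_csv(path, sep=dialect.sep, index=False)


def read_sample_metadata(path, sep: str = ",") -> pd.DataFrame:
    """Read per-sample metadata (group, age, bmi, phase, stage, absorbance).

    Enforces: group in {control, endometriosis}; stage is not_applicable
    iff the sample is a control; positive ages when present.
    """
    df = pd.read_csv(path, sep=sep)
    return validate_samples(df)


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    df = df.copy()
    bad_group = ~df["group"].isin(["control", "endometriosis"])
    if bad_group.any():
        raise ValueError(
            f"unknown group labels: {df.loc[bad_group, 'group'].unique().tolist()}"
        )
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    for col, default in (
        ("age", np.nan),
        ("bmi", np.nan),
        ("phase", "unknown"),
        ("stage", None),
        ("absorbance_414", np.nan),
    ):
        if col not in df.columns:
            df[col] = default
    ctrl = df["group"] == "control"
    df.loc[ctrl & df["stage"].isna(), "stage"] = "not_applicable"
    if (df.loc[ctrl, "stage"] != "not_applicable").any():
        raise ValueError("control samples must have stage = not_applicable")
    if (df.loc[~ctrl, "stage"] == "not_applicable").any():
        raise ValueError("endometriosis samples must carry an ASRM stage (I-IV)")
    bad_stage = ~df["stage"].isin(["I", "II", "III", "IV", "not_applicable"]) & df["stage"].notna()
    if bad_stage.any():
        raise ValueError(
            f"unknown ASRM stage labels: {df.loc[bad_stage, 'stage'].unique().tolist()}"
        )
    ages = df["age"].dropna()
    if (ages <= 0).any():
        raise ValueError("ages must be positive")
    return df.reset_index(drop=True)


def read_assay_metadata(path, sep: str = ",") -> pd.DataFrame:
    """Read per-assay roles; the ``roles`` column is ';'-separated."""
    df = pd.read_csv(path, sep=sep)
    return validate_assays(df)


def validate_assays(df: pd.DataFrame) -> pd.DataFrame:
    required = {"assay_id", "roles"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay metadata missing columns: {sorted(missing)}")
    df = df.copy()
    if df["assay_id"].duplicated().any():
        raise ValueError("duplicate assay_id in metadata")
    df["roles"] = df["roles"].map(_parse_roles)
    return df.reset_index(drop=True)


def _parse_roles(value) -> frozenset:
    if isinstance(value, (set, frozenset)):
        roles = frozenset(value)
    else:
        roles = frozenset(p.strip() for p in str(value).split(";") if p.strip())
    unknown = roles - ASSAY_ROLES
    if unknown:
        raise ValueError(f"unknown assay role(s): {sorted(unknown)}")
    return roles


def assays_with_role(assays: pd.DataFrame, role: str) -> list:
    """Assay ids carrying ``role`` (roles column may be str or set)."""
    if role not in ASSAY_ROLES:
        raise ValueError(f"unknown role {role!r}")
    roles = assays["roles"].map(_parse_roles)
    return sorted(assays.loc[roles.map(lambda r: role in r), "assay_id"])


def collapse_replicates(
    table: CqTable, discordance_limit: float = 0.5
) -> pd.DataFrame:
    """Mean Cq per (sample, assay, plate) with discordance flags.

    Technical replicates are averaged over the determined members.  A
    pair is *flagged* — never dropped — when the absolute Cq difference
    exceeds ``discordance_limit`` cycles, or when at least one member is
    undetermined (the determined value, if any, is kept).  A group with
    all members undetermined yields an undetermined (NaN) mean, flagged.
    """
    g = table.data.groupby(["sample_id", "assay_id", "plate_id"], sort=True)["cq"]
    out = g.agg(
        cq="mean", n_replicates="size", n_present="count",
        cq_max="max", cq_min="min",
    ).reset_index()
    out["n_missing"] = out["n_replicates"] - out["n_present"]
    spread = (out["cq_max"] - out["cq_min"]).fillna(0.0)
    out["discordant"] = (spread > discordance_limit) | (out["n_missing"] > 0)
    return out.drop(columns=["n_present", "cq_max", "cq_min"])


def apply_detection_limit(
    collapsed: pd.DataFrame, limit: float = DEFAULT_DETECTION_LIMIT
) -> pd.DataFrame:
    """Mark collapsed Cq values as detected/undetected.

    A value is detected iff it is determined and Cq <= limit (the
    boundary itself is detected; only strictly greater values fall
    below the detection level).  Undetected values stay in the table
    for audit but must be masked from normalization and testing.
    """
    if not limit > 0:
        raise ValueError("detection limit must be positive")
    out = collapsed.copy()
    out["detected"] = out["cq"].notna() & (out["cq"] <= limit)
    return out


def to_wide(
    collapsed: pd.DataFrame, detected_only: bool = True
) -> pd.DataFrame:
    """Pivot collapsed Cq to a samples x assays matrix (NaN = missing).

    If the frame has a ``detected`` column and ``detected_only`` is set,
    undetected values become NaN.
    """
    df = collapsed
    if detected_only and "detected" in df.columns:
        df = df.copy()
        df.loc[~df["detected"], "cq"] = np.nan
    wide = df.pivot_table(
        index="sample_id", columns="assay_id", values="cq", aggfunc="mean"
    )
    wide.index.name = "sample_id"
    wide.columns.name = "assay_id"
    return wide.sort_index(axis=0).sort_index(axis=1)
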