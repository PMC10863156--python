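"""Readers/writers for the arm-summary CSV schema.

One documented dialect: comma-separated, UTF-8, '.' decimal separator,
mandatory header.  Required columns (case-insensitive): study_id, role,
n, mean_baseline, sd_baseline, mean_followup, sd_followup.  Optional:
sd_change, corr_pre_post, direction.  Unknown columns are preserved in
the table but ignored by the estimators.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, List

import pandas as pd

from .effects import ArmSummary, InputError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "study_id",
    "role",
    "n",
    "mean_baseline",
    "sd_baseline",
    "mean_followup",
    "sd_followup",
)
OPTIONAL_COLUMNS = ("sd_change", "corr_pre_post", "direction")

#: Synonyms accepted in the ``role`` column.
ROLE_ALIASES: Dict[str, str] = {
    "active": "active",
    "intervention": "active",
    "treatment": "active",
    "placebo": "placebo",
    "sham": "placebo",
    "placebo_active": "placebo",
    "placebo_control": "placebo_control",
    "open_label_placebo": "placebo_control",
    "no_treatment": "no_treatment",
    "no treatment": "no_treatment",
    "untreated": "no_treatment",
    "waitlist": "no_treatment",
    "natural_history": "no_treatment",
}


class SchemaError(InputError):
    """The CSV file does not match the arm-summary schema."""


def _normalize_role(raw: str, row: int) -> str:
    key = str(raw).strip().lower().replace("-", "_")
    if key not in ROLE_ALIASES:
        raise SchemaError(f"row {row}: unknown arm role {raw!r}")
    return ROLE_ALIASES[key]


def read_arm_table(path: str) -> pd.DataFrame:
    """Read and validate an arm-summary CSV.

    Returns a DataFrame with normalized column names and roles, one row
    per (study_id, role).  Row numbers in error messages count data
    rows from 1 (the header is row 0).
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError(f"{path!r} has a header but no data rows")
    df = df.reset_index(drop=True)
    df["study_id"] = df["study_id"].astype(str)
    df["role"] = [
        _normalize_role(v, i + 1) for i, v in enumerate(df["role"].tolist())
    ]
    if "direction" not in df.columns:
        logger.warning(
            "no 'direction' column in %s: assuming lower_is_better for all arms",
            path,
        )
        df["direction"] = "lower_is_better"
    else:
        df["direction"] = df["direction"].fillna("lower_is_better")
    for col in ("n", "mean_baseline", "sd_baseline", "mean_followup", "sd_followup"):
        for i, v in enumerate(df[col].tolist()):
            try:
                float(v)
            except (TypeError, ValueError):
                raise SchemaError(f"row {i + 1}: non-numeric value {v!r} in column {col!r}")
            if pd.isna(v):
                raise SchemaError(f"row {i + 1}: missing value in column {col!r}")
    dupes = df.duplicated(subset=["study_id", "role"], keep=False)
    if dupes.any():
        first = df.index[dupes][0] + 1
        pair = (df.loc[first - 1, "study_id"], df.loc[first - 1, "role"])
        raise SchemaError(f"duplicate (study_id, role) pair {pair} at row {first}")
    return df


def write_arm_table(df: pd.DataFrame, path: str) -> None:
    """Write an arm-summary table back to CSV (documented dialect)."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def _row_to_arm(row: pd.Series) -> ArmSummary:
    def opt(name: str):
        if name not in row.index:
            return None
        v = row[name]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    return ArmSummary(
        study_id=str(row["study_id"]),
        role=str(row["role"]),
        n=int(row["n"]),
        mean_baseline=float(row["mean_baseline"]),
        sd_baseline=float(row["sd_baseline"]),
        mean_followup=float(row["mean_followup"]),
        sd_followup=float(row["sd_followup"]),
        sd_change=opt("sd_change"),
        corr_pre_post=opt("corr_pre_post"),
        direction=str(row.get("direction", "lower_is_better")),
    )


def arms_by_study(df: pd.DataFrame) -> Dict[str, Dict[str, ArmSummary]]:
    """Group a validated arm table into {study_id: {role: ArmSummary}}."""
    out: Dict[str, Dict[str, ArmSummary]] = {}
    for _, row in df.iterrows():
        arm = _row_to_arm(row)
        out.setdefault(arm.study_id, {})[arm.role] = arm
    return out


def read_meta_table(path: str) -> List["MetaInput"]:
    """Read a generic meta-analysis CSV with columns study_id, y, v."""
    from .meta import MetaInput

    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in ("study_id", "y", "v") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError(f"{path!r} has a header but no data rows")
    return [
        MetaInput(study_id=str(r["study_id"]), y=float(r["y"]), v=float(r["v"]))
        for _, r in df.iterrows()
    ]
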