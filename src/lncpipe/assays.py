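"""Wet-lab quantification formulas: anthocyanin content and 2^-ddCt.

Total anthocyanin content per gram fresh weight is the background-corrected
absorbance Q = (A530 - 0.25 * A657) / M, with A530/A657 the absorbances at
530 and 657 nm and M the fresh tissue mass in grams. Relative qPCR
expression follows the 2^-ddCt convention: dCt = Ct_target - Ct_reference
per sample, ddCt = dCt - dCt_calibrator per gene, fold change = 2^-ddCt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

__all__ = [
    "AssayReading",
    "anthocyanin_content",
    "anthocyanin_table",
    "ddct_fold_change",
    "stage_summary",
]


@dataclass(frozen=True)
class AssayReading:
    """One spectrophotometer reading of an anthocyanin extract."""

    sample_id: str
    stage: str
    a530: float
    a657: float
    mass_g: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.a530 < 0 or self.a657 < 0:
            raise ValidationError(f"{self.sample_id}: absorbances must be >= 0")
        if self.mass_g <= 0:
            raise ValidationError(f"{self.sample_id}: fresh mass must be > 0")


def anthocyanin_content(r: AssayReading) -> float:
    """Q = (A530 - 0.25 * A657) / M, per gram fresh weight.

    Negative Q (background exceeding signal) is returned with a warning
    rather than raised.
    """
    q = (r.a530 - 0.25 * r.a657) / r.mass_g
    if q < 0:
        warnings.warn(
            f"{r.sample_id}: negative anthocyanin content ({q:.4g}); "
            "A657 background exceeds the A530 signal",
            stacklevel=2,
        )
    return q


def anthocyanin_table(readings) -> pd.DataFrame:
    """Per-reading Q plus mean +/- SE per stage."""
    rows = [
        {"sample_id": r.sample_id, "stage": r.stage, "replicate": r.replicate,
         "q": anthocyanin_content(r)}
        for r in readings
    ]
    return pd.DataFrame(rows)


def ddct_fold_change(records: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Relative expression by 2^-ddCt.

    ``records`` needs columns sample_id, stage, gene, ct_target,
    ct_reference. ``calibrator`` names either a sample_id or a stage; the
    per-gene calibrator dCt is the mean over matching records (with a single
    calibrator record per gene, its own fold change is exactly 1).
    """
    df = records.copy()
    required = {"sample_id", "stage", "gene", "ct_target", "ct_reference"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValidationError(f"Ct table missing columns: {sorted(missing_cols)}")
    bad = df[df["ct_reference"].isna()]
    if not bad.empty:
        raise ValidationError(
            f"missing reference Ct for sample {bad.iloc[0]['sample_id']!r}"
        )
    df["dct"] = df["ct_target"] - df["ct_reference"]

    is_cal = (df["sample_id"] == calibrator) | (df["stage"] == calibrator)
    df["is_calibrator"] = is_cal
    out = []
    for gene, sub in df.groupby("gene", sort=False):
        cal = sub[sub["is_calibrator"]]
        if cal.empty:
            raise ValidationError(f"no calibrator records for gene {gene!r}")
        cal_dct = cal["dct"].mean()
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - cal_dct
        sub["fold_change"] = 2.0 ** (-sub["ddct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def stage_summary(table: pd.DataFrame, value_col: str = "fold_change") -> pd.DataFrame:
    """Replicate mean and standard error per (gene, stage) or per stage."""
    keys = [c for c in ("gene", "stage") if c in table.columns]
    g = table.groupby(keys, sort=False)[value_col]
    summary = g.agg(mean="mean", sd="std", n="count").reset_index()
    summary["se"] = summary["sd"] / summary["n"] ** 0.5
    return summary.drop(columns=["sd"])
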