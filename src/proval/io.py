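"""Cohort data model and CSV input/output.

A cohort table holds one row per participant-visit (visits ``baseline`` and
``followup``), with item-level questionnaire responses, the two 7-point
global-change anchors (follow-up only), the SARC-F screening score, and
baseline physical-performance measures (max grip strength, SPPB, 4-m walk
speed, chair-stand time, skeletal muscle mass index).

Missing values are empty cells in CSV; sentinel strings ("NA", ".", ...) are
rejected rather than silently treated as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, RangeError, SchemaError
from .schema import QuestionnaireSchema

logger = logging.getLogger(__name__)

VISITS = ("baseline", "followup")

#: clinical numeric columns -> (min, max); None = unbounded on that side
NUMERIC_COLUMNS: dict[str, tuple[float | None, float | None]] = {
    "sarcf": (0, 10),
    "grip_kg": (0, None),
    "sppb": (0, 12),
    "walk_speed_mps": (0, None),
    "chair_stand_s": (0, None),
    "smi_kg_m2": (0, None),
    "age_years": (0, None),
}

CATEGORICAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "followup_mode": ("telephone", "face_to_face", "none"),
}

ANCHOR_COLUMNS = ("anchor_fitness", "anchor_qol")
KEY_COLUMNS = ("participant_id", "visit")


@dataclass
class CohortTable:
    """Validated per-participant, per-visit cohort table.

    ``data`` is indexed positionally; use :meth:`baseline` / :meth:`followup`
    for visit slices. Construction validates all structural invariants.
    """

    data: pd.DataFrame
    schema: QuestionnaireSchema

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        _validate(self.data, self.schema)

    # -- accessors -------------------------------------------------------------

    def baseline(self) -> pd.DataFrame:
        return self.data[self.data["visit"] == "baseline"]

    def followup(self) -> pd.DataFrame:
        return self.data[self.data["visit"] == "followup"]

    @property
    def n_participants(self) -> int:
        return self.data["participant_id"].nunique()

    @property
    def item_columns(self) -> list[str]:
        return [c for c in self.schema.item_ids if c in self.data.columns]

    def __len__(self) -> int:
        return len(self.data)

    # -- output ----------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        """Write the cohort as UTF-8 CSV, missing values as empty cells."""
        self.data.to_csv(path, index=False, na_rep="")


def _empty_frame(schema: QuestionnaireSchema) -> pd.DataFrame:
    cols = list(KEY_COLUMNS) + list(schema.item_ids) + list(ANCHOR_COLUMNS) + \
        list(NUMERIC_COLUMNS) + list(CATEGORICAL_COLUMNS)
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def empty_cohort(schema: QuestionnaireSchema) -> CohortTable:
    """An empty but structurally valid cohort table."""
    return CohortTable(_empty_frame(schema), schema)


def _validate(df: pd.DataFrame, schema: QuestionnaireSchema) -> None:
    for col in KEY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing")

    known = set(KEY_COLUMNS) | set(schema.item_ids) | set(ANCHOR_COLUMNS) \
        | set(NUMERIC_COLUMNS) | set(CATEGORICAL_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"unknown column(s) not in schema: {unknown}")

    bad_visit = set(df["visit"].dropna()) - set(VISITS)
    if bad_visit:
        raise RangeError(f"visit labels must be in {VISITS}, got {sorted(bad_visit)}")

    dup = df.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        rows = df.loc[dup, list(KEY_COLUMNS)].to_records(index=False).tolist()
        raise IntegrityError(f"duplicate (participant, visit) rows: {rows}")

    base_ids = set(df.loc[df["visit"] == "baseline", "participant_id"])
    fu_ids = set(df.loc[df["visit"] == "followup", "participant_id"])
    orphans = fu_ids - base_ids
    if orphans:
        raise IntegrityError(
            f"follow-up rows without a matching baseline row: {sorted(map(str, orphans))}"
        )

    # numeric coercion: sentinel strings in numeric columns are an error
    numeric_cols = list(schema.item_ids) + list(NUMERIC_COLUMNS)
    for col in numeric_cols:
        if col not in df.columns:
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise RangeError(
                f"column {col!r} contains a non-numeric value; missing data must "
                f"be empty cells, not sentinel strings ({exc})"
            ) from None

    # range checks, with row identification
    spec_by_item = {it.item_id: it for d in schema.domains for it in d.items}
    for col in df.columns:
        if col in spec_by_item:
            lo, hi = spec_by_item[col].minimum, spec_by_item[col].maximum
        elif col in NUMERIC_COLUMNS:
            lo, hi = NUMERIC_COLUMNS[col]
        else:
            continue
        vals = df[col]
        bad = pd.Series(False, index=df.index)
        if lo is not None:
            bad |= vals < lo
        if hi is not None:
            bad |= vals > hi
        if bad.any():
            first = df.loc[bad].iloc[0]
            raise RangeError(
                f"column {col!r} out of range [{lo}, {hi}] for participant "
                f"{first['participant_id']!r} visit {first['visit']!r} "
                f"(value {first[col]!r})"
            )

    for col, levels in CATEGORICAL_COLUMNS.items():
        if col not in df.columns:
            continue
        bad_levels = set(df[col].dropna()) - set(levels)
        if bad_levels:
            raise RangeError(
                f"column {col!r}: values {sorted(bad_levels)} not in {levels}"
            )

    # anchors may only appear on follow-up rows
    for col in ANCHOR_COLUMNS:
        if col not in df.columns:
            continue
        # numeric 1-7 codes accepted (possibly read as strings from CSV)
        def _coerce_anchor(v):
            if isinstance(v, str):
                try:
                    return float(v)
                except ValueError:
                    return v
            return v
        df[col] = df[col].map(_coerce_anchor, na_action="ignore")
        at_baseline = df[(df["visit"] == "baseline") & df[col].notna()]
        if len(at_baseline):
            pid = at_baseline.iloc[0]["participant_id"]
            raise IntegrityError(
                f"anchor {col!r} recorded at baseline for participant {pid!r}; "
                "anchors are collected at follow-up only"
            )
        valid = set(schema.anchor_labels) | set(range(1, 8)) | set(float(i) for i in range(1, 8))
        bad_anchor = set(df[col].dropna()) - valid
        if bad_anchor:
            raise RangeError(
                f"column {col!r}: unknown anchor level(s) {sorted(map(str, bad_anchor))}"
            )


def load_cohort(path: str | Path, schema: QuestionnaireSchema) -> CohortTable:
    """Read and validate a cohort CSV against ``schema``.

    Missing cells are preserved as missing (never imputed).  Errors:
    :class:`~proval.exceptions.SchemaError` for unknown columns,
    :class:`~proval.exceptions.IntegrityError` for duplicate or orphaned rows,
    :class:`~proval.exceptions.RangeError` for out-of-range or sentinel values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=object, keep_default_na=False,
                     na_values=[""], encoding="utf-8")
    if "participant_id" in df.columns:
        df["participant_id"] = df["participant_id"].astype(str)
    n_missing = int(df.isna().sum().sum())
    logger.info("loaded %d rows from %s (%d missing cells)", len(df), path, n_missing)
    return CohortTable(df, schema)
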