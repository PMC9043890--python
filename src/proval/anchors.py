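"""Global-change anchors and per-participant change scores.

The two 7-point global rating-of-change anchors (overall fitness, overall
quality of life) are amalgamated to five analysis categories — the extreme
levels "much worse" and "much better" are merged into "worse" and "better"
because few participants choose them — plus a derived overlapping
"any improvement" group (slightly better, better or much better).

Change scores are follow-up minus baseline for the total score, every domain
score and SARC-F; only participants with both visits appear in the change
table, and participants lacking an anchor response are excluded from
anchor-grouped summaries only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import RangeError
from .io import CohortTable
from .schema import ANCHOR_LEVELS
from .scoring import TOTAL_COLUMN

logger = logging.getLogger(__name__)

#: the five amalgamated categories, worst to best
AMALGAMATED_CATEGORIES = (
    "worse", "slightly worse", "about the same", "slightly better", "better",
)
NO_CHANGE_CATEGORY = "about the same"
ANY_IMPROVEMENT_LEVELS = frozenset({"slightly better", "better", "much better"})


@dataclass(frozen=True)
class AnchorCategory:
    """Amalgamated anchor category with the derived any-improvement flag."""

    value: str
    any_improvement: bool


def amalgamate_anchor(raw, labels: tuple[str, ...] = ANCHOR_LEVELS) -> AnchorCategory:
    """Map a raw 7-level anchor response to its amalgamated category.

    ``raw`` may be a label from ``labels`` or a numeric 1-7 code (1 = worst).
    """
    if isinstance(raw, (int, float, np.integer, np.floating)) and not isinstance(raw, bool):
        code = float(raw)
        if code != int(code) or not 1 <= code <= 7:
            raise RangeError(f"numeric anchor code must be an integer 1-7, got {raw!r}")
        label = labels[int(code) - 1]
    elif raw in labels:
        label = raw
    else:
        raise RangeError(f"unknown anchor response {raw!r}; expected one of {labels} or 1-7")

    canonical = ANCHOR_LEVELS[labels.index(label)]
    if canonical == "much worse":
        value = "worse"
    elif canonical == "much better":
        value = "better"
    else:
        value = canonical
    return AnchorCategory(value=value, any_improvement=canonical in ANY_IMPROVEMENT_LEVELS)


def build_change_table(scores: pd.DataFrame, cohort: CohortTable) -> pd.DataFrame:
    """Per-participant change table (follow-up minus baseline).

    ``scores`` is the (participant_id, visit)-indexed frame from
    :func:`proval.scoring.score_cohort` (domain columns + ``total``).

    Returns one row per participant with both visits: baseline/follow-up
    total and SARC-F, ``change_<column>`` for every score column and SARC-F,
    and the amalgamated anchor categories (missing where the anchor was not
    answered).
    """
    labels = cohort.schema.anchor_labels
    df = cohort.data
    base = df[df["visit"] == "baseline"].set_index("participant_id")
    fu = df[df["visit"] == "followup"].set_index("participant_id")
    both = fu.index.intersection(base.index)

    sb = scores.xs("baseline", level="visit")
    sf = scores.xs("followup", level="visit")
    both = both.intersection(sb.index).intersection(sf.index)

    out = pd.DataFrame(index=both)
    out.index.name = "participant_id"
    for col in scores.columns:
        out[f"baseline_{col}"] = sb.loc[both, col].astype(float)
        out[f"followup_{col}"] = sf.loc[both, col].astype(float)
        out[f"change_{col}"] = out[f"followup_{col}"] - out[f"baseline_{col}"]

    if "sarcf" in df.columns:
        out["baseline_sarcf"] = base.loc[both, "sarcf"].astype(float)
        out["followup_sarcf"] = fu.loc[both, "sarcf"].astype(float)
        out["change_sarcf"] = out["followup_sarcf"] - out["baseline_sarcf"]

    for kind, col in (("fitness", "anchor_fitness"), ("qol", "anchor_qol")):
        cats, improv = [], []
        for pid in both:
            raw = fu.loc[pid, col] if col in fu.columns else np.nan
            if pd.isna(raw):
                cats.append(np.nan)
                improv.append(np.nan)
            else:
                ac = amalgamate_anchor(raw, labels)
                cats.append(ac.value)
                improv.append(ac.any_improvement)
        out[f"anchor_{kind}"] = cats
        out[f"any_improvement_{kind}"] = improv
        n_missing = int(pd.isna(pd.Series(cats)).sum())
        if n_missing:
            logger.info("%d participants lack the %s anchor; excluded from "
                        "anchor-grouped summaries only", n_missing, kind)
    return out.reset_index()


def change_summary(change_table: pd.DataFrame, anchor: str = "fitness",
                   include_any_improvement: bool = True) -> pd.DataFrame:
    """Mean (SD) of every change column per amalgamated anchor category.

    Mirrors the classic anchor-table layout: columns are the five categories
    (plus the overlapping 'any improvement' group), rows are change variables;
    each cell holds mean, sd and n.
    """
    cat_col = f"anchor_{anchor}"
    if cat_col not in change_table.columns:
        raise KeyError(f"no column {cat_col!r} in change table")
    change_cols = [c for c in change_table.columns if c.startswith("change_")]

    groups: dict[str, pd.DataFrame] = {}
    for cat in AMALGAMATED_CATEGORIES:
        groups[cat] = change_table[change_table[cat_col] == cat]
    if include_any_improvement:
        imp = change_table[change_table[f"any_improvement_{anchor}"] == True]  # noqa: E712
        groups["any improvement"] = imp

    rows = []
    for var in change_cols:
        row: dict = {"variable": var}
        for cat, sub in groups.items():
            vals = sub[var].dropna().astype(float)
            row[f"{cat}|mean"] = vals.mean() if len(vals) else np.nan
            row[f"{cat}|sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{cat}|n"] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows)


def baseline_followup_correlation(
    baseline_values, followup_values
) -> tuple[float, float, int]:
    """Pearson correlation between matched baseline and follow-up values.

    Returns ``(r, two-sided p, n)``.  The r feeds the (1 - r^2) sample-size
    adjustment downstream.  Raises on degenerate input (fewer than 3 matched
    pairs or zero variance).
    """
    x = pd.Series(np.asarray(baseline_values, dtype=float))
    y = pd.Series(np.asarray(followup_values, dtype=float))
    if len(x) != len(y):
        raise ValueError("baseline and follow-up series must be matched")
    mask = x.notna() & y.notna()
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError(f"need >= 3 matched pairs, got {len(x)}")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance in baseline or follow-up values")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(len(x))
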