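"""Grouped descriptive statistics with between-group tests.

Continuous variables flagged normal are summarised as mean (SD) and compared
with Student's t-test; flagged non-normal ones as median [IQR] with the
Mann-Whitney U test; categorical variables as count (%) with Pearson's
chi-squared test.  All tests two-sided; the test used is recorded per row.
Normality flags are configuration, not inference: the defaults mirror the
common pattern where chair-stand time is right-skewed and everything else is
treated as normal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable

logger = logging.getLogger(__name__)

DEFAULT_CONTINUOUS = (
    "age_years", "sppb", "grip_kg", "walk_speed_mps", "chair_stand_s",
    "sarcf", "smi_kg_m2",
)
DEFAULT_CATEGORICAL = ("sex",)

#: variable -> treated as normally distributed
DEFAULT_NORMAL_FLAGS = {v: v != "chair_stand_s" for v in DEFAULT_CONTINUOUS}

SIGNIFICANCE_LEVEL = 0.05  # two-sided, surfaced for all downstream reporting


def _summary_continuous(x: pd.Series, normal: bool) -> tuple[str, float, float]:
    x = x.dropna().astype(float)
    if normal:
        return f"{x.mean():.2f} ({x.std(ddof=1):.2f})", x.mean(), x.std(ddof=1)
    q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{med:.1f} [{q1:.1f}-{q3:.1f}]", med, q3 - q1


def describe_cohort(
    cohort: CohortTable,
    group_by: str = "followup_mode",
    variables: tuple[str, ...] | None = None,
    categorical: tuple[str, ...] | None = None,
    normal_flags: dict[str, bool] | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Baseline descriptives per group with pairwise tests against a reference.

    Groups are partitions of participants via the baseline value of
    ``group_by``.  Each non-reference group is compared with the reference
    group (default: the largest group).  Empty groups are dropped with a
    logged warning.

    Returns a tidy frame: variable, group, n, summary, statistic-relevant
    numbers, test name and two-sided p-value (p reported on non-reference
    groups).
    """
    variables = variables or DEFAULT_CONTINUOUS
    categorical = categorical or DEFAULT_CATEGORICAL
    flags = dict(DEFAULT_NORMAL_FLAGS)
    if normal_flags:
        flags.update(normal_flags)

    base = cohort.baseline().copy()
    if group_by not in base.columns:
        raise KeyError(f"grouping column {group_by!r} not in cohort")
    base[group_by] = base[group_by].fillna("none")

    groups: dict[str, pd.DataFrame] = {}
    for name, sub in base.groupby(group_by, sort=False):
        if len(sub) == 0:
            logger.warning("group %r is empty; dropped", name)
            continue
        groups[str(name)] = sub
    if not groups:
        raise ValueError("no non-empty groups")
    if reference is None:
        reference = max(groups, key=lambda g: len(groups[g]))

    rows: list[dict] = []
    for var in variables:
        if var not in base.columns:
            continue
        normal = flags.get(var, True)
        ref_vals = groups[reference][var].dropna().astype(float)
        for gname, sub in groups.items():
            vals = sub[var].dropna().astype(float)
            summary, center, spread = _summary_continuous(sub[var], normal)
            test, p = "", np.nan
            if gname != reference and len(vals) >= 2 and len(ref_vals) >= 2:
                if normal:
                    test = "t-test"
                    _, p = stats.ttest_ind(vals, ref_vals, equal_var=True)
                else:
                    test = "mann-whitney"
                    _, p = stats.mannwhitneyu(vals, ref_vals, alternative="two-sided")
            rows.append({"variable": var, "group": gname, "n": len(vals),
                         "summary": summary, "center": center, "spread": spread,
                         "test": test, "p": p,
                         "distribution": "normal" if normal else "non-normal"})

    for var in categorical:
        if var not in base.columns:
            continue
        levels = sorted(base[var].dropna().unique())
        for level in levels:
            for gname, sub in groups.items():
                n_level = int((sub[var] == level).sum())
                n_tot = int(sub[var].notna().sum())
                pct = 100.0 * n_level / n_tot if n_tot else np.nan
                test, p = "", np.nan
                if gname != reference:
                    ref_sub = groups[reference]
                    table = np.array([
                        [(sub[var] == lv).sum() for lv in levels],
                        [(ref_sub[var] == lv).sum() for lv in levels],
                    ])
                    if table.sum() and (table.sum(axis=0) > 0).all():
                        test = "chi-squared"
                        res = stats.chi2_contingency(table, correction=False)
                        p = res.pvalue
                rows.append({"variable": f"{var}={level}", "group": gname,
                             "n": n_level, "summary": f"{n_level} ({pct:.0f}%)",
                             "center": n_level, "spread": pct,
                             "test": test, "p": p, "distribution": "categorical"})

    return pd.DataFrame(rows)
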