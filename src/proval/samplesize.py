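"""Anchor-based MCID estimation and two-arm trial sample-size tables.

The minimum clinically important difference (MCID, delta) is the |mean change|
of the anchor group reporting slight improvement (or worsening), rounded to a
per-instrument precision (integer for 0-100 scores, one decimal for SARC-F).

For a 1:1 two-arm trial detecting delta with change SD sigma at two-sided
significance alpha and the given power, the normal-approximation per-arm size

    n_arm = 2 * sigma^2 * (z_{1-alpha/2} + z_power)^2 / delta^2

is doubled and ceiled to the nearest even integer.  When the analysis adjusts
for the baseline value, the total is multiplied by (1 - r^2) — r the
baseline-follow-up Pearson correlation — and ceiled to even again.  The
rounding pipeline is pinned in that order: even-ceiled total first, adjustment
applied to the rounded total, even-ceiled again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .anchors import AMALGAMATED_CATEGORIES


@dataclass
class McidResult:
    """Anchor-based MCID: rounded value, the raw mean retained, n, flag."""

    value: float | None
    raw_mean: float | None
    n: int
    flag: str | None = None


def estimate_mcid(group_changes, decimals: int = 0) -> McidResult:
    """|mean change| of an anchor group, rounded to ``decimals`` places."""
    vals = pd.Series(group_changes).dropna().astype(float)
    if len(vals) == 0:
        return McidResult(value=None, raw_mean=None, n=0, flag="empty_group")
    raw = float(vals.mean())
    rounded = round(abs(raw), decimals)
    if decimals == 0:
        rounded = float(int(rounded))
    flag = "zero_mcid" if rounded == 0 else None
    return McidResult(value=rounded, raw_mean=raw, n=len(vals), flag=flag)


def _ceil_even(x: float) -> int:
    n = math.ceil(x - 1e-9)
    return n if n % 2 == 0 else n + 1


def trial_sample_size(mcid: float, sd: float, power: float = 0.80,
                      alpha: float = 0.05) -> int:
    """Total N (both arms) to detect ``mcid`` with change SD ``sd``.

    Standard-normal quantiles (no t-correction); total ceiled to even.
    """
    if mcid <= 0:
        raise ValueError("MCID must be strictly positive")
    if sd <= 0:
        raise ValueError("SD must be strictly positive")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2.0) + stats.norm.ppf(power)
    n_arm = 2.0 * sd ** 2 * z ** 2 / mcid ** 2
    return _ceil_even(2.0 * n_arm)


def adjust_sample_size(n_total: int, r: float) -> int:
    """Baseline-adjusted total: ``n_total * (1 - r^2)``, ceiled to even."""
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    if n_total <= 0 or n_total % 2:
        raise ValueError("n_total must be an even positive integer")
    return _ceil_even(n_total * (1.0 - r ** 2))


#: anchor-table category -> sample-size-table row label
TABLE_CATEGORIES = {
    "slightly better": "slight improvement",
    "any improvement": "any improvement",
    "slightly worse": "slight worsening",
}

DEFAULT_ROUNDING = {"total": 0, "sarcf": 1}


def sample_size_table(
    change_table: pd.DataFrame,
    r_map: dict[str, float],
    instruments: tuple[str, ...] = ("total", "sarcf"),
    anchors: tuple[str, ...] = ("fitness", "qol"),
    powers: tuple[float, ...] = (0.80, 0.90),
    alpha: float = 0.05,
    rounding: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Full sample-size grid from a per-participant change table.

    One row per instrument x anchor x category; columns give MCID, SD of
    change (rounded to the instrument's precision before entering the
    formula), and unadjusted/adjusted totals at each power.  Rows whose MCID
    is undefined or zero are emitted flagged with missing n.
    """
    rounding = rounding or DEFAULT_ROUNDING
    rows = []
    for inst, anchor in product(instruments, anchors):
        cat_col = f"anchor_{anchor}"
        dec = rounding.get(inst, 0)
        for cat, label in TABLE_CATEGORIES.items():
            if cat == "any improvement":
                grp = change_table[change_table[f"any_improvement_{anchor}"] == True]  # noqa: E712
            else:
                grp = change_table[change_table[cat_col] == cat]
            changes = grp[f"change_{inst}"].dropna().astype(float)
            mcid = estimate_mcid(changes, decimals=dec)
            sd = round(changes.std(ddof=1), dec) if len(changes) > 1 else np.nan
            if dec == 0 and np.isfinite(sd):
                sd = float(int(sd))
            row = {"instrument": inst, "anchor_kind": anchor, "category": label,
                   "mcid": mcid.value, "mcid_raw": mcid.raw_mean, "sd": sd,
                   "n_group": mcid.n, "alpha_level": alpha,
                   "r_baseline_followup": r_map.get(inst, 0.0),
                   "flag": mcid.flag}
            for power in powers:
                tag = f"{int(round(power * 100))}"
                if mcid.flag or not np.isfinite(sd) or sd <= 0:
                    row[f"n_unadjusted_{tag}"] = np.nan
                    row[f"n_adjusted_{tag}"] = np.nan
                    row["flag"] = row["flag"] or "undefined_sd"
                    continue
                n_un = trial_sample_size(mcid.value, sd, power, alpha)
                row[f"n_unadjusted_{tag}"] = n_un
                row[f"n_adjusted_{tag}"] = adjust_sample_size(n_un, r_map.get(inst, 0.0))
            rows.append(row)
    return pd.DataFrame(rows)
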