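"""Responsiveness: Cohen's d (distribution form) and Guyatt's coefficient.

Cohen's d here is the responsiveness form used for longitudinal PRO
validation: |mean change| divided by the pooled SD of the baseline and
follow-up scores of the same group, pooled SD = sqrt((sd_b^2 + sd_f^2)/2).

Guyatt's responsiveness coefficient divides the group's |mean change| by the
SD of change in the group reporting 'no change' on the anchor — the stable
group's change SD acts as the noise floor.

Magnitudes are reported non-negative; when the change direction opposes the
anchor direction (e.g. an "improvement" group whose scores worsened) the
result carries a ``paradoxical`` flag instead of a sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anchors import NO_CHANGE_CATEGORY

#: instrument -> +1 if higher scores mean better health, -1 otherwise.
DEFAULT_DIRECTIONS = {"total": +1, "sarcf": -1}

#: anchor category -> expected sign of (direction * change)
_CATEGORY_SIGN = {"slightly worse": -1, "worse": -1,
                  "slightly better": +1, "better": +1, "any improvement": +1}


@dataclass
class EffectSize:
    """Non-negative effect magnitude with direction bookkeeping.

    ``paradoxical`` is True when the observed mean change runs against the
    direction implied by the anchor category; ``flag`` marks undefined cells
    (zero denominator, empty or singleton groups).
    """

    value: float | None
    n: int
    paradoxical: bool = False
    flag: str | None = None

    @property
    def defined(self) -> bool:
        return self.flag is None


def _direction_flags(mean_change: float, expected_sign: int,
                     higher_is_better: int) -> bool:
    observed = np.sign(mean_change) * higher_is_better
    return bool(observed != 0 and expected_sign != 0 and observed != expected_sign)


def cohens_d(baseline_scores, followup_scores, expected_sign: int = +1,
             higher_is_better: int = +1) -> EffectSize:
    """|mean change| / pooled SD of baseline and follow-up scores.

    ``expected_sign`` is the change direction the anchor category implies
    (+1 improvement, -1 worsening, 0 none); ``higher_is_better`` encodes the
    instrument's orientation.
    """
    b = np.asarray(pd.Series(baseline_scores).dropna(), dtype=float)
    f = np.asarray(pd.Series(followup_scores).dropna(), dtype=float)
    if len(b) != len(f):
        raise ValueError("baseline and follow-up scores must be matched")
    n = len(b)
    if n < 2:
        return EffectSize(value=None, n=n, flag="singleton_group" if n else "empty_group")
    pooled = np.sqrt((b.std(ddof=1) ** 2 + f.std(ddof=1) ** 2) / 2.0)
    if pooled == 0:
        return EffectSize(value=None, n=n, flag="zero_pooled_sd")
    mean_change = (f - b).mean()
    return EffectSize(value=float(abs(mean_change) / pooled), n=n,
                      paradoxical=_direction_flags(mean_change, expected_sign,
                                                   higher_is_better))


def guyatt_coefficient(group_changes, nochange_changes, expected_sign: int = +1,
                       higher_is_better: int = +1) -> EffectSize:
    """|mean change in group| / SD of change in the stable ('no change') group."""
    g = np.asarray(pd.Series(group_changes).dropna(), dtype=float)
    s = np.asarray(pd.Series(nochange_changes).dropna(), dtype=float)
    if len(g) == 0:
        return EffectSize(value=None, n=0, flag="empty_group")
    if len(s) < 2:
        return EffectSize(value=None, n=len(g), flag="nochange_too_small")
    sd = s.std(ddof=1)
    if sd == 0:
        return EffectSize(value=None, n=len(g), flag="zero_nochange_sd")
    mean_change = g.mean()
    return EffectSize(value=float(abs(mean_change) / sd), n=len(g),
                      paradoxical=_direction_flags(mean_change, expected_sign,
                                                   higher_is_better))


REPORT_CATEGORIES = ("slightly worse", "slightly better", "any improvement")


def responsiveness_table(
    change_table: pd.DataFrame,
    instruments: dict[str, int] | None = None,
    anchors: tuple[str, ...] = ("fitness", "qol"),
    categories: tuple[str, ...] = REPORT_CATEGORIES,
) -> pd.DataFrame:
    """Cohen's d and Guyatt's coefficient per instrument x anchor x category.

    Undefined cells are rendered flagged, never omitted.  ``instruments`` maps
    a score column stem (e.g. ``total``, ``sarcf``) to its orientation
    (+1 higher = better).
    """
    instruments = instruments or DEFAULT_DIRECTIONS
    rows = []
    for anchor in anchors:
        cat_col = f"anchor_{anchor}"
        nochange = change_table[change_table[cat_col] == NO_CHANGE_CATEGORY]
        for inst, direction in instruments.items():
            for cat in categories:
                if cat == "any improvement":
                    grp = change_table[change_table[f"any_improvement_{anchor}"] == True]  # noqa: E712
                else:
                    grp = change_table[change_table[cat_col] == cat]
                sign = _CATEGORY_SIGN.get(cat, 0)
                pairs = grp[[f"baseline_{inst}", f"followup_{inst}"]].dropna()
                d = cohens_d(pairs[f"baseline_{inst}"], pairs[f"followup_{inst}"],
                             expected_sign=sign, higher_is_better=direction)
                g = guyatt_coefficient(grp[f"change_{inst}"],
                                       nochange[f"change_{inst}"],
                                       expected_sign=sign, higher_is_better=direction)
                rows.append({
                    "instrument": inst, "anchor_kind": anchor, "category": cat,
                    "cohen_d": d.value, "cohen_d_paradoxical": d.paradoxical,
                    "cohen_d_flag": d.flag,
                    "guyatt": g.value, "guyatt_paradoxical": g.paradoxical,
                    "guyatt_flag": g.flag,
                    "n_group": g.n, "n_nochange": int(nochange[f"change_{inst}"].notna().sum()),
                })
    return pd.DataFrame(rows)
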