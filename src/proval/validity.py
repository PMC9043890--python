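"""Concurrent validity: correlations of scores with external measures.

Pearson correlations between the baseline total/domain scores and baseline
physical-performance measures and SARC-F, with pairwise-complete deletion per
cell (columns differ in completeness, e.g. walk speed is missing for a few
participants).  Directionality is preserved: a higher-is-better score is
expected to correlate negatively with SARC-F (higher = worse function).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable

DEFAULT_MEASURES = ("sarcf", "grip_kg", "sppb", "walk_speed_mps")


@dataclass
class ValidityMatrix:
    """Pearson r / p / per-cell n frames (rows scores, columns measures)."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    flags: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: score, measure, r, p, n, flag."""
        rows = []
        for score in self.r.index:
            for measure in self.r.columns:
                rows.append({"score": score, "measure": measure,
                             "r": self.r.loc[score, measure],
                             "p": self.p.loc[score, measure],
                             "n": self.n.loc[score, measure],
                             "flag": self.flags.loc[score, measure]})
        return pd.DataFrame(rows)


def validity_matrix(
    scores: pd.DataFrame,
    cohort: CohortTable,
    measures: tuple[str, ...] = DEFAULT_MEASURES,
    method: str = "pearson",
) -> ValidityMatrix:
    """Correlate baseline scores (total + domains) with external measures.

    ``scores`` is the (participant_id, visit)-indexed frame from
    :func:`proval.scoring.score_cohort`.  Cells with fewer than 3 complete
    pairs or zero variance are flagged, not silently filled.  ``method`` is
    ``"pearson"`` (default) or ``"spearman"``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    base_scores = scores.xs("baseline", level="visit")
    base = cohort.baseline().set_index("participant_id")
    common = base_scores.index.intersection(base.index)
    base_scores = base_scores.loc[common]
    base = base.loc[common]

    score_cols = list(base_scores.columns)
    r = pd.DataFrame(index=score_cols, columns=list(measures), dtype=float)
    p = pd.DataFrame(index=score_cols, columns=list(measures), dtype=float)
    n = pd.DataFrame(index=score_cols, columns=list(measures), dtype=int)
    flags = pd.DataFrame(index=score_cols, columns=list(measures), dtype=object)

    for m in measures:
        mv = base[m].astype(float) if m in base.columns else pd.Series(np.nan, index=base.index)
        for sc in score_cols:
            sv = base_scores[sc].astype(float)
            mask = sv.notna() & mv.notna()
            n.loc[sc, m] = int(mask.sum())
            if mask.sum() < 3:
                r.loc[sc, m] = np.nan
                p.loc[sc, m] = np.nan
                flags.loc[sc, m] = "too_few_pairs"
                continue
            x, y = sv[mask], mv[mask]
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                r.loc[sc, m] = np.nan
                p.loc[sc, m] = np.nan
                flags.loc[sc, m] = "zero_variance"
                continue
            rr, pp = corr(x, y)
            r.loc[sc, m] = float(rr)
            p.loc[sc, m] = float(pp)
            flags.loc[sc, m] = None
    return ValidityMatrix(r=r, p=p, n=n, flags=flags)
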