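"""Scoring: raw item responses -> 0-100 domain scores -> 0-100 total score.

Each domain score is the weighted raw item sum linearly rescaled so that the
worst attainable response pattern maps to 0 and the best to 100.  The total
score is the domain-weight-weighted mean of the domain scores (the arithmetic
mean under equal weights).  A domain score is reported missing whenever its
item completeness falls below the configured threshold (default: strict, all
items required); optional prorated scoring renormalises over answered items.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ProvalError
from .io import CohortTable
from .schema import QuestionnaireSchema

logger = logging.getLogger(__name__)

TOTAL_COLUMN = "total"


def normalize_score(raw_sum: float, min_possible: float, max_possible: float) -> float:
    """Rescale a raw (weighted) sum onto 0-100: ``100*(raw-min)/(max-min)``."""
    if max_possible <= min_possible:
        raise ProvalError(
            f"degenerate raw range: min {min_possible} >= max {max_possible}"
        )
    return 100.0 * (raw_sum - min_possible) / (max_possible - min_possible)


@dataclass
class DomainScores:
    """Per participant-visit domain scores (0-100) and item completeness.

    ``scores`` and ``completeness`` share a (participant_id, visit) MultiIndex
    and one column per domain.
    """

    scores: pd.DataFrame
    completeness: pd.DataFrame
    schema: QuestionnaireSchema


def score_domains(
    cohort: CohortTable,
    schema: QuestionnaireSchema | None = None,
    completeness_threshold: float = 1.0,
    prorate: bool = False,
) -> DomainScores:
    """Score every domain for every participant-visit row.

    Parameters
    ----------
    completeness_threshold : fraction of a domain's items that must be
        answered for the score to be reported (1.0 = strict).
    prorate : if True, rescale using the attainable range of the *answered*
        items only (mean-imputation-free proration); if False, any missing
        item renders the domain score missing once below the threshold.
    """
    schema = schema or cohort.schema
    df = cohort.data
    idx = pd.MultiIndex.from_frame(df[["participant_id", "visit"]])
    scores = pd.DataFrame(index=idx, columns=list(schema.domain_names), dtype=float)
    compl = pd.DataFrame(index=idx, columns=list(schema.domain_names), dtype=float)

    for dom in schema.domains:
        present_cols = [c for c in dom.item_ids if c in df.columns]
        if not present_cols:
            logger.warning("domain %r: no item columns present in cohort", dom.name)
            compl[dom.name] = 0.0
            continue
        spec = {it.item_id: it for it in dom.items}
        resp = df[present_cols].astype(float)
        answered = resp.notna()
        frac = answered.sum(axis=1) / len(dom.items)
        compl[dom.name] = frac.to_numpy()

        w = np.array([spec[c].weight for c in present_cols])
        lo = np.array([spec[c].minimum for c in present_cols])
        hi = np.array([spec[c].maximum for c in present_cols])

        raw = (resp.to_numpy() * w).copy()
        mask = answered.to_numpy()
        raw_sum = np.where(mask, raw, 0.0).sum(axis=1)
        if prorate:
            min_possible = (np.where(mask, w * lo, 0.0)).sum(axis=1)
            max_possible = (np.where(mask, w * hi, 0.0)).sum(axis=1)
        else:
            min_possible = np.full(len(df), float((w * lo).sum()))
            max_possible = np.full(len(df), float((w * hi).sum()))

        ok = frac.to_numpy() >= completeness_threshold - 1e-12
        if not prorate:
            ok &= frac.to_numpy() >= 1.0 - 1e-12  # strict needs every item
        rng = max_possible - min_possible
        with np.errstate(invalid="ignore", divide="ignore"):
            val = 100.0 * (raw_sum - min_possible) / rng
        val = np.where(ok & (rng > 0), val, np.nan)
        n_dropped = int((~ok & (frac.to_numpy() > 0)).sum())
        if n_dropped:
            logger.info("domain %r: %d rows below completeness threshold", dom.name, n_dropped)
        scores[dom.name] = val

    return DomainScores(scores=scores, completeness=compl, schema=schema)


def score_total(
    domain_scores: DomainScores,
    schema: QuestionnaireSchema | None = None,
    require_complete: bool = True,
) -> pd.Series:
    """Domain-weight-weighted mean of the domain scores.

    With ``require_complete`` (default) the total is missing whenever any
    domain score is missing; otherwise the weighted mean is taken over
    available domains.
    """
    schema = schema or domain_scores.schema
    sc = domain_scores.scores[list(schema.domain_names)]
    w = np.array([d.weight for d in schema.domains], dtype=float)
    vals = sc.to_numpy(dtype=float)
    avail = ~np.isnan(vals)
    wsum = (np.where(avail, vals * w, 0.0)).sum(axis=1)
    wtot = (np.where(avail, w, 0.0)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        total = wsum / wtot
    if require_complete:
        total = np.where(avail.all(axis=1), total, np.nan)
    return pd.Series(total, index=sc.index, name=TOTAL_COLUMN)


def score_cohort(
    cohort: CohortTable,
    schema: QuestionnaireSchema | None = None,
    completeness_threshold: float = 1.0,
    prorate: bool = False,
    require_complete: bool = True,
) -> pd.DataFrame:
    """Convenience wrapper: domain scores plus total in one frame.

    Returns a DataFrame indexed by (participant_id, visit) with one column per
    domain and a ``total`` column.
    """
    ds = score_domains(cohort, schema, completeness_threshold, prorate)
    out = ds.scores.copy()
    out[TOTAL_COLUMN] = score_total(ds, schema, require_complete)
    return out
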