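"""Internal consistency (Cronbach's alpha) and subdomain-total correlations.

Cronbach's alpha over a cases x components matrix:

    alpha = k/(k-1) * (1 - sum_i var_i / var_total)

with sample (n-1 denominator) variances over listwise-complete cases — the
denominator convention is pinned because alpha is invariant to it only when
applied consistently.  Confidence intervals use the Feldt F-distribution
method: the interval is ``1 - (1-alpha) * F`` at the appropriate quantiles
with degrees of freedom (n-1) and (n-1)(k-1).

For a multi-domain instrument, alpha is computed at three analysis scopes
(baseline, all follow-up, telephone-only follow-up) for the total score and
for each domain.  Components default to domain scores for the total and
question scores within a domain; a domain with a single question is flagged
not-calculable rather than given a fake zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable
from .schema import QuestionnaireSchema
from .scoring import DomainScores, score_domains, score_total

logger = logging.getLogger(__name__)


@dataclass
class ReliabilityResult:
    """Cronbach's alpha with its Feldt confidence interval.

    ``flag`` is None when alpha is defined; otherwise one of
    ``single_component`` (k < 2, mirrors an 'n/a, only one question' table
    cell), ``zero_total_variance`` or ``insufficient_cases``.
    """

    alpha: float | None
    k: int
    n: int
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float = 0.95
    flag: str | None = None

    @property
    def defined(self) -> bool:
        return self.flag is None


def alpha_confidence_interval(alpha: float, n: int, k: int,
                              level: float = 0.95) -> tuple[float, float]:
    """Feldt interval: ``1 - (1-alpha)*F_q`` with df (n-1), (n-1)(k-1)."""
    if k < 2 or n < 3:
        raise ValueError("Feldt interval needs k >= 2 components and n >= 3 cases")
    df1, df2 = n - 1, (n - 1) * (k - 1)
    tail = (1.0 - level) / 2.0
    f_hi = stats.f.ppf(1.0 - tail, df1, df2)
    f_lo = stats.f.ppf(tail, df1, df2)
    return 1.0 - (1.0 - alpha) * f_hi, 1.0 - (1.0 - alpha) * f_lo


def cronbach_alpha(components, ci_level: float = 0.95) -> ReliabilityResult:
    """Cronbach's alpha for a cases x components matrix (listwise deletion)."""
    mat = np.asarray(pd.DataFrame(components), dtype=float)
    if mat.ndim != 2:
        raise ValueError("component matrix must be 2-dimensional")
    k = mat.shape[1]
    if k < 2:
        return ReliabilityResult(alpha=None, k=k, n=mat.shape[0],
                                 ci_level=ci_level, flag="single_component")
    complete = ~np.isnan(mat).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("cronbach_alpha: %d incomplete cases dropped listwise", n_dropped)
    mat = mat[complete]
    n = mat.shape[0]
    if n < 3:
        return ReliabilityResult(alpha=None, k=k, n=n, ci_level=ci_level,
                                 flag="insufficient_cases")
    item_vars = mat.var(axis=0, ddof=1)
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return ReliabilityResult(alpha=None, k=k, n=n, ci_level=ci_level,
                                 flag="zero_total_variance")
    alpha = k / (k - 1.0) * (1.0 - item_vars.sum() / total_var)
    lo, hi = alpha_confidence_interval(alpha, n, k, ci_level)
    return ReliabilityResult(alpha=float(alpha), k=k, n=n, ci_low=float(lo),
                             ci_high=float(hi), ci_level=ci_level)


def question_scores(cohort: CohortTable, schema: QuestionnaireSchema | None = None,
                    domain: str | None = None) -> pd.DataFrame:
    """Weighted item sums per question, indexed by (participant_id, visit)."""
    schema = schema or cohort.schema
    df = cohort.data
    idx = pd.MultiIndex.from_frame(df[["participant_id", "visit"]])
    domains = [schema.domain(domain)] if domain else list(schema.domains)
    out = {}
    for dom in domains:
        for qid in dom.question_ids:
            items = [it for it in dom.items if it.question_id == qid]
            cols = [it.item_id for it in items if it.item_id in df.columns]
            if not cols:
                continue
            w = np.array([it.weight for it in items if it.item_id in df.columns])
            vals = df[cols].astype(float).to_numpy() * w
            out[qid] = vals.sum(axis=1)  # NaN-propagating: any missing item -> NaN
    return pd.DataFrame(out, index=idx)


def reliability_table(
    cohort: CohortTable,
    schema: QuestionnaireSchema | None = None,
    total_components: str = "domains",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Alpha for the total score and each domain across three analysis scopes.

    Scopes: ``baseline``, ``followup`` (all modes) and ``telephone`` (telephone
    follow-up only).  ``total_components`` selects what the total-score alpha
    treats as components: ``"domains"`` (7 domain scores, the default) or
    ``"questions"`` (all question scores).
    """
    schema = schema or cohort.schema
    if total_components not in ("domains", "questions"):
        raise ValueError("total_components must be 'domains' or 'questions'")
    ds = score_domains(cohort, schema)
    qs = question_scores(cohort, schema)

    df = cohort.data
    scopes = {
        "baseline": (df["visit"] == "baseline").to_numpy(),
        "followup": (df["visit"] == "followup").to_numpy(),
        "telephone": ((df["visit"] == "followup")
                      & (df.get("followup_mode") == "telephone")).to_numpy(),
    }

    records = []
    for scope, mask in scopes.items():
        # total score alpha
        comp = ds.scores.iloc[mask] if total_components == "domains" else qs.iloc[mask]
        res = cronbach_alpha(comp, ci_level)
        records.append({"component": "total", "scope": scope, **_as_row(res)})
        # per-domain alpha over question scores
        for dom in schema.domains:
            cols = [q for q in dom.question_ids if q in qs.columns]
            res = cronbach_alpha(qs.iloc[mask][cols], ci_level) if cols else \
                ReliabilityResult(None, 0, 0, flag="single_component")
            records.append({"component": dom.name, "scope": scope, **_as_row(res)})
    return pd.DataFrame(records)


def _as_row(res: ReliabilityResult) -> dict:
    return {"alpha": res.alpha, "k": res.k, "n": res.n,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "flag": res.flag}


def subdomain_total_correlations(
    domain_scores: DomainScores | pd.DataFrame,
    total: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson r of each subdomain with (a) the total and (b) the unweighted
    mean of the remaining subdomains, with two-sided p-values.

    Rows with zero variance in either column are flagged instead of reported.
    """
    if isinstance(domain_scores, DomainScores):
        sc = domain_scores.scores
        if total is None:
            total = score_total(domain_scores)
    else:
        sc = domain_scores
        if total is None:
            total = sc.mean(axis=1)

    rows = []
    for name in sc.columns:
        x = sc[name].astype(float)
        others = sc.drop(columns=[name]).astype(float).mean(axis=1)
        row = {"subdomain": name}
        for label, y in (("with_total", total.astype(float)),
                         ("excluding_self", others)):
            mask = x.notna() & y.notna()
            xv, yv = x[mask], y[mask]
            if len(xv) < 3 or xv.std(ddof=1) == 0 or yv.std(ddof=1) == 0:
                row[f"r_{label}"] = np.nan
                row[f"p_{label}"] = np.nan
                row["flag"] = "degenerate"
            else:
                r, p = stats.pearsonr(xv, yv)
                row[f"r_{label}"] = float(r)
                row[f"p_{label}"] = float(p)
                row.setdefault("flag", None)
            row[f"n_{label}"] = int(mask.sum())
        rows.append(row)
    return pd.DataFrame(rows)
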