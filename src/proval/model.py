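"""Model/Results interface tying the validation pipeline together.

:class:`PsychometricValidation` is built from a cohort (and its questionnaire
schema); :meth:`~PsychometricValidation.fit` runs the full validation —
scoring, internal consistency, subdomain-total correlations, anchor-grouped
change, responsiveness, MCID and sample-size planning, concurrent validity —
and returns a :class:`ValidationResults` carrying every table plus a
``summary()`` report.

The baseline-follow-up correlations that drive the (1 - r^2) sample-size
adjustment are estimated from the data themselves (overridable via ``r_map``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anchors import baseline_followup_correlation, build_change_table, change_summary
from .descriptives import describe_cohort
from .io import CohortTable, load_cohort
from .reliability import reliability_table, subdomain_total_correlations
from .responsiveness import responsiveness_table
from .samplesize import sample_size_table
from .schema import QuestionnaireSchema, default_schema
from .scoring import score_cohort, score_domains
from .validity import ValidityMatrix, validity_matrix


class PsychometricValidation:
    """PRO validation model for a two-visit cohort.

    Parameters
    ----------
    cohort : validated :class:`~proval.io.CohortTable`
    schema : questionnaire schema; defaults to the cohort's own
    r_map : optional {"total": r, "sarcf": r} override for the sample-size
        adjustment; when absent the correlations are estimated from the data.
    completeness_threshold, prorate : scoring policy (see
        :func:`proval.scoring.score_domains`).
    """

    def __init__(self, cohort: CohortTable, schema: QuestionnaireSchema | None = None,
                 *, r_map: dict[str, float] | None = None,
                 completeness_threshold: float = 1.0, prorate: bool = False,
                 total_components: str = "domains"):
        self.cohort = cohort
        self.schema = schema or cohort.schema
        self.r_map = r_map
        self.completeness_threshold = completeness_threshold
        self.prorate = prorate
        self.total_components = total_components

    @classmethod
    def from_csv(cls, cohort_path: str | Path,
                 schema: QuestionnaireSchema | str | Path | None = None,
                 **kwargs) -> "PsychometricValidation":
        """Build the model from a cohort CSV and a schema (object, JSON path,
        or the bundled stand-in when omitted)."""
        if schema is None:
            schema = default_schema()
        elif not isinstance(schema, QuestionnaireSchema):
            schema = QuestionnaireSchema.from_json(schema)
        return cls(load_cohort(cohort_path, schema), schema, **kwargs)

    def fit(self) -> "ValidationResults":
        scores = score_cohort(self.cohort, self.schema,
                              self.completeness_threshold, self.prorate)
        ds = score_domains(self.cohort, self.schema,
                           self.completeness_threshold, self.prorate)
        base_scores = scores.xs("baseline", level="visit")

        reliability = reliability_table(self.cohort, self.schema,
                                        total_components=self.total_components)
        base_ds = ds.scores.xs("baseline", level="visit")
        subdomain = subdomain_total_correlations(
            base_ds, base_scores["total"])

        change = build_change_table(scores, self.cohort)

        r_map: dict[str, float] = {}
        corr_details: dict[str, tuple[float, float, int]] = {}
        for inst in ("total", "sarcf"):
            bcol, fcol = f"baseline_{inst}", f"followup_{inst}"
            if bcol in change.columns:
                try:
                    r, p, nn = baseline_followup_correlation(change[bcol], change[fcol])
                    corr_details[inst] = (r, p, nn)
                    r_map[inst] = r
                except ValueError:
                    r_map[inst] = 0.0
        if self.r_map:
            r_map.update(self.r_map)

        resp = responsiveness_table(change)
        sizes = sample_size_table(change, r_map)
        validity = validity_matrix(scores, self.cohort)
        descriptives = describe_cohort(self.cohort) \
            if "followup_mode" in self.cohort.data.columns else pd.DataFrame()

        return ValidationResults(
            model=self, scores=scores, reliability=reliability,
            subdomain_correlations=subdomain, change_table=change,
            change_summary_fitness=change_summary(change, "fitness"),
            change_summary_qol=change_summary(change, "qol"),
            responsiveness=resp, sample_size=sizes, validity=validity,
            baseline_followup=corr_details, r_map=r_map,
            descriptives=descriptives,
        )


@dataclass
class ValidationResults:
    """All outputs of a fitted :class:`PsychometricValidation`."""

    model: PsychometricValidation
    scores: pd.DataFrame
    reliability: pd.DataFrame
    subdomain_correlations: pd.DataFrame
    change_table: pd.DataFrame
    change_summary_fitness: pd.DataFrame
    change_summary_qol: pd.DataFrame
    responsiveness: pd.DataFrame
    sample_size: pd.DataFrame
    validity: ValidityMatrix
    baseline_followup: dict
    r_map: dict
    descriptives: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> str:
        """Human-readable report of the headline statistics."""
        lines = ["Psychometric validation summary",
                 "=" * 34]
        base = self.scores.xs("baseline", level="visit")["total"].dropna()
        fu = self.scores.xs("followup", level="visit")["total"].dropna()
        lines.append(f"Participants: {len(base)} baseline / {len(fu)} follow-up")
        lines.append(f"Baseline total score: {base.mean():.1f} (SD {base.std(ddof=1):.1f})")

        rel = self.reliability
        tot = rel[(rel["component"] == "total")]
        for _, row in tot.iterrows():
            if row["alpha"] is not None and np.isfinite(row["alpha"]):
                lines.append(
                    f"Cronbach's alpha, total score, {row['scope']}: "
                    f"{row['alpha']:.3f} (95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f}, "
                    f"n={row['n']})")
        for inst, (r, p, nn) in self.baseline_followup.items():
            lines.append(f"Baseline-follow-up r ({inst}): {r:.2f} (p={p:.3g}, n={nn})")

        lines.append("")
        lines.append("Responsiveness (|effect|; ^ = paradoxical direction):")
        for _, row in self.responsiveness.iterrows():
            g = "undefined" if row["guyatt"] is None or not np.isfinite(row["guyatt"]) \
                else f"{row['guyatt']:.2f}" + ("^" if row["guyatt_paradoxical"] else "")
            d = "undefined" if row["cohen_d"] is None or not np.isfinite(row["cohen_d"]) \
                else f"{row['cohen_d']:.2f}" + ("^" if row["cohen_d_paradoxical"] else "")
            lines.append(f"  {row['instrument']:>6} | {row['anchor_kind']:>7} | "
                         f"{row['category']:<16} d={d:<10} Guyatt={g}")

        lines.append("")
        lines.append("Trial sample sizes (total N, two-arm 1:1, alpha 0.05):")
        for _, row in self.sample_size.iterrows():
            if row.get("flag"):
                lines.append(f"  {row['instrument']:>6} | {row['anchor_kind']:>7} | "
                             f"{row['category']:<17} [{row['flag']}]")
                continue
            lines.append(
                f"  {row['instrument']:>6} | {row['anchor_kind']:>7} | "
                f"{row['category']:<17} MCID={row['mcid']:g} SD={row['sd']:g} "
                f"80%: {row['n_unadjusted_80']:.0f}/{row['n_adjusted_80']:.0f} "
                f"90%: {row['n_unadjusted_90']:.0f}/{row['n_adjusted_90']:.0f} "
                f"(unadj/adj, r={row['r_baseline_followup']:.2f})")
        return "\n".join(lines)

    def plot_change_by_anchor(self, anchor: str = "fitness", ax=None):
        """Mean change in total score (with SD bars) per anchor category."""
        import matplotlib.pyplot as plt

        summary = self.change_summary_fitness if anchor == "fitness" \
            else self.change_summary_qol
        row = summary[summary["variable"] == "change_total"].iloc[0]
        cats = [c for c in ("worse", "slightly worse", "about the same",
                            "slightly better", "better", "any improvement")
                if f"{c}|mean" in row.index]
        means = [row[f"{c}|mean"] for c in cats]
        sds = [row[f"{c}|sd"] for c in cats]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        ax.bar(range(len(cats)), means, yerr=sds, capsize=4, color="steelblue")
        ax.axhline(0, color="black", lw=0.8)
        ax.set_xticks(range(len(cats)))
        ax.set_xticklabels(cats, rotation=30, ha="right")
        ax.set_ylabel("Change in total score (follow-up - baseline)")
        ax.set_title(f"Change by global {anchor} anchor category")
        return ax
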