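# Methods

This note records the statistical conventions the package pins down, the
design decisions taken where the methodology is genuinely open, and what the
synthetic-data generator does and does not emulate.

## Scoring

A domain score is the weighted raw item sum rescaled linearly so the worst
attainable response pattern maps to 0 and the best to 100:
`100·(raw − min)/(max − min)`.  The total score is the domain-weight-weighted
mean of domain scores (arithmetic mean under equal weights).  Scores are
monotone in every item response and invariant to affine rescaling of the raw
item scale.

*Completeness.*  No published imputation rule exists for the instrument
family this targets, so the default is strict: a domain score is missing if
any item is missing, and the total is missing if any domain is missing.
`completeness_threshold` + `prorate=True` enable prorated scoring
(renormalising over answered items), which is unbiased only under
missing-completely-at-random items — the caller opts in.

*Stand-in schema.*  The bundled schema reproduces the *structure* of a
seven-domain, 22-question, 55-item instrument (single-question Fears domain,
raw range 1–4, equal weights) but none of the licensed content.  Published
weighting schemes, when available to a user, travel through the same schema
abstraction.

## Internal consistency

Cronbach's alpha uses sample variances (n−1 denominator) throughout.  Alpha
is invariant to the denominator convention only if it is applied to both the
component and total variances consistently, so the convention is pinned and
tested.  Cases are deleted listwise per component matrix; deletion counts are
logged.

Confidence intervals use the Feldt method: `1 − (1−α)·F` at the appropriate
F quantiles with degrees of freedom `(n−1)` and `(n−1)(k−1)`.  The method
assumes compound symmetry (essentially parallel components); simulated
coverage on exchangeable items is ~95% (checked at n=200, k=5, 1000
replicates).  The interval method is isolated in
`alpha_confidence_interval` and swappable.

The total-score alpha treats the domain scores as components by default,
with question-level components available (`total_components="questions"`).
The two scopes answer different questions (domain homogeneity vs item-bank
homogeneity) and can differ substantially: a total alpha near 0.95 over 22
questions corresponds to a mean inter-question correlation of ~0.43, which
is attainable even when two domains are internally heterogeneous, whereas
the 7-component domain-level alpha is bounded much lower in that case.
Single-component domains are flagged `single_component`, never scored 0.

## Anchors and change

The two 7-point global rating-of-change anchors (overall fitness, overall
quality of life) are amalgamated by merging "much worse" into "worse" and
"much better" into "better" — the extreme levels are rarely endorsed — and a
derived overlapping "any improvement" group (slightly better ∪ better ∪
much better) is carried separately, never double-counted in the
five-category partition.  Change is follow-up minus baseline for every
score; participants lacking an anchor are excluded from anchor-grouped
summaries only, with exclusion counts logged.

The baseline–follow-up Pearson correlation is computed per instrument and
drives the `(1−r²)` sample-size adjustment; it is deliberately distinct from
a test–retest ICC (no stability claim is made over a six-month interval).

## Responsiveness

Cohen's d (responsiveness form) divides |mean change| by the pooled SD of
baseline and follow-up scores `√((sd_b² + sd_f²)/2)` **within the anchor
subgroup** — chosen because d is reported per category; a whole-sample
variant is a one-argument change.  Guyatt's coefficient divides |mean
change| by the SD of change in the "about the same" group.  Magnitudes are
reported non-negative with a `paradoxical` flag raised when the observed
direction opposes the anchor's (taking each instrument's orientation into
account: lower SARC-F is better).  Undefined cells — empty groups, singleton
groups, zero denominators — are flagged, never silently dropped.

## MCID and sample size

The anchor-based MCID is |mean change| in the group reporting slight change,
rounded to a per-instrument precision: integers for 0–100 scores, one
decimal for SARC-F (0–10).  The unrounded mean is retained and reported
alongside.  The SD of change entering the sample-size formula is rounded at
the same precision, matching how such tables are published.

Per-arm `n = 2σ²(z₁₋α/₂ + z_power)²/δ²` with standard-normal quantiles (no
t-correction); the total (both arms) is ceiled to the nearest even integer;
the baseline adjustment multiplies the *rounded* total by `(1−r²)` and ceils
to even again.  This rounding pipeline is pinned because published tables of
this kind are not reproducible under any single alternative ordering; a
handful of published cells (notably extreme slight-worsening rows) remain
inconsistent with any rounding order and are not targeted.  Whether the MCID
enters as the rounded integer or the raw mean also varies between published
cells; the rounded value reproduces more of them and is the default.

`n` is strictly decreasing in δ, increasing in σ and power before rounding
(weakly after), invariant to common rescaling of δ and σ, and the
adjusted/unadjusted ratio converges to `(1−r²)` as n grows.

## Concurrent validity

Pearson correlations (Spearman behind a flag) between baseline scores and
external measures use pairwise-complete observations per cell, because the
measures differ in completeness; per-cell n is reported.  Signs are
preserved, not folded: a higher-is-better score should correlate negatively
with SARC-F.

## Synthetic cohort generator

The generator emulates a sarcopenia-registry cohort: n=147 at baseline,
SARC-F ≥ 3 eligibility at screening, ~15% dropout, telephone-dominated
follow-up (8/125 face-to-face), two global-change anchors with ~6% missing.

**Cross-sectional structure.**  A single latent function trait `z ~ N(0,1)`
drives everything: per-domain common factors `F_d = γz + √(1−γ²)u_d`
(default γ=0.75), equicorrelated items within domains
(`ρ_d` solved from per-domain alpha targets via Spearman–Brown), and
physical measures linked to `z` with loadings solved in closed form from
target Pearson correlations with the total score (−0.45 SARC-F, 0.37 grip,
0.48 SPPB, 0.48 walk speed).  Sex-specific grip/muscle-mass marginals are
handled by solving the loading against the pooled (between + within sex)
variance.  Infeasible targets (|loading| > 1) raise a config error naming
the offending target.

**Item scale.**  Item responses are continuous on the raw 1–4 scale by
default (integer discretisation available via a flag).  This is deliberate:
coarse 4-level discretisation attenuates Pearson correlations by far more
than the tolerances the recovery tests work to, so the continuous scale is
what makes "configured α, configured r" exact statements rather than
approximate ones.  Consequences for realism are noted under limitations.

**Longitudinal structure.**  Each completer draws a raw 7-level fitness
anchor (category probabilities matching the reference frequencies; the
unreported split of the merged extreme levels is fixed at a small share of
each end), and the QoL anchor equals the fitness anchor with probability 0.6
else redraws from its marginal.  Total-score change is injected per
amalgamated category as `c = μ_cat + β(b − b̄) + ε` where the
regression-to-the-mean slope β is solved in closed form so the marginal
baseline–follow-up correlation hits its target (0.27 for the total, 0.63
for SARC-F) given the pooled change variance implied by the category cells;
ε gets whatever variance leaves the category change SD at its configured
value.  Clipping at the score bounds [0,100] (and [0,10] for SARC-F) is
mean-compensated: the injected location is solved by Brent root-finding on
the truncated-normal expectation over the category's realised baselines, so
configured category mean changes stay exact in expectation despite the
bounds.  Category-specific per-domain offsets then spread the change across
domains (zero-sum noise, SD 8 score points), projected back into the
[0,100] box preserving the weighted mean, and finally each domain target is
realised at item level by a uniform shift plus small item noise (SD 0.12
raw units), box-projected preserving the weighted sum.

**What the generator does not emulate, and known attenuations.**
Realised domain SDs run ~10–20% below target for low-consistency domains
(boundary clipping of high-variance items); the realised SARC-F–total
correlation is ~10% weaker than its −0.45 target (eligibility truncation
plus integer rounding of SARC-F); the published baseline total alpha of
0.944 is not targeted at the default domain-component scope (see Internal
consistency above).  Anchor choice is independent of baseline severity;
there are no mode effects (telephone vs face-to-face is a label only), no
secular trends, no informative dropout, and change SDs are compressed
slightly in categories where clipping bites.  Passing recovery tests
therefore demonstrate correctness of the estimators under a clean latent
model — not robustness to the messiness of real registry data.

## Problem sizes and tolerances

Recovery tests use the sizes at which Monte-Carlo error is comfortably
below the assertion tolerances: alpha vs Spearman–Brown at n=2000 (±0.02),
baseline–follow-up r at n=5000 (±0.03), anchor-group mean changes at 4
standard errors, validity cells at ±0.05, Feldt coverage at 1000 replicates
of n=200.  Oracle-equivalence tests (alpha, Pearson r, per-arm n) run 120
random small instances against independently coded brute-force formulas,
plus pingouin (alpha + Feldt CI) and statsmodels `NormalIndPower` as
external cross-checks.  The acceptance script oversamples the
slight-improvement anchor category when measuring cell-mean recovery so the
cell holds ~1,300 participants instead of ~170; the change model itself is
untouched by that reweighting.

## Limitations

* The 7-point anchor wording and the amalgamation rule are fixed; other
  anchor designs (5-point, numeric rating) would need a schema extension.
* The MCID here is the anchor-group mean change; credibility intervals or
  ROC-based MCIDs are out of scope.
* No multiplicity correction is applied anywhere (matching the validation
  workflow this implements); interpret the correlation matrices accordingly.
* Two visits only; no support for repeated follow-ups or time-to-event
  outcomes.
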