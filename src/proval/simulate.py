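"""Synthetic longitudinal PRO cohorts with controlled psychometric structure.

The generator emulates a sarcopenia-registry-like cohort: ~147 participants
recruited on a SARC-F screening score of 3+, a baseline visit with item-level
questionnaire responses and physical-performance measures, ~15% dropout, and
a follow-up visit with repeat questionnaire, repeat SARC-F and two 7-point
global-change anchors.

Structure
---------
* A single latent "function" trait ``z ~ N(0,1)`` drives the baseline
  questionnaire (through per-domain common factors with loading ``gamma``)
  and the physical measures (loadings solved in closed form from the target
  Pearson correlations with the total score).
* Within a domain, items are equicorrelated with correlation ``rho``; the
  implied domain internal consistency follows the Spearman-Brown form
  ``alpha = k*rho / (1 + (k-1)*rho)``.
* Follow-up change is injected at the total-score level per anchor category
  (category-specific mean and SD), with a regression-to-the-mean slope solved
  from the target baseline-follow-up correlation, then distributed to domains
  and items by uniform shifts.  Clipping at the score bounds is
  mean-compensated (a truncated-normal expectation solved with brentq), so
  the configured anchor-group mean changes are exact in expectation.

Default parameters are the registry cohort's published summary statistics, so
``generate_cohort(default_config(), seed)`` -> full pipeline demonstrates the
whole validation workflow with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConfigError
from .io import ANCHOR_COLUMNS, CATEGORICAL_COLUMNS, KEY_COLUMNS, NUMERIC_COLUMNS, \
    CohortTable, empty_cohort
from .schema import ANCHOR_LEVELS, QuestionnaireSchema, default_schema

__all__ = ["SimConfig", "default_config", "generate_cohort", "generate_item_matrix",
           "rho_for_alpha"]


def rho_for_alpha(alpha: float, k: int) -> float:
    """Invert Spearman-Brown: inter-item correlation giving ``alpha`` at k items."""
    if k < 2:
        raise ValueError("need k >= 2 items")
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    return alpha / (k - (k - 1) * alpha)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: amalgamated anchor category -> (mean change, SD of change), total score
DEFAULT_TOTAL_CHANGE = {
    "worse": (-8.5, 15.9),
    "slightly worse": (-0.5, 16.0),
    "about the same": (-0.3, 12.3),
    "slightly better": (21.3, 19.0),
    "better": (14.4, 17.0),
}

#: same for SARC-F (lower = better, so improvement means negative change)
DEFAULT_SARCF_CHANGE = {
    "worse": (0.83, 1.49),
    "slightly worse": (0.28, 1.99),
    "about the same": (-0.07, 1.67),
    "slightly better": (-1.00, 2.12),
    "better": (-1.64, 1.69),
}

#: per-domain mean change by category (default stand-in schema domain names)
DEFAULT_DOMAIN_CHANGE_MEANS = {
    "physical_mental_health": {"worse": -6.2, "slightly worse": 2.4,
                               "about the same": 5.8, "slightly better": 32.7,
                               "better": 17.4},
    "locomotion": {"worse": -7.8, "slightly worse": -0.5, "about the same": -4.3,
                   "slightly better": 25.0, "better": 16.4},
    "body_composition": {"worse": -3.9, "slightly worse": 4.1,
                         "about the same": 12.4, "slightly better": 22.5,
                         "better": 14.0},
    "functionality": {"worse": -7.4, "slightly worse": -0.7, "about the same": -0.9,
                      "slightly better": 15.5, "better": 14.7},
    "activities_daily_living": {"worse": -11.9, "slightly worse": -0.9,
                                "about the same": -4.5, "slightly better": 20.5,
                                "better": 12.0},
    "leisure_activities": {"worse": -11.6, "slightly worse": 0.7,
                           "about the same": 6.9, "slightly better": 20.0,
                           "better": 12.1},
    "fears": {"worse": -6.7, "slightly worse": 3.5, "about the same": 4.9,
              "slightly better": 7.5, "better": 6.8},
}

DEFAULT_DOMAIN_MEANS = {
    "physical_mental_health": 55.5, "locomotion": 48.8, "body_composition": 58.4,
    "functionality": 52.6, "activities_daily_living": 46.1,
    "leisure_activities": 36.1, "fears": 67.5,
}
DEFAULT_DOMAIN_SDS = {
    "physical_mental_health": 15.6, "locomotion": 18.1, "body_composition": 17.2,
    "functionality": 12.8, "activities_daily_living": 14.9,
    "leisure_activities": 17.3, "fears": 19.1,
}
#: per-domain target internal consistency (item-level equicorrelation solved
#: from these via Spearman-Brown); single-item domains use a communality value.
DEFAULT_DOMAIN_ALPHAS = {
    "physical_mental_health": 0.76, "locomotion": 0.89, "body_composition": 0.17,
    "functionality": 0.87, "activities_daily_living": 0.88,
    "leisure_activities": 0.39, "fears": 0.15,
}

#: raw 7-level anchor probabilities (worst to best).  Amalgamated-category
#: frequencies follow the reference cohort (30/25/46/5/11 of 117 for fitness,
#: 26/15/63/3/10 for QoL); the unreported split of the merged extreme levels
#: is set to a small share of each end.
DEFAULT_FITNESS_PROBS = (6 / 117, 24 / 117, 25 / 117, 46 / 117, 5 / 117,
                         8 / 117, 3 / 117)
DEFAULT_QOL_PROBS = (5 / 117, 21 / 117, 15 / 117, 63 / 117, 3 / 117,
                     7 / 117, 3 / 117)


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort generator (defaults = registry-like).

    Correlation targets refer to the continuous latent construction; bounded
    scales (clipping, rounding, eligibility truncation) attenuate a few of
    the realised values slightly (see the methods note).
    """

    n_baseline: int = 147
    dropout_fraction: float = 22 / 147
    face_to_face_fraction: float = 8 / 125      # among completers
    anchor_missing_fraction: float = 8 / 125    # completers without anchors
    schema: QuestionnaireSchema = field(default_factory=default_schema)

    # cross-sectional structure
    domain_means: dict = field(default_factory=lambda: dict(DEFAULT_DOMAIN_MEANS))
    domain_sds: dict = field(default_factory=lambda: dict(DEFAULT_DOMAIN_SDS))
    domain_alphas: dict = field(default_factory=lambda: dict(DEFAULT_DOMAIN_ALPHAS))
    domain_factor_loading: float = 0.75   # gamma: domain factor on latent trait

    # external measures: target Pearson r with the baseline total score
    target_r: dict = field(default_factory=lambda: {
        "sarcf": -0.45, "grip_kg": 0.37, "sppb": 0.48, "walk_speed_mps": 0.48,
        "smi_kg_m2": 0.15,
    })
    sex_female_fraction: float = 72 / 147
    age_mean: float = 77.6
    age_sd: float = 7.3
    sarcf_mean: float = 5.28
    sarcf_sd: float = 1.82
    sarcf_threshold: int = 3              # eligibility: screening SARC-F >= 3
    sppb_mean: float = 5.5
    sppb_sd: float = 2.3
    walk_mean: float = 0.61
    walk_sd: float = 0.24
    grip_by_sex: dict = field(default_factory=lambda: {
        "male": (27.2, 9.4), "female": (15.7, 6.1)})
    smi_by_sex: dict = field(default_factory=lambda: {
        "male": (7.84, 1.21), "female": (6.65, 1.13)})
    chair_log_median: float = math.log(24.0)
    chair_log_sd: float = 0.35
    chair_r_log: float = -0.30            # with latent trait, log scale
    missing_fractions: dict = field(default_factory=lambda: {
        "walk_speed_mps": 5 / 147, "chair_stand_s": 41 / 147,
        "grip_kg": 8 / 147, "smi_kg_m2": 8 / 147,
    })

    # longitudinal structure
    fitness_probs: tuple = DEFAULT_FITNESS_PROBS
    qol_probs: tuple = DEFAULT_QOL_PROBS
    anchor_agreement: float = 0.6         # P(QoL anchor equals fitness anchor)
    total_change: dict = field(default_factory=lambda: dict(DEFAULT_TOTAL_CHANGE))
    sarcf_change: dict = field(default_factory=lambda: dict(DEFAULT_SARCF_CHANGE))
    domain_change_means: dict = field(
        default_factory=lambda: {d: dict(v) for d, v in DEFAULT_DOMAIN_CHANGE_MEANS.items()})
    r_baseline_followup_total: float = 0.27
    r_baseline_followup_sarcf: float = 0.63
    domain_change_noise_sd: float = 8.0
    followup_item_noise_sd: float = 0.12

    def validate(self) -> None:
        if self.n_baseline < 0:
            raise ConfigError("n_baseline must be >= 0")
        for name, p in (("dropout_fraction", self.dropout_fraction),
                        ("face_to_face_fraction", self.face_to_face_fraction),
                        ("anchor_missing_fraction", self.anchor_missing_fraction),
                        ("anchor_agreement", self.anchor_agreement),
                        ("sex_female_fraction", self.sex_female_fraction)):
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for probs, name in ((self.fitness_probs, "fitness_probs"),
                            (self.qol_probs, "qol_probs")):
            if len(probs) != 7 or any(p < 0 for p in probs):
                raise ConfigError(f"{name} must be 7 non-negative probabilities")
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ConfigError(f"{name} must sum to 1 (got {sum(probs):.6f})")
        for r_name, r in (("r_baseline_followup_total", self.r_baseline_followup_total),
                          ("r_baseline_followup_sarcf", self.r_baseline_followup_sarcf)):
            if not -1 < r < 1:
                raise ConfigError(f"{r_name} must be in (-1, 1)")
        if not 0 <= self.domain_factor_loading < 1:
            raise ConfigError("domain_factor_loading must be in [0, 1)")
        for d in self.schema.domain_names:
            a = self.domain_alphas.get(d, 0.5)
            if not 0 <= a < 1:
                raise ConfigError(f"domain_alphas[{d!r}] must be in [0, 1)")


def default_config(**overrides) -> SimConfig:
    """Registry-emulating default configuration; keyword overrides applied."""
    cfg = SimConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


# ---------------------------------------------------------------------------
# low-level building blocks
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_item_matrix(n: int, k: int, rho: float, seed=None,
                         item_min: float = 1.0, item_max: float = 4.0,
                         discretize: bool = False) -> np.ndarray:
    """Equicorrelated item responses on the raw item scale.

    Responses are continuous on [item_min, item_max] by default (six latent
    SDs span the range, so boundary clipping is negligible and the empirical
    mean inter-item correlation matches ``rho`` to sampling error); with
    ``discretize=True`` they are rounded to integers, which attenuates the
    inter-item correlation as real coarse Likert scales do.
    """
    if k < 2:
        raise ValueError("need k >= 2 items")
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    rng = _as_rng(seed)
    common = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, k))
    y = math.sqrt(rho) * common + math.sqrt(1.0 - rho) * noise
    mid = (item_min + item_max) / 2.0
    scale = (item_max - item_min) / 6.0
    x = np.clip(mid + scale * y, item_min, item_max)
    if discretize:
        x = np.clip(np.floor(x + 0.5), item_min, item_max)
    return x


def _clipped_normal_mean(mu: np.ndarray, sigma: float, lo: float, hi: float) -> np.ndarray:
    """E[clip(X, lo, hi)] for X ~ N(mu, sigma^2), vectorised over mu."""
    if sigma <= 0:
        return np.clip(mu, lo, hi)
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    cdf_a, cdf_b = stats.norm.cdf(a), stats.norm.cdf(b)
    pdf_a, pdf_b = stats.norm.pdf(a), stats.norm.pdf(b)
    return lo * cdf_a + hi * (1.0 - cdf_b) + mu * (cdf_b - cdf_a) \
        + sigma * (pdf_a - pdf_b)


def _compensated_shift(b: np.ndarray, centred: np.ndarray, sigma_eps: float,
                       mu_target: float, lo: float, hi: float) -> float:
    """Solve the location m so that mean E[clip(b + m + centred + eps)] - mean b
    equals ``mu_target`` despite clipping at [lo, hi]."""
    b_mean = float(b.mean())

    def gap(m: float) -> float:
        mu = b + m + centred
        return float(_clipped_normal_mean(mu, sigma_eps, lo, hi).mean()) - b_mean - mu_target

    span = (hi - lo)
    try:
        return float(optimize.brentq(gap, -2 * span, 2 * span, xtol=1e-10))
    except ValueError:
        # target unreachable within the bounds; fall back to uncompensated
        return mu_target


def _project_box_weighted(v: np.ndarray, w: np.ndarray, target: np.ndarray,
                          lo: float, hi: float, max_iter: int = 50) -> np.ndarray:
    """Project each row of ``v`` onto [lo, hi]^k while preserving the weighted
    mean ``target`` (which must itself lie in [lo, hi]).  Overflow past a bound
    is redistributed over unsaturated coordinates, weight-proportionally."""
    v = v.copy()
    w = np.asarray(w, dtype=float)
    w = w / w.sum()
    for _ in range(max_iter):
        v = np.clip(v, lo, hi)
        cur = v @ w
        diff = target - cur
        if np.all(np.abs(diff) < 1e-9):
            break
        up = diff > 0
        free = np.where(up[:, None], v < hi - 1e-12, v > lo + 1e-12)
        wfree = (free * w).sum(axis=1)
        wfree = np.where(wfree > 0, wfree, np.inf)
        v = v + free * (diff / wfree)[:, None] * np.ones_like(v)
    return np.clip(v, lo, hi)


def _solve_regression_slope(r: float, s2: float, t2: float, what: str) -> float:
    """Slope beta of change on baseline giving corr(baseline, follow-up) = r,
    when the marginal change variance is t2 and baseline variance is s2.

    From f = b + mu + beta*(b - bbar) + eps with Var(change) = t2:
    lam = 1 + beta solves lam^2 - 2 r^2 lam + r^2 - r^2 t2/s2 = 0.
    """
    disc = r ** 2 * (r ** 2 - 1.0 + t2 / s2)
    if disc < 0:
        raise ConfigError(
            f"infeasible correlation target for {what}: baseline-follow-up "
            f"r={r} requires change variance >= (1-r^2)*baseline variance "
            f"({(1 - r**2) * s2:.2f}), got {t2:.2f}")
    lam = r ** 2 + math.copysign(math.sqrt(disc), r)
    return lam - 1.0


def _pooled_change_var(cells: dict, probs: dict) -> float:
    ps = np.array([probs[c] for c in cells])
    ps = ps / ps.sum()
    mus = np.array([cells[c][0] for c in cells])
    sds = np.array([cells[c][1] for c in cells])
    mbar = float(ps @ mus)
    return float(ps @ (sds ** 2 + (mus - mbar) ** 2))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _domain_latent_stats(cfg: SimConfig) -> tuple[dict, float, float]:
    """Analytic corr(domain, z), corr(total, z) and SD(total) for the
    continuous latent construction."""
    schema = cfg.schema
    gamma = cfg.domain_factor_loading
    w = np.array([d.weight for d in schema.domains], dtype=float)
    w = w / w.sum()
    c, s = {}, {}
    for dom in schema.domains:
        k = len(dom.items)
        alpha = cfg.domain_alphas.get(dom.name, 0.5)
        rho = alpha if k == 1 else rho_for_alpha(alpha, k)
        iw = np.array([it.weight * (it.maximum - it.minimum) for it in dom.items])
        iw = iw / iw.sum()
        var_ybar = rho + (1.0 - rho) * float((iw ** 2).sum())
        c[dom.name] = math.sqrt(rho) * gamma / math.sqrt(var_ybar)
        s[dom.name] = cfg.domain_sds.get(dom.name, 15.0)
    sig = np.array([s[d.name] for d in schema.domains])
    cc = np.array([c[d.name] for d in schema.domains])
    cov_tz = float((w * sig * cc).sum())
    var_t = float((w ** 2 * sig ** 2 * (1 - cc ** 2)).sum() + cov_tz ** 2)
    return c, cov_tz / math.sqrt(var_t), math.sqrt(var_t)


def _measure_loading(cfg: SimConfig, target: float, corr_tz: float,
                     name: str, by_sex: dict | None = None) -> float:
    if by_sex is None:
        c = target / corr_tz
    else:
        p_f = cfg.sex_female_fraction
        mu_f, sd_f = by_sex["female"]
        mu_m, sd_m = by_sex["male"]
        sd_within = p_f * sd_f + (1 - p_f) * sd_m
        var_pooled = p_f * sd_f ** 2 + (1 - p_f) * sd_m ** 2 \
            + p_f * (1 - p_f) * (mu_f - mu_m) ** 2
        c = target * math.sqrt(var_pooled) / (corr_tz * sd_within)
    if abs(c) > 1:
        raise ConfigError(
            f"infeasible correlation target: target_r[{name!r}]={target} "
            f"needs loading {c:.2f} > 1 given corr(total, trait)={corr_tz:.2f}")
    return c


def _linked_normal(rng, z, c, mu, sd, n):
    return mu + sd * (c * z + math.sqrt(1 - c ** 2) * rng.standard_normal(n))


def _score_domains_from_items(items: np.ndarray, dom) -> np.ndarray:
    w = np.array([it.weight for it in dom.items])
    lo = np.array([it.minimum for it in dom.items])
    hi = np.array([it.maximum for it in dom.items])
    return 100.0 * ((items - lo) * w).sum(axis=1) / float((w * (hi - lo)).sum())


def generate_cohort(config: SimConfig | None = None, seed=None) -> CohortTable:
    """Draw a reproducible synthetic cohort satisfying all table invariants."""
    cfg = config or default_config()
    cfg.validate()
    rng = _as_rng(seed)
    schema = cfg.schema
    n = cfg.n_baseline
    if n == 0:
        return empty_cohort(schema)

    pid = np.array([f"P{i+1:04d}" for i in range(n)])
    z = rng.standard_normal(n)
    _, corr_tz, _ = _domain_latent_stats(cfg)

    # ---- baseline questionnaire items ------------------------------------
    base_items: dict[str, np.ndarray] = {}
    base_domain_scores = np.empty((n, len(schema.domains)))
    for j, dom in enumerate(schema.domains):
        k = len(dom.items)
        alpha = cfg.domain_alphas.get(dom.name, 0.5)
        rho = alpha if k == 1 else rho_for_alpha(alpha, k)
        gamma = cfg.domain_factor_loading
        factor = gamma * z + math.sqrt(1 - gamma ** 2) * rng.standard_normal(n)
        y = math.sqrt(rho) * factor[:, None] \
            + math.sqrt(1 - rho) * rng.standard_normal((n, k))
        iw = np.array([it.weight * (it.maximum - it.minimum) for it in dom.items])
        iw = iw / iw.sum()
        var_ybar = rho + (1 - rho) * float((iw ** 2).sum())
        mu_d = cfg.domain_means.get(dom.name, 50.0)
        sd_d = cfg.domain_sds.get(dom.name, 15.0)
        s_lat = sd_d / (100.0 * math.sqrt(var_ybar))
        for col, it in enumerate(dom.items):
            width = it.maximum - it.minimum
            x = it.minimum + width * (mu_d / 100.0 + s_lat * y[:, col])
            base_items[it.item_id] = np.clip(x, it.minimum, it.maximum)
        mat = np.column_stack([base_items[it.item_id] for it in dom.items])
        base_domain_scores[:, j] = _score_domains_from_items(mat, dom)

    dw = np.array([d.weight for d in schema.domains], dtype=float)
    dw = dw / dw.sum()
    base_total = base_domain_scores @ dw

    # ---- baseline clinical measures --------------------------------------
    sex = np.where(rng.random(n) < cfg.sex_female_fraction, "female", "male")
    age = cfg.age_mean + cfg.age_sd * rng.standard_normal(n)

    c_s = _measure_loading(cfg, cfg.target_r["sarcf"], corr_tz, "sarcf")
    loc_s = cfg.sarcf_mean + cfg.sarcf_sd * c_s * z
    scale_s = cfg.sarcf_sd * math.sqrt(1 - c_s ** 2)
    cut = cfg.sarcf_threshold - 0.5
    a = (cut - loc_s) / scale_s
    b = (10.49 - loc_s) / scale_s
    sarcf_lat = stats.truncnorm.rvs(a, b, loc=loc_s, scale=scale_s, random_state=rng)
    sarcf = np.clip(np.floor(sarcf_lat + 0.5), cfg.sarcf_threshold, 10).astype(int)

    c_sppb = _measure_loading(cfg, cfg.target_r["sppb"], corr_tz, "sppb")
    sppb = np.clip(np.floor(_linked_normal(rng, z, c_sppb, cfg.sppb_mean,
                                           cfg.sppb_sd, n) + 0.5), 0, 12).astype(int)

    c_walk = _measure_loading(cfg, cfg.target_r["walk_speed_mps"], corr_tz,
                              "walk_speed_mps")
    walk = np.clip(_linked_normal(rng, z, c_walk, cfg.walk_mean, cfg.walk_sd, n),
                   0.05, None)

    c_grip = _measure_loading(cfg, cfg.target_r["grip_kg"], corr_tz, "grip_kg",
                              by_sex=cfg.grip_by_sex)
    grip = np.empty(n)
    for s_label, (mu, sd) in cfg.grip_by_sex.items():
        m = sex == s_label
        grip[m] = _linked_normal(rng, z[m], c_grip, mu, sd, int(m.sum()))
    grip = np.clip(grip, 1.0, None)

    c_smi = _measure_loading(cfg, cfg.target_r["smi_kg_m2"], corr_tz, "smi_kg_m2",
                             by_sex=cfg.smi_by_sex)
    smi = np.empty(n)
    for s_label, (mu, sd) in cfg.smi_by_sex.items():
        m = sex == s_label
        smi[m] = _linked_normal(rng, z[m], c_smi, mu, sd, int(m.sum()))
    smi = np.clip(smi, 3.0, None)

    chair = np.exp(cfg.chair_log_median + cfg.chair_log_sd
                   * (cfg.chair_r_log * z
                      + math.sqrt(1 - cfg.chair_r_log ** 2) * rng.standard_normal(n)))

    measures = {"sarcf": sarcf.astype(float), "grip_kg": grip, "sppb": sppb.astype(float),
                "walk_speed_mps": walk, "chair_stand_s": chair, "smi_kg_m2": smi}
    for col, frac in cfg.missing_fractions.items():
        if col in measures and frac > 0:
            miss = rng.random(n) < frac
            measures[col] = np.where(miss, np.nan, measures[col])

    # ---- follow-up: dropout, anchors, injected change --------------------
    complete = rng.random(n) >= cfg.dropout_fraction
    idx_c = np.flatnonzero(complete)
    n_c = len(idx_c)
    mode = np.full(n, "none", dtype=object)
    mode[idx_c] = np.where(rng.random(n_c) < cfg.face_to_face_fraction,
                           "face_to_face", "telephone")

    fit_raw = rng.choice(7, size=n_c, p=np.asarray(cfg.fitness_probs))
    same = rng.random(n_c) < cfg.anchor_agreement
    qol_raw = np.where(same, fit_raw,
                       rng.choice(7, size=n_c, p=np.asarray(cfg.qol_probs)))
    from .anchors import amalgamate_anchor  # local import avoids cycle at load
    fit_cat = np.array([amalgamate_anchor(ANCHOR_LEVELS[i]).value for i in fit_raw])

    fu_total = np.full(n, np.nan)
    fu_sarcf = np.full(n, np.nan)
    fu_items: dict[str, np.ndarray] = {c: np.full(n, np.nan) for c in base_items}

    if n_c:
        b_tot = base_total[idx_c]
        s2 = float(b_tot.var(ddof=1)) if n_c > 1 else 1.0
        probs5 = _amalgamated_probs(cfg.fitness_probs)
        t2 = _pooled_change_var(cfg.total_change, probs5)
        beta = _solve_regression_slope(cfg.r_baseline_followup_total, s2, t2,
                                       "total score")
        b_sarc = sarcf[idx_c].astype(float)
        s2_s = float(b_sarc.var(ddof=1)) if n_c > 1 else 1.0
        t2_s = _pooled_change_var(cfg.sarcf_change, probs5)
        beta_s = _solve_regression_slope(cfg.r_baseline_followup_sarcf, s2_s, t2_s,
                                         "SARC-F")

        f_tot = np.empty(n_c)
        f_sarc = np.empty(n_c)
        for cat in cfg.total_change:
            m = fit_cat == cat
            if not m.any():
                continue
            mu_cat, sd_cat = cfg.total_change[cat]
            var_eps = sd_cat ** 2 - beta ** 2 * s2
            if var_eps < 0:
                raise ConfigError(
                    f"infeasible pair: total_change[{cat!r}] SD {sd_cat} too small "
                    f"for baseline-follow-up r {cfg.r_baseline_followup_total}")
            sig_eps = math.sqrt(var_eps)
            centred = beta * (b_tot[m] - b_tot.mean())
            shift = _compensated_shift(b_tot[m], centred, sig_eps, mu_cat, 0.0, 100.0)
            f_pre = b_tot[m] + shift + centred + sig_eps * rng.standard_normal(int(m.sum()))
            f_tot[m] = np.clip(f_pre, 0.0, 100.0)

            mu_s, sd_s = cfg.sarcf_change[cat]
            var_eps_s = sd_s ** 2 - beta_s ** 2 * s2_s
            if var_eps_s < 0:
                raise ConfigError(
                    f"infeasible pair: sarcf_change[{cat!r}] SD {sd_s} too small "
                    f"for baseline-follow-up r {cfg.r_baseline_followup_sarcf}")
            sig_eps_s = math.sqrt(var_eps_s)
            centred_s = beta_s * (b_sarc[m] - b_sarc.mean())
            shift_s = _compensated_shift(b_sarc[m], centred_s, sig_eps_s, mu_s, 0.0, 10.0)
            f_pre_s = b_sarc[m] + shift_s + centred_s \
                + sig_eps_s * rng.standard_normal(int(m.sum()))
            f_sarc[m] = np.clip(f_pre_s, 0.0, 10.0)

        change = f_tot - b_tot
        # distribute change to domains: category-specific offsets + noise,
        # recentred so the weighted domain mean stays exactly the new total
        offsets = np.zeros((n_c, len(schema.domains)))
        for j, dom in enumerate(schema.domains):
            per_cat = cfg.domain_change_means.get(dom.name)
            if per_cat:
                for cat in cfg.total_change:
                    m = fit_cat == cat
                    offsets[m, j] = per_cat.get(cat, cfg.total_change[cat][0]) \
                        - cfg.total_change[cat][0]
        noise = cfg.domain_change_noise_sd * rng.standard_normal(offsets.shape)
        dev = offsets + noise
        dev = dev - (dev @ dw)[:, None]
        v = base_domain_scores[idx_c] + change[:, None] + dev
        v = _project_box_weighted(v, dw, f_tot, 0.0, 100.0)

        # back-propagate each domain target to its items by a uniform shift
        for j, dom in enumerate(schema.domains):
            w_it = np.array([it.weight for it in dom.items])
            lo = np.array([it.minimum for it in dom.items])
            hi = np.array([it.maximum for it in dom.items])
            span = float((w_it * (hi - lo)).sum())
            target_sum = v[:, j] / 100.0 * span + float((w_it * lo).sum())
            x0 = np.column_stack([base_items[it.item_id][idx_c] for it in dom.items])
            x0 = x0 + cfg.followup_item_noise_sd * rng.standard_normal(x0.shape)
            cur = (x0 * w_it).sum(axis=1)
            x0 = x0 + ((target_sum - cur) / w_it.sum())[:, None]
            # box-project on the weighted mean scale, then rescale back
            tgt_mean = target_sum / w_it.sum()
            x = _project_box_weighted(x0, w_it, tgt_mean, float(lo.min()), float(hi.max()))
            if not (np.allclose(lo, lo[0]) and np.allclose(hi, hi[0])):
                x = np.clip(x, lo, hi)  # heterogeneous ranges: best effort
            for col, it in enumerate(dom.items):
                fu_items[it.item_id][idx_c] = x[:, col]

        fu_total[idx_c] = f_tot
        fu_sarcf[idx_c] = np.clip(np.floor(f_sarc + 0.5), 0, 10)

    # ---- assemble the two-visit table ------------------------------------
    rows = {"participant_id": pid, "visit": np.full(n, "baseline", dtype=object)}
    rows.update({k: v for k, v in base_items.items()})
    rows.update({"anchor_fitness": np.full(n, np.nan, dtype=object),
                 "anchor_qol": np.full(n, np.nan, dtype=object)})
    rows.update(measures)
    rows.update({"age_years": age, "sex": sex, "followup_mode": mode})
    base_df = pd.DataFrame(rows)

    if n_c:
        anchor_missing = rng.random(n_c) < cfg.anchor_missing_fraction
        fit_labels = np.array([ANCHOR_LEVELS[i] for i in fit_raw], dtype=object)
        qol_labels = np.array([ANCHOR_LEVELS[i] for i in qol_raw], dtype=object)
        fit_labels[anchor_missing] = np.nan
        qol_labels[anchor_missing] = np.nan
        fu_rows = {"participant_id": pid[idx_c],
                   "visit": np.full(n_c, "followup", dtype=object)}
        fu_rows.update({k: fu_items[k][idx_c] for k in base_items})
        fu_rows["anchor_fitness"] = fit_labels
        fu_rows["anchor_qol"] = qol_labels
        fu_rows["sarcf"] = fu_sarcf[idx_c]
        for col in ("grip_kg", "sppb", "walk_speed_mps", "chair_stand_s", "smi_kg_m2"):
            fu_rows[col] = np.full(n_c, np.nan)
        fu_rows["age_years"] = age[idx_c] + 0.5
        fu_rows["sex"] = sex[idx_c]
        fu_rows["followup_mode"] = mode[idx_c]
        df = pd.concat([base_df, pd.DataFrame(fu_rows)], ignore_index=True)
    else:
        df = base_df

    return CohortTable(df, schema)


def _amalgamated_probs(raw_probs) -> dict:
    p = np.asarray(raw_probs, dtype=float)
    return {
        "worse": p[0] + p[1],
        "slightly worse": p[2],
        "about the same": p[3],
        "slightly better": p[4],
        "better": p[5] + p[6],
    }
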