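"""Synthetic two-arm lung-cancer screening trials.

The generator emulates the structure of large CT-screening trials: harmonized
baseline risk factors, blocked stratified randomization, a 7-10 year
equalized follow-up window, four histology groups whose mixture depends on
covariates, and histology-specific screening effects realized as a
late-to-early stage shift.

Mechanism
---------
Each participant draws covariates, then (independently of arm) a latent
lung-cancer event within the follow-up window from a logistic baseline-risk
model.  Cases draw a latent histology from a covariate-dependent multinomial
in which prolonged smoking cessation, fewer pack-years and female sex raise
the adenocarcinoma share and lower the small-cell share.  Stage (early/late)
is drawn per histology; in the CT arm a per-histology fraction of late-stage
incidence is shifted to early stage, and death follows stage-conditional case
fatality.  The per-histology *relative mortality reduction* requested in the
config is therefore the derived net effect of the stage shift; the implied
shift fraction is solved in closed form.  Because the mixture ties histology
to covariates while the screening effect is purely histology-specific, overall
screening effectiveness inherits covariate heterogeneity *emergently* -- the
key mechanism the downstream analyses are designed to detect.

Counterfactual outcomes under both arms are drawn with shared uniforms
(monotone coupling) and returned in a :class:`GroundTruth` sidecar together
with analytic per-record death probabilities under each arm, enabling
parameter-recovery tests against the exact simulated estimand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import COLUMN_ORDER, HISTOLOGY_GROUPS, Cohort

OUTCOME_COLUMNS = frozenset({
    "id", "arm", "followup_years", "lc_diagnosis", "lc_diagnosis_time",
    "histology", "stage_group", "detection_mode", "lc_death", "lc_death_time",
})


@dataclass
class MissingSpec:
    """Missingness for one covariate.

    ``mechanism`` is ``"MCAR"`` (blank uniformly at ``rate``) or ``"MAR"``
    (rate depends on a fully observed conditioning variable ``by`` through
    the per-level ``rate_by`` mapping; levels absent from the mapping fall
    back to ``rate``).
    """

    rate: float
    mechanism: str = "MCAR"
    by: str | None = None
    rate_by: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        rates = [self.rate] + list((self.rate_by or {}).values())
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError(f"missingness rates must lie in [0, 1]: {rates}")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "MAR" and self.by is None:
            raise ValueError("MAR missingness requires a conditioning variable")


@dataclass
class SimulationConfig:
    """Parameters of one simulated trial arm-pair.

    Model coefficients (``baseline_lc_risk`` and the per-class
    ``histology_mixture`` logits, reference class ADN) are expressed on the
    feature basis of :func:`model_features`.  ``screening_effect`` maps each
    histology to its target relative reduction in lung-cancer death within
    the follow-up window (negative = harm), realized through the stage shift.
    """

    n_per_arm: int = 10_000
    trial_style: str = "nelson"
    trial_label: str = "SYNTH"
    followup_cap: float = 10.0
    seed: int = 12345
    covariate_params: dict = field(default_factory=dict)
    histology_mixture: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_lc_risk: dict[str, float] = field(default_factory=dict)
    stage_late_prob: dict[str, float] = field(default_factory=dict)
    case_fatality: dict[str, tuple[float, float]] = field(default_factory=dict)
    screening_effect: dict[str, float] = field(default_factory=dict)
    screen_detection_prob: dict[str, float] = field(
        default_factory=lambda: {"CT": 0.65, "control": 0.0})
    nos_fraction: float = 0.05
    missingness: dict[str, MissingSpec] = field(default_factory=dict)
    n_centers: int = 4
    block_lengths: tuple[int, ...] = (6, 8)

    def validate(self) -> None:
        probs = ([self.nos_fraction]
                 + list(self.stage_late_prob.values())
                 + [p for pair in self.case_fatality.values() for p in pair]
                 + list(self.screen_detection_prob.values()))
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for h, r in self.screening_effect.items():
            if not -1.0 < r < 1.0:
                raise ValueError(
                    f"screening_effect[{h}] must lie in (-1, 1), got {r}")
        for coefs in self.histology_mixture.values():
            if any(not np.isfinite(v) for v in coefs.values()):
                raise ValueError("histology mixture logits must be finite")
        for h in HISTOLOGY_GROUPS:
            self.stage_shift(h)  # raises if infeasible

    def stage_shift(self, histology: str) -> float:
        """Late-to-early incidence shift fraction implied by the target
        mortality reduction for one histology (closed form).

        With control late-stage probability ``p``, early/late case fatality
        ``(fe, fl)`` and target reduction ``r``, the CT-arm late probability
        is ``p * (1 - s)`` where ``s = r * D / (p * (fl - fe))`` and
        ``D = (1-p) fe + p fl`` is the control-arm mean case fatality.
        """
        p = self.stage_late_prob[histology]
        fe, fl = self.case_fatality[histology]
        r = self.screening_effect.get(histology, 0.0)
        if fl <= fe:
            raise ValueError(f"{histology}: late-stage fatality must exceed early")
        mean_cf = (1.0 - p) * fe + p * fl
        s = r * mean_cf / (p * (fl - fe)) if p > 0 else 0.0
        if p * (1.0 - s) > 1.0 or s > 1.0:
            raise ValueError(
                f"{histology}: target effect {r} infeasible for the configured "
                f"stage distribution/case fatality (shift {s:.3f})")
        return s


@dataclass
class GroundTruth:
    """Latent per-record state plus the analytic estimands implied by the config.

    ``frame`` columns: latent histology / stage / death under both arms
    (coupled counterfactuals) and the analytic per-record death probabilities
    ``p_death_control`` / ``p_death_ct`` (marginal over histology and stage).
    """

    frame: pd.DataFrame
    config: SimulationConfig

    @property
    def true_overall_relative_effectiveness(self) -> float:
        """1 - sum(E[y_CT]) / sum(E[y_control]) over the realized covariates."""
        f = self.frame
        return 1.0 - f["p_death_ct"].sum() / f["p_death_control"].sum()

    def true_relative_effectiveness(self, mask: np.ndarray | pd.Series | None = None) -> float:
        f = self.frame if mask is None else self.frame[np.asarray(mask)]
        return 1.0 - f["p_death_ct"].sum() / f["p_death_control"].sum()

    @property
    def true_histology_effects(self) -> dict[str, float]:
        return dict(self.config.screening_effect)


# ---------------------------------------------------------------------------
# default configurations
# ---------------------------------------------------------------------------

def _base_mixture() -> dict[str, dict[str, float]]:
    # reference class ADN; gradients place adenocarcinoma in women, former
    # smokers and light pack-year histories, small-cell in heavy current
    # smokers (Fig-3-style pattern)
    return {
        "ADN": {},
        "SQM": {"1": -2.15, "z_py": 1.00, "current": 0.80, "male": 1.30,
                "z_yq": -0.70},
        "OTH": {"1": -1.30, "z_py": -0.20},
        "SCLC": {"1": -2.05, "z_py": 1.10, "current": 1.00, "male": 0.50,
                 "z_yq": -1.00},
    }


def nelson_like_config(n_per_arm: int = 7_500, seed: int = 12345,
                       **overrides) -> SimulationConfig:
    """NELSON-like defaults: 84% male, median age 58, 10-year window,
    unscreened control arm, favourable squamous-cell screening effect."""
    cfg = SimulationConfig(
        n_per_arm=n_per_arm,
        trial_style="nelson",
        trial_label="SYNTH-NELSON",
        followup_cap=10.0,
        seed=seed,
        covariate_params={
            "male_prop": 0.84, "age_mean": 58.0, "age_sd": 5.0,
            "age_range": (50.0, 75.0), "current_prop": 0.55,
            "years_quit_max": 10.0, "cigs_mean": 20.0, "cigs_sd": 6.0,
            "cigs_range": (10.0, 60.0), "years_smoked_mean": 37.0,
            "years_smoked_sd": 6.0, "years_smoked_range": (25.0, 55.0),
            "bmi_mean": 26.0, "bmi_sd": 4.0, "bmi_range": (16.0, 45.0),
            "copd_prop": 0.12, "emphysema_prop": 0.10,
            "personal_cancer_prop": 0.05, "family_lc_prop": 0.12,
            "education_levels": 6,
            "race_probs": {"white": 0.97, "black": 0.01, "hispanic": 0.01,
                           "asian": 0.01},
        },
        histology_mixture=_base_mixture(),
        baseline_lc_risk={"1": -3.20, "z_age": 0.30, "male": 0.05,
                          "current": 0.35, "z_py": 0.50, "z_yq": -0.15,
                          "copd": 0.35},
        stage_late_prob={"ADN": 0.60, "SQM": 0.70, "OTH": 0.65, "SCLC": 0.85},
        case_fatality={"ADN": (0.25, 0.80), "SQM": (0.20, 0.80),
                       "OTH": (0.30, 0.80), "SCLC": (0.55, 0.85)},
        screening_effect={"ADN": 0.20, "SQM": 0.50, "OTH": 0.30, "SCLC": 0.10},
        screen_detection_prob={"CT": 0.65, "control": 0.0},
        nos_fraction=0.05,
        missingness={
            "bmi": MissingSpec(0.045),
            "copd": MissingSpec(0.35),
            "emphysema": MissingSpec(0.35),
        },
    )
    return replace(cfg, **overrides)


def nlst_like_config(n_per_arm: int = 26_500, seed: int = 12345,
                     **overrides) -> SimulationConfig:
    """NLST-like defaults: 59% male, median age 60, heavier smoking
    histories (>=30 pack-years), 7-year window, radiography control arm
    (squamous-cell screening effect adverse)."""
    cfg = SimulationConfig(
        n_per_arm=n_per_arm,
        trial_style="nlst",
        trial_label="SYNTH-NLST",
        followup_cap=7.0,
        seed=seed,
        covariate_params={
            "male_prop": 0.59, "age_mean": 60.5, "age_sd": 5.0,
            "age_range": (55.0, 75.0), "current_prop": 0.48,
            "years_quit_max": 15.0, "cigs_mean": 24.0, "cigs_sd": 9.0,
            "cigs_range": (10.0, 80.0), "years_smoked_mean": 36.0,
            "years_smoked_sd": 7.0, "years_smoked_range": (25.0, 55.0),
            "bmi_mean": 27.5, "bmi_sd": 4.5, "bmi_range": (16.0, 50.0),
            "copd_prop": 0.18, "emphysema_prop": 0.12,
            "personal_cancer_prop": 0.04, "family_lc_prop": 0.21,
            "education_levels": 6,
            "race_probs": {"white": 0.90, "black": 0.045, "hispanic": 0.02,
                           "asian": 0.02},
        },
        histology_mixture=_base_mixture(),
        baseline_lc_risk={"1": -3.80, "z_age": 0.30, "male": 0.05,
                          "current": 0.35, "z_py": 0.50, "z_yq": -0.15,
                          "copd": 0.35},
        stage_late_prob={"ADN": 0.60, "SQM": 0.70, "OTH": 0.65, "SCLC": 0.85},
        case_fatality={"ADN": (0.25, 0.80), "SQM": (0.20, 0.80),
                       "OTH": (0.30, 0.80), "SCLC": (0.55, 0.85)},
        screening_effect={"ADN": 0.23, "SQM": -0.28, "OTH": 0.35, "SCLC": 0.11},
        screen_detection_prob={"CT": 0.65, "control": 0.25},
        nos_fraction=0.05,
        missingness={
            "bmi": MissingSpec(0.01),
            "copd": MissingSpec(0.01),
            "emphysema": MissingSpec(0.01),
            "family_lc_history": MissingSpec(0.02),
            "race_ethnicity": MissingSpec(0.02),
        },
    )
    return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# feature basis shared by the risk and mixture models
# ---------------------------------------------------------------------------

def model_features(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Feature basis the generator's coefficient dictionaries refer to.

    Centering/scaling constants are fixed package conventions (age about 60,
    pack-years about 40) so that intercepts are interpretable as
    reference-profile logits.
    """
    n = len(df)
    return {
        "1": np.ones(n),
        "z_age": (df["age"].to_numpy(float) - 60.0) / 5.0,
        "male": (df["sex"] == "male").to_numpy(float),
        "female": (df["sex"] == "female").to_numpy(float),
        "current": (df["smoking_status"] == "current").to_numpy(float),
        "z_py": (df["pack_years"].to_numpy(float) - 40.0) / 20.0,
        "z_yq": df["years_quit"].to_numpy(float) / 10.0,
        "copd": df["copd"].to_numpy(float) if df["copd"].notna().all()
        else df["copd"].fillna(False).to_numpy(float),
        "bmi_c": (df["bmi"].to_numpy(float) - 27.0) / 5.0,
    }


def _linear_predictor(features: Mapping[str, np.ndarray],
                      coefs: Mapping[str, float], n: int) -> np.ndarray:
    lp = np.zeros(n)
    for term, beta in coefs.items():
        lp += beta * features[term]
    return lp


def mixture_probabilities(df: pd.DataFrame,
                          mixture: Mapping[str, Mapping[str, float]]) -> np.ndarray:
    """Per-record multinomial histology probabilities, columns ordered as
    :data:`HISTOLOGY_GROUPS`."""
    feats = model_features(df)
    logits = np.column_stack([
        _linear_predictor(feats, mixture.get(h, {}), len(df))
        for h in HISTOLOGY_GROUPS
    ])
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------

def blocked_randomization(strata: np.ndarray, rng: np.random.Generator,
                          block_lengths: tuple[int, ...] = (6, 8)) -> np.ndarray:
    """Blocked randomization stratified by ``strata``.

    Within each stratum, participants are assigned in consecutive blocks of
    randomly chosen even length; each block contains equal numbers of both
    arms in random order.  Returns an arm array aligned with ``strata``.
    """
    arms = np.empty(len(strata), dtype=object)
    order = np.argsort(strata, kind="stable")
    sorted_strata = strata[order]
    boundaries = np.flatnonzero(
        np.r_[True, sorted_strata[1:] != sorted_strata[:-1], True])
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        members = order[lo:hi]
        pos = 0
        while pos < len(members):
            blen = int(rng.choice(block_lengths))
            block = np.array(["CT", "control"] * (blen // 2), dtype=object)
            rng.shuffle(block)
            take = min(blen, len(members) - pos)
            arms[members[pos:pos + take]] = block[:take]
            pos += take
    return arms


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, n, mean, sd, lo, hi):
    x = rng.normal(mean, sd, size=n)
    return np.clip(x, lo, hi)


def _draw_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    p = cfg.covariate_params
    n = 2 * cfg.n_per_arm
    sex = np.where(rng.random(n) < p["male_prop"], "male", "female").astype(object)
    age = _truncated_normal(rng, n, p["age_mean"], p["age_sd"], *p["age_range"])
    current = rng.random(n) < p["current_prop"]
    years_quit = np.where(
        current, 0.0, rng.uniform(0.5, p["years_quit_max"], size=n))
    cigs = _truncated_normal(rng, n, p["cigs_mean"], p["cigs_sd"], *p["cigs_range"])
    years_smoked = _truncated_normal(
        rng, n, p["years_smoked_mean"], p["years_smoked_sd"],
        *p["years_smoked_range"])
    pack_years = cigs * years_smoked / 20.0
    bmi = _truncated_normal(rng, n, p["bmi_mean"], p["bmi_sd"], *p["bmi_range"])
    race_levels = np.array(list(p["race_probs"]) + ["other"], dtype=object)
    race_p = np.array(list(p["race_probs"].values()))
    race_p = np.append(race_p, max(0.0, 1.0 - race_p.sum()))
    race = race_levels[rng.choice(len(race_levels), size=n,
                                  p=race_p / race_p.sum())]
    ids = np.char.add(f"{cfg.trial_label}-",
                      np.char.zfill(np.arange(n).astype(str), 7)).astype(object)
    centers = np.array([f"C{k + 1}" for k in range(cfg.n_centers)],
                       dtype=object)
    df = pd.DataFrame({
        "id": ids,
        "trial": cfg.trial_label,
        "center": centers[rng.integers(cfg.n_centers, size=n)],
        "age": np.round(age, 1),
        "sex": sex,
        "race_ethnicity": race,
        "education": rng.integers(1, p["education_levels"] + 1, size=n).astype(float),
        "bmi": np.round(bmi, 1),
        "smoking_status": np.where(current, "current", "former").astype(object),
        "cigs_per_day": np.round(cigs, 1),
        "years_smoked": np.round(years_smoked, 1),
        "years_quit": np.round(years_quit, 1),
        "copd": rng.random(n) < p["copd_prop"],
        "emphysema": rng.random(n) < p["emphysema_prop"],
        "personal_cancer_history": rng.random(n) < p["personal_cancer_prop"],
        "family_lc_history": rng.random(n) < p["family_lc_prop"],
    })
    df["pack_years"] = np.round(df["cigs_per_day"] * df["years_smoked"] / 20.0, 2)
    return df


def simulate_cohort(cfg: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Generate one two-arm trial cohort plus its ground truth.

    Deterministic given ``cfg.seed``.  Arm assignment uses blocked
    randomization stratified by 5-year age group, sex and screening center.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    df = _draw_covariates(cfg, rng)
    n = len(df)
    cap = cfg.followup_cap

    age_group = (df["age"] // 5).astype(int).astype(str)
    strata = (age_group + "|" + df["sex"] + "|" + df["center"]).to_numpy()
    df["arm"] = blocked_randomization(strata, rng, cfg.block_lengths)
    ct = (df["arm"] == "CT").to_numpy()

    feats = model_features(df)
    p_lc = 1.0 / (1.0 + np.exp(-_linear_predictor(feats, cfg.baseline_lc_risk, n)))
    lc = rng.random(n) < p_lc

    p_hist = mixture_probabilities(df, cfg.histology_mixture)
    u_hist = rng.random(n)
    hist_idx = (u_hist[:, None] > np.cumsum(p_hist, axis=1)).sum(axis=1)
    hist_idx = np.minimum(hist_idx, len(HISTOLOGY_GROUPS) - 1)
    histology = np.asarray(HISTOLOGY_GROUPS, dtype=object)[hist_idx]

    late0 = np.array([cfg.stage_late_prob[h] for h in HISTOLOGY_GROUPS])[hist_idx]
    shift = np.array([cfg.stage_shift(h) for h in HISTOLOGY_GROUPS])[hist_idx]
    late1 = np.clip(late0 * (1.0 - shift), 0.0, 1.0)
    u_stage = rng.random(n)
    stage0 = np.where(u_stage < late0, "late", "early").astype(object)
    stage1 = np.where(u_stage < late1, "late", "early").astype(object)

    fe = np.array([cfg.case_fatality[h][0] for h in HISTOLOGY_GROUPS])[hist_idx]
    fl = np.array([cfg.case_fatality[h][1] for h in HISTOLOGY_GROUPS])[hist_idx]
    u_death = rng.random(n)
    y0 = lc & (u_death < np.where(stage0 == "late", fl, fe))
    y1 = lc & (u_death < np.where(stage1 == "late", fl, fe))

    # analytic per-record death probabilities under each arm: marginalize
    # histology (mixture row) and stage within histology
    p_death0 = np.zeros(n)
    p_death1 = np.zeros(n)
    for j, h in enumerate(HISTOLOGY_GROUPS):
        p = cfg.stage_late_prob[h]
        s = cfg.stage_shift(h)
        fe_h, fl_h = cfg.case_fatality[h]
        d0 = (1.0 - p) * fe_h + p * fl_h
        p1 = p * (1.0 - s)
        d1 = (1.0 - p1) * fe_h + p1 * fl_h
        p_death0 += p_hist[:, j] * d0
        p_death1 += p_hist[:, j] * d1
    p_death0 *= p_lc
    p_death1 *= p_lc

    # observed outcome = counterfactual of the assigned arm
    death = np.where(ct, y1, y0)
    stage = np.where(ct, stage1, stage0)
    t_dx = rng.uniform(0.3, cap - 0.3, size=n)
    u_t = rng.random(n)
    t_death = t_dx + u_t * (cap - t_dx)

    obs_hist = histology.copy()
    nsclc = lc & np.isin(histology, ("ADN", "SQM", "OTH"))
    nos = nsclc & (rng.random(n) < cfg.nos_fraction)
    obs_hist[nos] = "NOS"

    det_p = np.where(ct, cfg.screen_detection_prob["CT"],
                     cfg.screen_detection_prob["control"])
    screen_det = rng.random(n) < det_p

    df["followup_years"] = np.where(lc & death, np.round(t_death, 3), cap)
    df["lc_diagnosis"] = lc
    df["lc_diagnosis_time"] = np.where(lc, np.round(t_dx, 3), np.nan)
    df["histology"] = np.where(lc, obs_hist, "none").astype(object)
    df["stage_group"] = np.where(lc, stage, "none").astype(object)
    df["detection_mode"] = np.where(
        lc, np.where(screen_det, "screen", "clinical"), "none").astype(object)
    df["lc_death"] = lc & death
    df["lc_death_time"] = np.where(lc & death, np.round(t_death, 3), np.nan)
    for col in ("copd", "emphysema", "personal_cancer_history",
                "family_lc_history", "lc_diagnosis", "lc_death"):
        df[col] = df[col].astype("boolean")
    df = df[list(COLUMN_ORDER)]

    truth = pd.DataFrame({
        "id": df["id"],
        "arm": df["arm"],
        "lc_event": lc,
        "latent_histology": histology,
        "stage_control": np.where(lc, stage0, "none").astype(object),
        "stage_ct": np.where(lc, stage1, "none").astype(object),
        "y_control": lc & y0,
        "y_ct": lc & y1,
        "p_lc": p_lc,
        "p_death_control": p_death0,
        "p_death_ct": p_death1,
    })
    for j, h in enumerate(HISTOLOGY_GROUPS):
        truth[f"p_hist_{h}"] = p_hist[:, j]

    cohort = Cohort(df.reset_index(drop=True), trial=cfg.trial_label,
                    followup_cap=cap)
    return cohort, GroundTruth(truth.reset_index(drop=True), cfg)


def inject_missingness(cohort: Cohort, cfg: SimulationConfig,
                       seed: int | None = None) -> Cohort:
    """Blank covariate values per the config's missingness specs.

    MAR mechanisms condition on fully observed variables only; outcome and
    design columns (arm, follow-up, diagnosis, histology, stage, death) are
    never blanked and requesting them raises.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    df = cohort.records.copy()
    for var, spec in cfg.missingness.items():
        if var in OUTCOME_COLUMNS:
            raise ValueError(f"refusing to blank outcome/design column {var!r}")
        if var not in df.columns:
            raise ValueError(f"unknown column {var!r} in missingness config")
        if spec.mechanism == "MCAR":
            rates = np.full(len(df), spec.rate)
        else:
            if df[spec.by].isna().any():
                raise ValueError(
                    f"MAR conditioning variable {spec.by!r} must be fully observed")
            level_rates = spec.rate_by or {}
            rates = df[spec.by].map(
                lambda v: level_rates.get(v, spec.rate)).to_numpy(float)
        blank = rng.random(len(df)) < rates
        if df[var].dtype == "boolean":
            df.loc[blank, var] = pd.NA
        else:
            df.loc[blank, var] = np.nan
    return Cohort(df, cohort.trial, cohort.followup_cap)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.frame.to_csv(path, index=False)
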