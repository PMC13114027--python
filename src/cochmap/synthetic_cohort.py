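"""Synthetic cohort generator emulating a unilateral CI outcome study.

No patient-level data are available for this kind of retrospective CT
study, so every pipeline stage is exercised on virtual cohorts whose
marginal structure matches the published summary statistics: 44
postlingually deafened adults (15 male / 29 female), age ~ N(66.6, 16.8)
truncated to [21, 89] years, preoperative pure-tone average ~
N(97.2, 20.2) dB HL, sex-conditional duct length (34.6 +/- 0.9 mm male,
33.6 +/- 1.5 mm female), electrode coverage ~ N(74.8, 4.6) %, six partial
insertions with extracochlear contacts, three second-implant exclusions,
and per-timepoint attrition 35 -> 33 -> 27.

Speech scores (four measures at 3/6/12 months, 0-100 %) are built from a
latent linear model: standardized age and hearing-threshold effects plus
a mismatch effect whose coefficient is solved exactly from a configured
target partial correlation, plus Gaussian noise.  Sentence scores pass
through a soft ceiling above 80 % to emulate the test's limited headroom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .electrode_map import ElectrodeArray, default_frequency_map, locate_contacts
from .geometry import GeometryConfig, ramanujan_perimeter
from .mismatch import fit_mismatch_profile
from .tonotopy import GreenwoodParams

__all__ = [
    "MEASURES",
    "TIMEPOINTS",
    "GeneratorConfig",
    "PatientRecord",
    "solve_effect_size",
    "generate_cohort",
    "cohort_to_frame",
]

MEASURES = ("monosyllable", "consonant", "word", "sentence")
TIMEPOINTS = ("3m", "6m", "12m")

# Configured effect sizes: target partial correlation (controlling age and
# PTA) for each measure x timepoint.
_DEFAULT_TARGET_R = {
    ("monosyllable", "3m"): -0.41,
    ("monosyllable", "6m"): -0.41,
    ("monosyllable", "12m"): -0.40,
    ("consonant", "3m"): -0.52,
    ("consonant", "6m"): -0.41,
    ("consonant", "12m"): -0.50,
    ("word", "3m"): -0.39,
    ("word", "6m"): -0.39,
    ("word", "12m"): -0.20,
    ("sentence", "3m"): -0.35,
    ("sentence", "6m"): -0.28,
    ("sentence", "12m"): -0.13,
}

# Mean score (percent correct) per measure x timepoint: scores improve
# with time, open-set materials score higher than phoneme-level ones, and
# sentence means sit near the ceiling by 6-12 months.
_DEFAULT_SCORE_MEANS = {
    ("monosyllable", "3m"): 45.0,
    ("monosyllable", "6m"): 52.0,
    ("monosyllable", "12m"): 58.0,
    ("consonant", "3m"): 50.0,
    ("consonant", "6m"): 58.0,
    ("consonant", "12m"): 63.0,
    ("word", "3m"): 55.0,
    ("word", "6m"): 64.0,
    ("word", "12m"): 70.0,
    ("sentence", "3m"): 70.0,
    ("sentence", "6m"): 78.0,
    ("sentence", "12m"): 85.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the virtual cohort, with study-matched defaults."""

    n_patients: int = 44
    n_male: int = 15
    n_female: int = 29
    age_mean: float = 66.6
    age_sd: float = 16.8
    age_range: tuple[float, float] = (21.0, 89.0)
    pta_mean: float = 97.2
    pta_sd: float = 20.2
    pta_range: tuple[float, float] = (40.0, 130.0)
    cdl_male: tuple[float, float] = (34.6, 0.9)  # mean, SD (mm)
    cdl_female: tuple[float, float] = (33.6, 1.5)
    cdl_range: tuple[float, float] = (30.0, 37.0)
    coverage_mean: float = 74.8
    coverage_sd: float = 4.6
    coverage_max: float = 89.0  # keeps apical angles below ~720 degrees
    ba_ratio_mean: float = 6.5 / 8.7
    ba_ratio_sd: float = 0.01
    h_mean: float = 4.0
    h_sd: float = 0.3
    p_right: float = 22.0 / 35.0
    n_extracochlear: int = 6
    n_second_ci: int = 3
    shortfall_range: tuple[float, float] = (0.10, 0.30)
    attrition: tuple[int, int, int] = (35, 33, 27)
    target_r: dict = field(default_factory=lambda: dict(_DEFAULT_TARGET_R))
    gamma_age: float = -0.2
    gamma_pta: float = -0.2
    noise_sd: float = 1.0
    score_means: dict = field(default_factory=lambda: dict(_DEFAULT_SCORE_MEANS))
    score_scale: float = 12.0  # score points per latent SD
    ceiling_threshold: float = 80.0  # sentence soft ceiling
    ceiling_compression: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male + self.n_female != self.n_patients:
            raise ValueError("sex counts must sum to n_patients")
        for name in ("age_sd", "pta_sd", "coverage_sd", "noise_sd", "score_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(sd <= 0 for _, sd in (self.cdl_male, self.cdl_female)):
            raise ValueError("CDL SDs must be positive")
        if list(self.attrition) != sorted(self.attrition, reverse=True):
            raise ValueError("attrition counts must be non-increasing")
        n_analyzable = self.n_patients - self.n_extracochlear - self.n_second_ci
        if self.attrition[0] > n_analyzable:
            raise ValueError(
                f"attrition[0]={self.attrition[0]} exceeds the "
                f"{n_analyzable} analyzable patients"
            )
        for key, r in self.target_r.items():
            if abs(r) >= 1.0:
                raise ValueError(f"infeasible target correlation {r} for {key}")


@dataclass(frozen=True)
class PatientRecord:
    """One virtual patient: covariates, geometry, mismatch, and scores."""

    id: str
    sex: str
    side: str
    age: float
    pta: float
    A: float
    B: float
    H: float
    cdl: float
    inserted_mm: float
    coverage_pct: float
    exclusion_code: str  # none | extracochlear | second_ci
    insertion_complete: bool
    aid_deg: float
    apical_place_hz: float
    mismatch_c6: float
    c6_place_hz: float
    c6_center_hz: float
    scores: dict = field(default_factory=dict)  # (measure, timepoint) -> float|nan


def solve_effect_size(r_target: float, noise_sd: float) -> float:
    """Latent-model coefficient that yields a given population partial r.

    With a standardized mismatch residual and residual noise of standard
    deviation ``noise_sd``, a coefficient ``gamma = r sigma / sqrt(1 -
    r^2)`` makes the population partial correlation (after removing the
    covariates) exactly ``r``.
    """
    if abs(r_target) >= 1.0:
        raise ValueError(f"|r_target| must be < 1, got {r_target}")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    return r_target * noise_sd / math.sqrt(1.0 - r_target**2)


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    a, b = (np.asarray(lo) - mean) / sd, (np.asarray(hi) - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _standardize(v: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mu, sd = v[mask].mean(), v[mask].std(ddof=1)
    return (v - mu) / sd


def generate_cohort(
    cfg: GeneratorConfig = GeneratorConfig(),
    geometry: GeometryConfig = GeometryConfig(),
    array: ElectrodeArray = ElectrodeArray(),
    greenwood: GreenwoodParams = GreenwoodParams(),
) -> list[PatientRecord]:
    """Draw one virtual cohort.

    All randomness flows from ``cfg.seed`` through per-stage substreams,
    so cohorts are reproducible and individual stages stay decoupled.
    Exclusion and attrition counts are exact; which patients they hit is
    random.  The nine excluded ears are assigned among female patients so
    the analysis subset keeps the study's 15 male / 20 female split.
    """
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(6)]
    rng_demo, rng_geo, rng_cov, rng_excl, rng_score, rng_attr = streams
    n = cfg.n_patients
    fmap = default_frequency_map(n_channels=array.n_contacts)

    sex = np.array(["male"] * cfg.n_male + ["female"] * cfg.n_female)
    rng_demo.shuffle(sex)
    side = np.where(rng_demo.random(n) < cfg.p_right, "right", "left")
    age = _truncnorm(rng_demo, cfg.age_mean, cfg.age_sd, *cfg.age_range, size=n)
    pta = _truncnorm(rng_demo, cfg.pta_mean, cfg.pta_sd, *cfg.pta_range, size=n)

    cdl = np.empty(n)
    for label, (mu, sd) in (("male", cfg.cdl_male), ("female", cfg.cdl_female)):
        m = sex == label
        cdl[m] = _truncnorm(rng_geo, mu, sd, *cfg.cdl_range, size=int(m.sum()))
    # Back-solve basal-turn calipers from CDL: the Ramanujan perimeter is
    # homogeneous of degree 1, so for a fixed width/diameter ratio rho,
    # CDL = eca_scale * (A/2) * P(1, rho).
    rho = cfg.ba_ratio_mean + cfg.ba_ratio_sd * rng_geo.standard_normal(n)
    A = np.array(
        [2.0 * c / (geometry.eca_scale * ramanujan_perimeter(1.0, r)) for c, r in zip(cdl, rho)]
    )
    B = rho * A
    H = _truncnorm(rng_geo, cfg.h_mean, cfg.h_sd, 2.0, 6.0, size=n)

    # Insertion depth: every ear receives the same array inserted to the
    # same mark, so the *length* inserted is what varies (surgical
    # variability), and coverage inherits an anticorrelation with CDL.
    # The length distribution is chosen so that coverage = 100 L / CDL has
    # the configured mean and SD at the population CDL distribution.
    p_male = cfg.n_male / cfg.n_patients
    mu_cdl = p_male * cfg.cdl_male[0] + (1 - p_male) * cfg.cdl_female[0]
    var_cdl = (
        p_male * cfg.cdl_male[1] ** 2
        + (1 - p_male) * cfg.cdl_female[1] ** 2
        + p_male * (1 - p_male) * (cfg.cdl_male[0] - cfg.cdl_female[0]) ** 2
    )
    inserted_mean = cfg.coverage_mean / 100.0 * mu_cdl
    var_inserted = (cfg.coverage_sd / 100.0 * mu_cdl) ** 2 - (
        cfg.coverage_mean / 100.0
    ) ** 2 * var_cdl
    if var_inserted <= 0:
        raise ValueError(
            "coverage SD too small for the CDL spread; cannot decompose "
            "insertion-length variability"
        )
    lo_ins = array.contact_span * 1.005  # keep C12 intracochlear
    hi_ins = cfg.coverage_max / 100.0 * cdl  # keep apical angles < ~720 deg
    inserted = _truncnorm(rng_cov, inserted_mean, math.sqrt(var_inserted), lo_ins, hi_ins)
    coverage = 100.0 * inserted / cdl

    # Exclusions: exact counts, drawn among female patients.
    exclusion = np.array(["none"] * n, dtype=object)
    female_idx = np.flatnonzero(sex == "female")
    picked = rng_excl.choice(female_idx, size=cfg.n_extracochlear + cfg.n_second_ci, replace=False)
    exclusion[picked[: cfg.n_extracochlear]] = "extracochlear"
    exclusion[picked[cfg.n_extracochlear :]] = "second_ci"
    shortfall = rng_excl.uniform(*cfg.shortfall_range, size=cfg.n_extracochlear)
    partial = picked[: cfg.n_extracochlear]
    # Partial insertions stop short of the mark; cap below the contact
    # span so at least one basal contact is genuinely extracochlear.
    inserted[partial] = np.minimum(
        inserted[partial] * (1.0 - shortfall), 0.995 * array.contact_span
    )

    # Geometry pass: per-ear electrode state and mismatch statistic.
    states, profiles = [], []
    for i in range(n):
        st = locate_contacts(inserted[i], cdl[i], array, geometry, fmap, greenwood)
        states.append(st)
        profiles.append(fit_mismatch_profile(st))
    mismatch = np.array([p.mismatch_c6 for p in profiles])

    analyzable = exclusion == "none"
    z_age = _standardize(age, analyzable)
    z_pta = _standardize(pta, analyzable)
    z_mm = _standardize(mismatch, analyzable)

    scores: dict[tuple[str, str], np.ndarray] = {}
    for measure in MEASURES:
        for tp in TIMEPOINTS:
            gamma_mm = solve_effect_size(cfg.target_r[(measure, tp)], cfg.noise_sd)
            latent = (
                cfg.gamma_age * z_age
                + cfg.gamma_pta * z_pta
                + gamma_mm * z_mm
                + cfg.noise_sd * rng_score.standard_normal(n)
            )
            s = cfg.score_means[(measure, tp)] + cfg.score_scale * latent
            if measure == "sentence":
                over = s > cfg.ceiling_threshold
                s[over] = cfg.ceiling_threshold + cfg.ceiling_compression * (
                    s[over] - cfg.ceiling_threshold
                )
            scores[(measure, tp)] = np.clip(s, 0.0, 100.0)

    # Attrition: nested per-timepoint missingness with exact counts.
    analyzable_idx = np.flatnonzero(analyzable)
    dropout_order = rng_attr.permutation(analyzable_idx)
    missing_at: dict[str, set[int]] = {}
    for tp, n_kept in zip(TIMEPOINTS, cfg.attrition):
        n_missing = len(analyzable_idx) - n_kept
        missing_at[tp] = set(dropout_order[:n_missing].tolist())

    records = []
    for i in range(n):
        st, pr = states[i], profiles[i]
        patient_scores = {}
        for measure in MEASURES:
            for tp in TIMEPOINTS:
                if i in missing_at[tp]:
                    patient_scores[(measure, tp)] = float("nan")
                else:
                    patient_scores[(measure, tp)] = float(scores[(measure, tp)][i])
        records.append(
            PatientRecord(
                id=f"P{i + 1:03d}",
                sex=str(sex[i]),
                side=str(side[i]),
                age=float(age[i]),
                pta=float(pta[i]),
                A=float(A[i]),
                B=float(B[i]),
                H=float(H[i]),
                cdl=float(cdl[i]),
                inserted_mm=float(inserted[i]),
                coverage_pct=float(st.coverage_pct),
                exclusion_code=str(exclusion[i]),
                insertion_complete=bool(st.insertion_complete),
                aid_deg=float(st.aid_deg),
                apical_place_hz=float(st.place_hz[0]),
                mismatch_c6=float(pr.mismatch_c6),
                c6_place_hz=float(pr.c6_place_hz),
                c6_center_hz=float(pr.c6_center_hz),
                scores=patient_scores,
            )
        )
    return records


def cohort_to_frame(records: list[PatientRecord]):
    """Serialize a cohort to the tabular schema consumed by the pipeline."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "patient_id": r.id,
            "sex": r.sex,
            "side": r.side,
            "age_years": r.age,
            "pta_db": r.pta,
            "A_mm": r.A,
            "B_mm": r.B,
            "H_mm": r.H,
            "cdl_mm": r.cdl,
            "inserted_mm": r.inserted_mm,
            "exclusion_code": r.exclusion_code,
        }
        for measure in MEASURES:
            for tp in TIMEPOINTS:
                row[f"score_{measure}_{tp}"] = r.scores[(measure, tp)]
        rows.append(row)
    return pd.DataFrame(rows)
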