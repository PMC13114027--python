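"""End-to-end orchestration: cohort I/O, eligibility filtering, analysis report.

The pipeline consumes a per-patient cohort table (CSV), applies the
study's eligibility cascade (all ears -> ears with fully intracochlear
electrodes -> unilateral-CI ears with outcomes), computes the per-ear
mismatch statistic, and runs the inferential grid: 12 partial
correlations (4 speech measures x 3 timepoints) between mismatch and
score, controlling age and preoperative hearing threshold, with
Bonferroni control over the 12-test family and per-timepoint listwise
deletion of missing scores.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .electrode_map import ElectrodeArray, default_frequency_map, locate_contacts
from .geometry import CochlearMeasurements, GeometryConfig, eca_cdl
from .mismatch import fit_mismatch_profile
from .stats import TestFamily, partial_correlation, pearson, two_sample_t
from .synthetic_cohort import MEASURES, TIMEPOINTS
from .tonotopy import GreenwoodParams

__all__ = [
    "REQUIRED_COLUMNS",
    "SCORE_COLUMNS",
    "EligibilitySets",
    "AnalysisReport",
    "read_cohort",
    "write_cohort",
    "apply_eligibility_filter",
    "compute_mismatch_table",
    "run_full_analysis",
]

logger = logging.getLogger("cochmap")

SCORE_COLUMNS = [f"score_{m}_{t}" for m in MEASURES for t in TIMEPOINTS]
REQUIRED_COLUMNS = [
    "patient_id",
    "sex",
    "side",
    "age_years",
    "pta_db",
    "A_mm",
    "B_mm",
    "inserted_mm",
    "exclusion_code",
] + SCORE_COLUMNS
_EXCLUSION_CODES = {"none", "extracochlear", "second_ci"}


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; computes ``cdl_mm`` if absent."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {', '.join(missing)}")
    bad = ~df["exclusion_code"].isin(_EXCLUSION_CODES)
    if bad.any():
        rows = df.index[bad].tolist()
        raise ValueError(
            f"unknown exclusion_code in rows {rows}: "
            f"{sorted(df.loc[bad, 'exclusion_code'].unique())}"
        )
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id values: {dups}")
    if "cdl_mm" not in df.columns or df["cdl_mm"].isna().any():
        cdl = [
            eca_cdl(CochlearMeasurements(A=row.A_mm, B=row.B_mm))
            for row in df.itertuples()
        ]
        if "cdl_mm" in df.columns:
            df["cdl_mm"] = df["cdl_mm"].fillna(pd.Series(cdl, index=df.index))
        else:
            df["cdl_mm"] = cdl
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class EligibilitySets:
    """The three nested analysis populations and their counts."""

    geometry_set: pd.DataFrame  # all implanted ears (preoperative imaging)
    electrode_set: pd.DataFrame  # fully intracochlear electrode arrays
    outcome_set: pd.DataFrame  # unilateral-CI ears entering outcome analysis
    counts: dict = field(default_factory=dict)


def apply_eligibility_filter(cohort: pd.DataFrame) -> EligibilitySets:
    """Apply the eligibility cascade and report counts and percentages."""
    bad = ~cohort["exclusion_code"].isin(_EXCLUSION_CODES)
    if bad.any():
        raise ValueError(
            f"unknown exclusion_code in rows {cohort.index[bad].tolist()}"
        )
    geometry_set = cohort
    electrode_set = cohort[cohort["exclusion_code"] != "extracochlear"]
    outcome_set = electrode_set[electrode_set["exclusion_code"] != "second_ci"]
    n_all, n_el, n_out = len(geometry_set), len(electrode_set), len(outcome_set)
    if n_out == 0:
        logger.warning("eligibility filter left an empty outcome set")
    counts = {
        "geometry_n": n_all,
        "electrode_n": n_el,
        "electrode_pct": 100.0 * n_el / n_all if n_all else float("nan"),
        "outcome_n": n_out,
        "outcome_pct": 100.0 * n_out / n_all if n_all else float("nan"),
    }
    logger.info(
        "eligibility: %d ears -> %d fully inserted (%.1f%%) -> %d with outcomes",
        n_all, n_el, counts["electrode_pct"], n_out,
    )
    return EligibilitySets(geometry_set, electrode_set, outcome_set, counts)


def compute_mismatch_table(
    cohort: pd.DataFrame,
    geometry: GeometryConfig = GeometryConfig(),
    array: ElectrodeArray = ElectrodeArray(),
    greenwood: GreenwoodParams = GreenwoodParams(),
) -> pd.DataFrame:
    """Per-ear mismatch table: AID, coverage, C6 mismatch and frequencies."""
    fmap = default_frequency_map(n_channels=array.n_contacts)
    rows = []
    for row in cohort.itertuples():
        state = locate_contacts(
            row.inserted_mm, row.cdl_mm, array, geometry, fmap, greenwood
        )
        profile = fit_mismatch_profile(state)
        rows.append(
            {
                "patient_id": row.patient_id,
                "ear": row.side,
                "AID_deg": state.aid_deg,
                "coverage_pct": state.coverage_pct,
                "apical_place_hz": float(state.place_hz[0]),
                "mismatch_c6_semitones": profile.mismatch_c6,
                "c6_place_hz": profile.c6_place_hz,
                "c6_center_hz": profile.c6_center_hz,
                "insertion_complete": state.insertion_complete,
            }
        )
    return pd.DataFrame(rows)


def _summary(series) -> dict:
    v = np.asarray(series, float)
    v = v[np.isfinite(v)]
    return {"mean": float(v.mean()), "sd": float(v.std(ddof=1)), "n": int(len(v))}


@dataclass(frozen=True)
class AnalysisReport:
    """Structured analysis output mirroring the study's summary tables."""

    cohort_summary: dict  # geometry/electrode summaries (means +/- SD)
    correlation_grid: pd.DataFrame  # measure x timepoint partial correlations
    diagnostics: dict  # Pearson diagnostics and sex/side t-tests
    eligibility: dict
    family: TestFamily
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "cohort_summary": self.cohort_summary,
            "correlation_grid": self.correlation_grid.to_dict(orient="records"),
            "diagnostics": self.diagnostics,
            "eligibility": self.eligibility,
            "family": asdict(self.family) | {"corrected_threshold": self.family.corrected_threshold},
            "metadata": self.metadata,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)

    def grid_table(self) -> pd.DataFrame:
        """Human-readable analog of the outcome table (r to 2 dp, p to 3 dp)."""
        t = self.correlation_grid.copy()
        t["r_partial"] = t["r_partial"].round(2)
        t["p"] = t["p"].round(3)
        return t


def _config_hash(*cfgs) -> str:
    blob = json.dumps([asdict(c) if hasattr(c, "__dataclass_fields__") else c for c in cfgs],
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_full_analysis(
    cohort: pd.DataFrame,
    geometry: GeometryConfig = GeometryConfig(),
    array: ElectrodeArray = ElectrodeArray(),
    greenwood: GreenwoodParams = GreenwoodParams(),
    family: TestFamily = TestFamily(alpha=0.05, m=12),
    seed: int | None = None,
) -> AnalysisReport:
    """Run the complete analysis on a validated cohort table.

    Requires at least 8 outcome-eligible patients.  Cells with too few
    complete observations are marked not-estimable (NaN) and the run
    continues.
    """
    sets = apply_eligibility_filter(cohort)
    if sets.counts["outcome_n"] < 8:
        raise ValueError(
            f"outcome set has only {sets.counts['outcome_n']} patients; need >= 8"
        )

    mm_all = compute_mismatch_table(cohort, geometry, array, greenwood)
    mm_electrode = mm_all[mm_all["patient_id"].isin(sets.electrode_set["patient_id"])]
    el = sets.electrode_set.merge(mm_electrode, on="patient_id")
    out = sets.outcome_set.merge(mm_electrode, on="patient_id")

    # Outcome grid: partial correlation of mismatch vs score per cell,
    # controlling age and PTA, listwise deletion per timepoint.
    grid_rows = []
    for measure in MEASURES:
        for tp in TIMEPOINTS:
            col = f"score_{measure}_{tp}"
            sub = out[["mismatch_c6_semitones", col, "age_years", "pta_db"]].dropna()
            cell = {"measure": measure, "timepoint": tp, "n": len(sub)}
            try:
                res = partial_correlation(
                    sub["mismatch_c6_semitones"],
                    sub[col],
                    sub[["age_years", "pta_db"]].to_numpy(),
                    family=family,
                )
                cell.update(
                    r_partial=res.r, p=res.p, df=res.df,
                    significant_raw=bool(res.significant_raw),
                    significant_bonferroni=bool(res.significant_bonferroni),
                )
            except ValueError as err:
                logger.warning("cell %s/%s not estimable: %s", measure, tp, err)
                cell.update(
                    r_partial=float("nan"), p=float("nan"), df=len(sub) - 4,
                    significant_raw=False, significant_bonferroni=False,
                )
            grid_rows.append(cell)
    grid = pd.DataFrame(grid_rows)

    # Pearson diagnostics on the electrode set, sex/side t-tests on all ears.
    def _pearson_dict(x, y):
        r = pearson(x, y)
        return {"r": r.r, "p": r.p, "n": r.n}

    diagnostics = {
        "aid_vs_cdl": _pearson_dict(el["AID_deg"], el["cdl_mm"]),
        "aid_vs_mismatch": _pearson_dict(el["AID_deg"], el["mismatch_c6_semitones"]),
        "coverage_vs_mismatch": _pearson_dict(el["coverage_pct"], el["mismatch_c6_semitones"]),
        "cdl_vs_mismatch": _pearson_dict(el["cdl_mm"], el["mismatch_c6_semitones"]),
    }
    g = sets.geometry_set
    for label, col, lo, hi in (("cdl_by_sex", "sex", "male", "female"),
                               ("cdl_by_side", "side", "right", "left")):
        tt = two_sample_t(
            g.loc[g[col] == lo, "cdl_mm"], g.loc[g[col] == hi, "cdl_mm"]
        )
        diagnostics[label] = {"t": tt.t_stat, "df": tt.df, "p": tt.p}

    cohort_summary = {
        "A_mm": _summary(g["A_mm"]),
        "B_mm": _summary(g["B_mm"]),
        "cdl_mm": _summary(g["cdl_mm"]),
        "cdl_mm_male": _summary(g.loc[g["sex"] == "male", "cdl_mm"]),
        "cdl_mm_female": _summary(g.loc[g["sex"] == "female", "cdl_mm"]),
        "AID_deg": _summary(el["AID_deg"]),
        "coverage_pct": _summary(el["coverage_pct"]),
        "apical_place_hz": _summary(el["apical_place_hz"]),
        "mismatch_c6_semitones": _summary(el["mismatch_c6_semitones"]),
    }
    if "H_mm" in g.columns:
        cohort_summary["H_mm"] = _summary(g["H_mm"])

    metadata = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(geometry, array, greenwood, family),
    }
    return AnalysisReport(
        cohort_summary=cohort_summary,
        correlation_grid=grid,
        diagnostics=diagnostics,
        eligibility=sets.counts,
        family=family,
        metadata=metadata,
    )
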