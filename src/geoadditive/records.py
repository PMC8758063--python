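"""Respondent records: ingestion, biomarker-based outcome derivation,
descriptive prevalence tables and covariate screening.

Outcomes follow the survey's operational definitions: diabetes is a random
blood glucose strictly above 140 mg/dl; hypertension discards the first of
three blood-pressure readings and flags mean systolic >= 140 mmHg or mean
diastolic >= 90 mmHg over readings 2-3, or current antihypertensive
medication use.  Records missing the relevant biomarker are excluded
per-outcome (never globally) and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CodingScheme",
    "Dataset",
    "DEFAULT_CODING",
    "classify_diabetes",
    "classify_hypertension",
    "derive_outcomes",
    "prevalence_table",
    "screen_covariates",
    "build_design",
    "read_records",
]

GLUCOSE_THRESHOLD = 140.0  # mg/dl, strict
SBP_THRESHOLD = 140.0  # mmHg, inclusive
DBP_THRESHOLD = 90.0  # mmHg, inclusive

#: Survey categorical covariates: ordered levels, reference first, with the
#: integer effect codes retained purely as level labels (the design itself
#: uses reference/dummy coding so that posterior contrasts are against the
#: reference level, matching how fixed-effect tables are laid out).
_LEVELS = {
    "sex": ["Female", "Male"],
    "residence": ["Rural", "Urban"],
    "marital_status": ["Never married", "Married", "Widowed/Divorced/Separated"],
    "caste": ["Scheduled tribe", "Scheduled caste", "Others"],
    "education": ["Illiterate", "Primary", "Secondary", "Higher secondary"],
}
_YESNO = [
    "consume_milk",
    "consume_pulses",
    "consume_vegetables",
    "eat_fruits",
    "consume_egg",
    "eat_fish",
    "eat_chicken",
    "eat_fried_food",
    "take_aerated_drinks",
    "consume_alcohol",
    "smoke_cigarettes",
    "consume_tobacco",
]
for _name in _YESNO:
    _LEVELS[_name] = ["No", "Yes"]

CONTINUOUS_COVARIATES = ("age", "bmi", "wealth_score")


@dataclass(frozen=True)
class CodingScheme:
    """Design coding for the categorical covariates.

    ``levels`` maps covariate -> ordered level list with the reference level
    first; each non-reference level contributes one dummy column.  ``codes``
    keeps the survey's integer effect-code labels (-1 for the reference,
    1, 2, ... for the rest) purely as metadata.
    """

    levels: dict[str, list[str]]
    codes: dict[str, dict[str, int]] = field(default_factory=dict)

    def reference(self, covariate: str) -> str:
        return self.levels[covariate][0]

    def design_columns(self, covariate: str) -> list[str]:
        return [f"{covariate}={lv}" for lv in self.levels[covariate][1:]]


def _default_codes() -> dict[str, dict[str, int]]:
    out = {}
    for cov, lv in _LEVELS.items():
        out[cov] = {lv[0]: -1, **{l: i for i, l in enumerate(lv[1:], start=1)}}
    return out


DEFAULT_CODING = CodingScheme(levels=dict(_LEVELS), codes=_default_codes())


@dataclass
class Dataset:
    """Respondent table plus the district labelling used by the map.

    ``frame`` holds one row per respondent; ``district_index`` maps district
    label -> 0-based position 0..S-1 consistent with the adjacency graph.
    """

    frame: pd.DataFrame
    district_index: dict

    def __post_init__(self):
        missing = set(self.frame["district_id"]) - set(self.district_index)
        if missing:
            raise ValueError(f"records reference unknown districts: {sorted(missing)!r}")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_districts(self) -> int:
        return len(self.district_index)

    def district_positions(self) -> np.ndarray:
        return self.frame["district_id"].map(self.district_index).to_numpy(dtype=int)


def classify_diabetes(glucose) -> np.ndarray:
    """1 iff random blood glucose strictly exceeds 140 mg/dl; NaN propagates.

    Vectorised; scalar input returns a scalar.
    """
    g = np.asarray(glucose, dtype=float)
    out = np.where(np.isnan(g), np.nan, (g > GLUCOSE_THRESHOLD).astype(float))
    if np.any(np.asarray(glucose, dtype=float) <= 0):
        raise ValueError("glucose must be positive (mg/dl)")
    return out if out.ndim else out.item()


def classify_hypertension(bp_readings, on_bp_medication) -> float:
    """Hypertension flag from three (systolic, diastolic) readings + medication.

    The first reading is discarded; the respondent is hypertensive when the
    mean of readings 2-3 is >= 140 systolic or >= 90 diastolic, or when on
    antihypertensive medication.  Missing/short readings without medication
    give NaN (excluded from the hypertension model).
    """
    if on_bp_medication:
        return 1.0
    if bp_readings is None:
        return math.nan
    readings = list(bp_readings)
    if len(readings) != 3:
        log.warning("expected 3 BP readings, got %d; outcome set missing", len(readings))
        return math.nan
    sbp = (readings[1][0] + readings[2][0]) / 2.0
    dbp = (readings[1][1] + readings[2][1]) / 2.0
    return 1.0 if (sbp >= SBP_THRESHOLD or dbp >= DBP_THRESHOLD) else 0.0


def derive_outcomes(frame: pd.DataFrame) -> pd.DataFrame:
    """Add 0/1 ``diabetes`` and ``hypertension`` columns (NaN when underivable).

    Expects ``glucose`` plus either ``bp_readings`` (list of 3 pairs) or the
    six wide columns ``sbp1..sbp3``/``dbp1..dbp3``, and ``on_bp_medication``.
    """
    out = frame.copy()
    out["diabetes"] = np.where(
        frame["glucose"].isna(), np.nan, (frame["glucose"] > GLUCOSE_THRESHOLD).astype(float)
    )
    meds = frame["on_bp_medication"].fillna(False).astype(bool).to_numpy()
    if "bp_readings" in frame.columns:
        htn = np.array(
            [classify_hypertension(r, m) for r, m in zip(frame["bp_readings"], meds)]
        )
    else:
        sbp = frame[["sbp2", "sbp3"]].mean(axis=1)
        dbp = frame[["dbp2", "dbp3"]].mean(axis=1)
        htn = np.where(
            meds,
            1.0,
            np.where(
                sbp.isna() | dbp.isna(),
                np.nan,
                ((sbp >= SBP_THRESHOLD) | (dbp >= DBP_THRESHOLD)).astype(float),
            ),
        )
    out["hypertension"] = htn
    for name in ("diabetes", "hypertension"):
        n_missing = int(out[name].isna().sum())
        if n_missing:
            log.info("%d records lack the %s biomarker; excluded from that model", n_missing, name)
    return out


def prevalence_table(frame: pd.DataFrame, covariate: str, outcome: str):
    """Per-level prevalence (%) and the Pearson chi-square test of independence.

    Returns ``(table, chi2, pvalue)`` where ``table`` has one row per level
    with columns level / n / cases / prevalence_pct.  Levels with zero count
    are dropped with a warning; a single-level table has an undefined test
    (chi2 and p reported as NaN).  No continuity correction is applied.
    """
    sub = frame[[covariate, outcome]].dropna()
    counts = sub.groupby(covariate, observed=True)[outcome].agg(["count", "sum"])
    declared = DEFAULT_CODING.levels.get(covariate)
    if declared is not None:
        for lv in declared:
            if lv not in counts.index:
                log.warning("level %r of %s has zero count; dropped", lv, covariate)
        counts = counts.reindex([lv for lv in declared if lv in counts.index])
    table = pd.DataFrame(
        {
            "level": counts.index,
            "n": counts["count"].to_numpy(dtype=int),
            "cases": counts["sum"].to_numpy(dtype=int),
            "prevalence_pct": 100.0 * counts["sum"] / counts["count"],
        }
    ).reset_index(drop=True)
    if len(table) < 2:
        return table, math.nan, math.nan
    contingency = np.column_stack([table["cases"], table["n"] - table["cases"]])
    if (contingency.sum(axis=0) == 0).any():
        # outcome all-0 or all-1: independence test degenerate
        return table, 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(contingency, correction=False)
    return table, float(chi2), float(p)


def build_design(frame: pd.DataFrame, covariates, coding: CodingScheme = DEFAULT_CODING):
    """Reference-coded fixed-effect design with an intercept column.

    Returns ``(X, labels)``; the reference level of each covariate carries no
    column, so each coefficient is a log-odds contrast against the reference.
    Unknown category values raise with the offending row and level named.
    """
    cols = [np.ones(len(frame))]
    labels = ["(Intercept)"]
    for cov in covariates:
        levels = coding.levels[cov]
        vals = frame[cov]
        bad = ~vals.isin(levels)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"record {frame.index[i]!r}: unseen level {vals.iloc[i]!r} for covariate {cov!r}"
            )
        for lv in levels[1:]:
            cols.append((vals == lv).to_numpy(dtype=float))
            labels.append(f"{cov}={lv}")
    return np.column_stack(cols), labels


def screen_covariates(
    frame: pd.DataFrame,
    candidates,
    outcome: str,
    alpha: float = 0.20,
    coding: CodingScheme = DEFAULT_CODING,
):
    """Joint ML logistic screening: keep covariates with any Wald p < alpha.

    All candidates enter one multiple logistic regression of the derived 0/1
    outcome; a categorical covariate is retained when at least one of its
    design columns has a two-sided Wald p-value below ``alpha`` (default the
    deliberately permissive 20% level used to admit covariates into the
    spatial model).  Continuous candidates enter as single linear columns.
    Non-convergence (e.g. separation) flags the covariate and retains it
    rather than silently dropping it.

    Returns ``(selected, detail)``: the retained covariate names, and a frame
    with one row per design column (covariate, column, coef, pvalue).
    """
    if not list(candidates):
        return [], pd.DataFrame(columns=["covariate", "column", "coef", "pvalue"])
    import statsmodels.api as sm

    sub = frame.dropna(subset=[outcome])
    blocks, labels, owner = [np.ones(len(sub))], ["(Intercept)"], [None]
    for cov in candidates:
        if cov in CONTINUOUS_COVARIATES or cov not in coding.levels:
            blocks.append(sub[cov].to_numpy(dtype=float))
            labels.append(cov)
            owner.append(cov)
        else:
            X_c, lab_c = build_design(sub, [cov], coding)
            for j in range(1, X_c.shape[1]):
                blocks.append(X_c[:, j])
                labels.append(lab_c[j])
                owner.append(cov)
    X = np.column_stack(blocks)
    y = sub[outcome].to_numpy(dtype=float)

    flagged = False
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        pvals = fit.pvalues
        coefs = fit.params
        if not np.all(np.isfinite(pvals)):
            flagged = True
    except Exception as exc:  # separation / singular design
        log.warning("screening regression failed to converge (%s); retaining all", exc)
        flagged = True
        pvals = np.full(X.shape[1], np.nan)
        coefs = np.full(X.shape[1], np.nan)

    detail = pd.DataFrame(
        {
            "covariate": owner[1:],
            "column": labels[1:],
            "coef": coefs[1:],
            "pvalue": pvals[1:],
        }
    )
    selected = []
    for cov in candidates:
        rows = detail["covariate"] == cov
        p_cov = detail.loc[rows, "pvalue"]
        c_cov = detail.loc[rows, "coef"]
        # exploding coefficients mark (quasi-)separation: Wald p is unusable
        separated = p_cov.isna().any() or (c_cov.abs() > 10.0).any()
        if flagged or separated:
            log.warning("covariate %r flagged (separation/non-convergence); retained", cov)
            selected.append(cov)
        elif (p_cov < alpha).any():
            selected.append(cov)
    return selected, detail


def read_records(path) -> pd.DataFrame:
    """Read the respondent CSV (one row each; empty fields are missing)."""
    frame = pd.read_csv(path)
    required = {"respondent_id", "district_id", "age", "glucose", "on_bp_medication"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    if ((frame["age"] < 15) | (frame["age"] > 49)).any():
        raise ValueError("age outside the surveyed range [15, 49]")
    frame["on_bp_medication"] = frame["on_bp_medication"].astype(bool)
    return frame
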