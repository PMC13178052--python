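"""Leakage-safe construction of modelling cohorts from event tables.

The pipeline's modelling stage predicts a first I50 code from strictly
pre-diagnostic claims. Everything here enforces the temporal contract: for
cases, only events dated at least ``washout_days`` (default 365) before
the first I50 code — and within the feature years (2018-2021) — may
contribute to features; controls contribute their full feature-year
window. Imputation/encoding statistics are fitted on training partitions
only and carried in an explicit, serializable state object so no partition
ever sees its own statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HF = "HF"
NON_HF = "NON_HF"

# ICD-10 chapter blocks: (first prefix, last prefix, Roman numeral)
ICD_CHAPTERS = [
    ("A00", "B99", "I"), ("C00", "D48", "II"), ("D50", "D89", "III"),
    ("E00", "E90", "IV"), ("F00", "F99", "V"), ("G00", "G99", "VI"),
    ("H00", "H59", "VII"), ("H60", "H95", "VIII"), ("I00", "I99", "IX"),
    ("J00", "J99", "X"), ("K00", "K93", "XI"), ("L00", "L99", "XII"),
    ("M00", "M99", "XIII"), ("N00", "N99", "XIV"), ("O00", "O99", "XV"),
    ("P00", "P96", "XVI"), ("Q00", "Q99", "XVII"), ("R00", "R99", "XVIII"),
    ("S00", "T98", "XIX"), ("V01", "Y98", "XX"), ("Z00", "Z99", "XXI"),
    ("U00", "U99", "XXII"),
]

MANDATORY_DEMOGRAPHICS = ["age", "sex", "race", "height", "weight"]

AGE_BOUNDS = (18.0, 110.0)
BMI_BOUNDS = (12.0, 60.0)


def icd_chapter(code: str) -> str:
    prefix = code[:3]
    for start, end, numeral in ICD_CHAPTERS:
        if start <= prefix <= end:
            return numeral
    logger.warning("ICD code %r outside every chapter block -> OTHER", code)
    return "OTHER"


@dataclass(frozen=True)
class CohortSpec:
    """Sizes and seeds for development/validation/low-prevalence cohorts.

    The final validation cohort is the source of the low-prevalence set:
    it is assembled with exactly ``low_prev_n_controls`` controls, all of
    which enter the low-prevalence set together with ``low_prev_n_cases``
    cases sampled from the same cohort.
    """

    n_cases: int = 10_000
    n_controls: int = 9_995
    validation_sizes: Sequence[int] = (20_000, 17_041)
    low_prev_n_cases: int = 175
    low_prev_n_controls: int = 8_541
    split_fraction: float = 0.8
    seed: int = 0


@dataclass
class PreprocessorState:
    """Training-partition statistics for imputation, capping, encoding and
    (optionally) standardization. Fitted exclusively on training rows."""

    medians: dict = field(default_factory=dict)
    modes: dict = field(default_factory=dict)
    p99_caps: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    categories: dict = field(default_factory=dict)
    standardize: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "PreprocessorState":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


def completeness_filter(demographics: pd.DataFrame) -> pd.Index:
    """Ids of patients with all five mandatory fields (age, sex, race,
    height, weight) present."""
    mask = demographics[MANDATORY_DEMOGRAPHICS].notna().all(axis=1)
    retained = demographics.loc[mask, "patient_id"]
    if len(retained) == 0:
        logger.warning("completeness filter retained zero patients")
    return pd.Index(retained)


def apply_washout(
    events: pd.DataFrame,
    first_i50: Mapping[str, object] | pd.Series,
    washout_days: int = 365,
    feature_years: tuple[int, int] = (2018, 2021),
) -> pd.DataFrame:
    """Filter events to the leakage-safe feature window.

    Cases (patients with a first I50 date): keep events dated at least
    ``washout_days`` before it, i.e. ``date <= first_i50 - washout_days``
    (inclusive boundary, plain calendar-day arithmetic), and within the
    feature years. Controls: keep events within the feature years only.
    A case left with zero surviving events is retained downstream with
    all-zero counts (flagged via log).
    """
    df = events.copy()
    dates = pd.to_datetime(df["event_date"])
    i50 = pd.Series(dict(first_i50))
    i50 = pd.to_datetime(i50, errors="coerce")
    cutoff = df["patient_id"].map(i50 - pd.Timedelta(days=washout_days))

    in_years = dates.dt.year.between(feature_years[0], feature_years[1])
    is_case = cutoff.notna()
    keep = in_years & (~is_case | (dates <= cutoff))

    dropped_cases = df.loc[is_case & ~keep, "patient_id"].unique()
    kept_cases = df.loc[is_case & keep, "patient_id"].unique()
    silent = set(dropped_cases) - set(kept_cases)
    if silent:
        logger.info("%d case(s) have zero events surviving the washout", len(silent))
    return df.loc[keep].reset_index(drop=True)


def assert_no_leakage(
    events_used: pd.DataFrame,
    first_i50: Mapping[str, object] | pd.Series,
    washout_days: int = 365,
    forbidden_year: int = 2022,
) -> None:
    """Machine-checked leakage assertion on a feature-event table."""
    dates = pd.to_datetime(events_used["event_date"])
    if (dates.dt.year >= forbidden_year).any():
        raise AssertionError(f"feature events dated in {forbidden_year} or later")
    i50 = pd.to_datetime(pd.Series(dict(first_i50)), errors="coerce")
    cutoff = events_used["patient_id"].map(i50 - pd.Timedelta(days=washout_days))
    bad = cutoff.notna() & (dates > cutoff)
    if bad.any():
        raise AssertionError(f"{int(bad.sum())} event(s) inside the washout window")


def assign_pseudo_index(
    control_ids: Sequence, case_index_dates: Sequence, seed: int = 0
) -> dict:
    """Give each control a pseudo index date sampled (with replacement)
    from the cases' first-I50 date distribution.

    Applying the washout at these dates equalises the observation windows
    of cases and controls, removing the volume bias that otherwise lets a
    model detect cases by their shorter windows. Off by default in the
    pipeline: the source study describes no control index date.
    """
    dates = pd.to_datetime(pd.Series(list(case_index_dates))).dropna().to_numpy()
    if len(dates) == 0:
        raise ValueError("no case index dates to mirror")
    rng = np.random.default_rng(seed)
    picked = rng.choice(dates, size=len(control_ids), replace=True)
    return dict(zip(control_ids, pd.to_datetime(picked)))


def build_features(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    case_ids: set | Sequence | None = None,
) -> pd.DataFrame:
    """Aggregate windowed events into per-patient feature vectors.

    Columns: demographics (age, sex, race, bmi), ``ch_<numeral>`` ICD-10
    chapter counts, ``icd_<prefix>`` 3-character code counts and
    ``proc_<id>`` procedure counts — counts left untransformed. Patients in
    the demographics table with no surviving events get all-zero counts.
    When ``case_ids`` is given a ``label`` column (HF / NON_HF) is added.
    """
    df = events.copy()
    df["prefix"] = df["icd10"].astype(str).str[:3]
    df["chapter"] = df["prefix"].map(
        lambda p: icd_chapter(p)
    )

    code_counts = (
        df.pivot_table(index="patient_id", columns="prefix", values="icd10",
                       aggfunc="count", fill_value=0)
        .add_prefix("icd_")
    )
    chapter_counts = (
        df.pivot_table(index="patient_id", columns="chapter", values="icd10",
                       aggfunc="count", fill_value=0)
        .add_prefix("ch_")
    )
    procs = df[df["procedure"].notna()]
    proc_counts = (
        procs.pivot_table(index="patient_id", columns="procedure", values="icd10",
                          aggfunc="count", fill_value=0)
        .add_prefix("proc_")
        if len(procs) else pd.DataFrame(index=code_counts.index)
    )

    base = demographics.set_index("patient_id")[["age", "sex", "race", "bmi"]]
    out = base.join([chapter_counts, code_counts, proc_counts], how="left")
    count_cols = [c for c in out.columns if c.split("_")[0] in ("ch", "icd", "proc")]
    out[count_cols] = out[count_cols].fillna(0).astype(int)
    out = out.reset_index()
    if case_ids is not None:
        case_ids = set(case_ids)
        out["label"] = np.where(out["patient_id"].isin(case_ids), HF, NON_HF)
    return out


def count_columns(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns
            if c.startswith(("ch_", "icd_", "proc_"))]


def plausibility_filter(
    features: pd.DataFrame, state: "PreprocessorState | None" = None
) -> pd.DataFrame:
    """Apply clinical plausibility rules.

    Age outside [18, 110] or BMI outside [12, 60] drops the patient
    (cohort eligibility); count features above the training-fitted 99th
    percentile caps are set missing (to be median-imputed) rather than
    dropping the patient.
    """
    out = features.copy()
    ok_age = out["age"].between(*AGE_BOUNDS) | out["age"].isna()
    ok_bmi = out["bmi"].between(*BMI_BOUNDS) | out["bmi"].isna()
    out = out.loc[ok_age & ok_bmi].reset_index(drop=True)
    if state is not None and state.p99_caps:
        for col, cap in state.p99_caps.items():
            if col in out.columns:
                col_vals = out[col].astype(float)
                out[col] = col_vals.mask(col_vals > cap)
    return out


def fit_preprocessor(
    train_features: pd.DataFrame, standardize: bool = False
) -> PreprocessorState:
    """Fit imputation medians/modes, p99 caps, one-hot categories and
    (optionally) standardization statistics on training rows only."""
    continuous = ["age", "bmi"] + count_columns(train_features)
    categorical = [c for c in ("sex", "race") if c in train_features.columns]
    state = PreprocessorState(standardize=standardize)
    for col in continuous:
        if col not in train_features.columns:
            continue
        series = train_features[col].astype(float)
        if series.notna().sum() == 0:
            raise ValueError(f"feature {col!r} entirely missing in training data")
        state.medians[col] = float(series.median())
        if col.startswith(("ch_", "icd_", "proc_")):
            state.p99_caps[col] = float(series.quantile(0.99))
        if standardize:
            state.means[col] = float(series.mean())
            state.sds[col] = float(series.std(ddof=0)) or 1.0
    for col in categorical:
        series = train_features[col]
        if series.notna().sum() == 0:
            raise ValueError(f"feature {col!r} entirely missing in training data")
        state.modes[col] = str(series.mode().iloc[0])
        state.categories[col] = sorted(series.dropna().astype(str).unique())
    return state


def apply_preprocessor(
    state: PreprocessorState, features: pd.DataFrame
) -> pd.DataFrame:
    """Impute, one-hot encode, and optionally standardize using training
    statistics only. Returns a fully numeric table indexed by patient_id
    (label column, if present, passed through untouched)."""
    out = features.set_index("patient_id").copy()
    label = out.pop("label") if "label" in out.columns else None
    for col, med in state.medians.items():
        if col in out.columns:
            out[col] = out[col].astype(float).fillna(med)
        else:
            out[col] = med
    for col, mode in state.modes.items():
        if col in out.columns:
            filled = out[col].astype(object).where(out[col].notna(), mode).astype(str)
        else:
            filled = pd.Series(mode, index=out.index)
        for cat in state.categories[col]:
            out[f"{col}__{cat}"] = (filled == cat).astype(float)
        out = out.drop(columns=[col])
    if state.standardize:
        for col, mean in state.means.items():
            out[col] = (out[col] - mean) / state.sds[col]
    ordered = sorted(c for c in out.columns)
    out = out[ordered].astype(float)
    if label is not None:
        out["label"] = label
    return out.reset_index()


def assemble_cohorts(
    features: pd.DataFrame, spec: CohortSpec
) -> dict[str, np.ndarray]:
    """Sample pairwise-disjoint development, validation and low-prevalence
    cohorts (plus an 80/20 stratified development split).

    Development is balanced (``n_cases`` + ``n_controls``). Validation
    cohorts draw from the remaining pool; the final one is built with
    exactly ``low_prev_n_controls`` controls, all of which form the
    low-prevalence set together with ``low_prev_n_cases`` of its cases.
    """
    rng = np.random.default_rng(spec.seed)
    cases = features.loc[features["label"] == HF, "patient_id"].to_numpy()
    controls = features.loc[features["label"] == NON_HF, "patient_id"].to_numpy()

    def _take(pool: np.ndarray, k: int, stratum: str) -> tuple[np.ndarray, np.ndarray]:
        if len(pool) < k:
            raise ValueError(
                f"insufficient patients in stratum {stratum!r}: need {k}, have {len(pool)}"
            )
        picked = rng.choice(pool, size=k, replace=False)
        rest = pool[~np.isin(pool, picked)]
        return picked, rest

    dev_cases, cases = _take(cases, spec.n_cases, "cases/development")
    dev_controls, controls = _take(controls, spec.n_controls, "controls/development")
    development = np.concatenate([dev_cases, dev_controls])

    out: dict[str, np.ndarray] = {"development": development}

    n_train_cases = int(round(spec.split_fraction * spec.n_cases))
    n_train_controls = int(round(spec.split_fraction * spec.n_controls))
    train = np.concatenate([
        rng.choice(dev_cases, size=n_train_cases, replace=False),
        rng.choice(dev_controls, size=n_train_controls, replace=False),
    ])
    out["development_train"] = train
    out["development_test"] = development[~np.isin(development, train)]

    sizes = list(spec.validation_sizes)
    for i, size in enumerate(sizes, start=1):
        if i == len(sizes):
            n_ctrl = spec.low_prev_n_controls
            n_case = size - n_ctrl
        else:
            n_case = size // 2
            n_ctrl = size - n_case
        v_cases, cases = _take(cases, n_case, f"cases/validation_{i}")
        v_controls, controls = _take(controls, n_ctrl, f"controls/validation_{i}")
        out[f"validation_{i}"] = np.concatenate([v_cases, v_controls])
        if i == len(sizes):
            lp_cases, _ = _take(v_cases, spec.low_prev_n_cases, "cases/low_prevalence")
            out["low_prevalence"] = np.concatenate([lp_cases, v_controls])
    return out
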