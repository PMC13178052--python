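"""Rule-based HF phenotyping of ambulatory patients and deaths.

Ambulatory stream: a patient with at least one I50-prefixed event is
DIAGNOSED_HF; otherwise, a patient with at least one trigger-ICD event
(I21, I25, I42, I48) *and* at least one trigger procedure (BNP/NT-proBNP,
echocardiography, catheterisation, ergospirometry, Chagas serology) is
POTENTIAL_HF; everyone else is NEITHER. The conjunction of the two trigger
conditions is the strictest reading of the flowchart and is switchable to
a disjunction via ``trigger_logic="or"``.

Mortality stream: a certificate with I50 anywhere (underlying cause, Part
I lines A-D, or Part II) is an HF_DEATH. With no I50 anywhere, a
mortality-set code (B57, I05-I08, I21-I25, I34-I39, I42-I44, I48, I49,
I51) found in the Part I lines or Part II — the underlying cause is
deliberately excluded from this search — marks a POTENTIAL_HF_DEATH,
subclassified by cause. Everything else is OTHER.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .records import CodeSet, PART1_LINES

logger = logging.getLogger(__name__)

DIAGNOSED_HF = "DIAGNOSED_HF"
POTENTIAL_HF = "POTENTIAL_HF"
NEITHER = "NEITHER"

HF_DEATH = "HF_DEATH"
POTENTIAL_HF_DEATH = "POTENTIAL_HF_DEATH"
OTHER = "OTHER"

ISCHAEMIC = "ISCHAEMIC"
VALVULAR = "VALVULAR"
CARDIOMYOPATHY = "CARDIOMYOPATHY"
OTHER_CARDIAC = "OTHER_CARDIAC"
NONE = "NONE"

HF_PREFIX = "I50"

# subclass membership at the 3-character prefix level; priority is
# ischaemic > valvular > cardiomyopathy > other cardiac (the dominance of
# infarction/ischaemia among potential HF deaths requires ischaemic first)
_ISCHAEMIC_SET = CodeSet("ischaemic", ranges=(("I21", "I25"),))
_VALVULAR_SET = CodeSet("valvular", ranges=(("I05", "I08"), ("I34", "I39")))
_CARDIOMYOPATHY_SET = CodeSet("cardiomyopathy", prefixes=("B57",), ranges=(("I42", "I44"),))
_OTHER_CARDIAC_SET = CodeSet("other_cardiac", prefixes=("I48", "I49", "I51"))


@dataclass(frozen=True)
class AmbulatoryPhenotype:
    patient_id: str
    label: str
    classification_year: int | None
    first_i50_date: date | None
    trigger_icds_hit: frozenset
    trigger_procedures_hit: frozenset


@dataclass(frozen=True)
class MortalityPhenotype:
    person_id: str
    label: str
    subclass: str
    matched_codes: frozenset


def classify_ambulatory(
    events: pd.DataFrame,
    trigger_icds: CodeSet,
    trigger_procs: CodeSet,
    trigger_logic: str = "and",
) -> AmbulatoryPhenotype:
    """Classify one patient's event sequence (columns event_date, icd10,
    procedure, all codes normalized, sorted by date)."""
    patient_id = events["patient_id"].iloc[0] if len(events) else ""
    if len(events) == 0:
        logger.info("empty event sequence for patient %r -> NEITHER", patient_id)
        return AmbulatoryPhenotype(patient_id, NEITHER, None, None,
                                   frozenset(), frozenset())

    icds = events["icd10"].astype(str)
    is_i50 = icds.str.startswith(HF_PREFIX)
    if is_i50.any():
        first = events.loc[is_i50, "event_date"].min()
        return AmbulatoryPhenotype(
            patient_id, DIAGNOSED_HF, first.year, first, frozenset(), frozenset()
        )

    icd_hits = events.loc[[icd_matches_set(c, trigger_icds) for c in icds]]
    proc_hits = events.loc[[
        p is not None and not (isinstance(p, float) and np.isnan(p))
        and trigger_procs.contains_procedure(p)
        for p in events["procedure"]
    ]]
    has_icd, has_proc = len(icd_hits) > 0, len(proc_hits) > 0
    qualifies = (has_icd and has_proc) if trigger_logic == "and" else (has_icd or has_proc)
    if qualifies:
        dates = []
        if has_icd:
            dates.append(icd_hits["event_date"].min())
        if has_proc:
            dates.append(proc_hits["event_date"].min())
        # first date at which all required conditions are satisfied
        qual_date = max(dates) if trigger_logic == "and" else min(dates)
        return AmbulatoryPhenotype(
            patient_id, POTENTIAL_HF, qual_date.year, None,
            frozenset(c[:3] for c in icd_hits["icd10"]),
            frozenset(proc_hits["procedure"]),
        )
    return AmbulatoryPhenotype(patient_id, NEITHER, None, None,
                               frozenset(), frozenset())


def icd_matches_set(code: str, cs: CodeSet) -> bool:
    return cs.contains_icd(code)


def classify_ambulatory_table(
    events: pd.DataFrame,
    trigger_icds: CodeSet,
    trigger_procs: CodeSet,
    trigger_logic: str = "and",
) -> pd.DataFrame:
    """Vectorized classification of a whole event table.

    Returns one row per patient: patient_id, label, classification_year,
    first_i50_date.
    """
    if trigger_logic not in ("and", "or"):
        raise ValueError(f"trigger_logic must be 'and' or 'or': {trigger_logic!r}")
    df = events.copy()
    df["event_date"] = pd.to_datetime(df["event_date"])
    prefix = df["icd10"].astype(str).str[:3]

    trig_prefixes = set(trigger_icds.all_prefixes())
    trig_procs = set(trigger_procs.procedures)

    df["_is_i50"] = prefix == HF_PREFIX
    df["_is_trig_icd"] = prefix.isin(trig_prefixes)
    df["_is_trig_proc"] = df["procedure"].isin(trig_procs)

    df["_i50_date"] = df["event_date"].where(df["_is_i50"])
    df["_trig_icd_date"] = df["event_date"].where(df["_is_trig_icd"])
    df["_trig_proc_date"] = df["event_date"].where(df["_is_trig_proc"])
    out = (
        df.groupby("patient_id", sort=True)[["_i50_date", "_trig_icd_date", "_trig_proc_date"]]
        .min()
        .rename(columns={
            "_i50_date": "first_i50_date",
            "_trig_icd_date": "first_trig_icd",
            "_trig_proc_date": "first_trig_proc",
        })
    )

    diagnosed = out["first_i50_date"].notna()
    if trigger_logic == "and":
        potential = (~diagnosed) & out["first_trig_icd"].notna() & out["first_trig_proc"].notna()
        qual_date = out[["first_trig_icd", "first_trig_proc"]].max(axis=1)
    else:
        potential = (~diagnosed) & (out["first_trig_icd"].notna() | out["first_trig_proc"].notna())
        qual_date = out[["first_trig_icd", "first_trig_proc"]].min(axis=1)

    label = np.where(diagnosed, DIAGNOSED_HF, np.where(potential, POTENTIAL_HF, NEITHER))
    year = pd.Series(pd.NaT, index=out.index)
    year[diagnosed] = out.loc[diagnosed, "first_i50_date"]
    year[potential] = qual_date[potential]

    result = pd.DataFrame({
        "patient_id": out.index,
        "label": label,
        "classification_year": pd.to_datetime(year).dt.year.values,
        "first_i50_date": out["first_i50_date"].dt.date.values,
    }).reset_index(drop=True)
    return result


def subclassify_cause(matched_codes: frozenset | set) -> str:
    """Map the mortality-set prefixes found on a certificate to a cause
    subclass, with fixed priority ischaemic > valvular > cardiomyopathy >
    other cardiac."""
    if not matched_codes:
        return NONE
    if any(_ISCHAEMIC_SET.contains_icd(c) for c in matched_codes):
        return ISCHAEMIC
    if any(_VALVULAR_SET.contains_icd(c) for c in matched_codes):
        return VALVULAR
    if any(_CARDIOMYOPATHY_SET.contains_icd(c) for c in matched_codes):
        return CARDIOMYOPATHY
    return OTHER_CARDIAC


def classify_death(cert: pd.Series | dict, mortality_set: CodeSet) -> MortalityPhenotype:
    """Classify a single death certificate (normalized codes)."""
    line_codes: list[str] = []
    for col in [f"line_{l.lower()}" for l in PART1_LINES] + ["part2"]:
        v = cert.get(col)
        if isinstance(v, (list, tuple)):
            line_codes.extend(v)
    underlying = cert["underlying_cause"]
    all_codes = [underlying] + line_codes

    if any(c.startswith(HF_PREFIX) for c in all_codes):
        return MortalityPhenotype(cert["person_id"], HF_DEATH, NONE, frozenset())

    # underlying cause deliberately excluded from the potential-HF search
    matched = frozenset(c[:3] for c in line_codes if mortality_set.contains_icd(c))
    if matched:
        return MortalityPhenotype(
            cert["person_id"], POTENTIAL_HF_DEATH, subclassify_cause(matched), matched
        )
    return MortalityPhenotype(cert["person_id"], OTHER, NONE, frozenset())


def classify_death_table(deaths: pd.DataFrame, mortality_set: CodeSet) -> pd.DataFrame:
    """Classify every certificate; returns person_id, label, subclass,
    matched_codes and the certificate year."""
    rows = []
    for _, cert in deaths.iterrows():
        ph = classify_death(cert, mortality_set)
        rows.append({
            "person_id": ph.person_id,
            "label": ph.label,
            "subclass": ph.subclass,
            "matched_codes": sorted(ph.matched_codes),
            "classification_year": pd.Timestamp(cert["death_date"]).year,
        })
    return pd.DataFrame(rows)


def summarize_by_year(
    phenotypes: pd.DataFrame, demographics: pd.DataFrame,
    age_col: str = "age", id_col: str = "patient_id",
) -> pd.DataFrame:
    """Yearly summary per label: n, mean age (SD), n male, % male.

    Mirrors the layout of the published descriptive tables; rows for
    empty (year, label) combinations are omitted, and percentages are
    computed from each row's own counts.
    """
    merged = phenotypes.merge(demographics, on=id_col, how="left")
    merged = merged[merged["label"].notna() & merged["classification_year"].notna()]
    rows = []
    for (year, label), grp in merged.groupby(["classification_year", "label"]):
        n = len(grp)
        n_male = int((grp["sex"] == "male").sum())
        rows.append({
            "year": int(year),
            "label": label,
            "n": n,
            "mean_age": round(float(grp[age_col].mean()), 2) if grp[age_col].notna().any() else float("nan"),
            "sd_age": round(float(grp[age_col].std(ddof=1)), 2) if grp[age_col].notna().sum() > 1 else float("nan"),
            "n_male": n_male,
            "pct_male": round(100.0 * n_male / n, 2),
        })
    return pd.DataFrame(rows).sort_values(["label", "year"]).reset_index(drop=True)


def male_percentage(n_male: int, n: int) -> float:
    """Male share of a summary row, in percent, rounded to 2 decimals."""
    if n <= 0:
        raise ValueError("row count must be positive")
    return round(100.0 * n_male / n, 2)


def proxy_model_concordance(
    proxy_positive_ids: set, model_positive_ids: set
) -> tuple[int, float]:
    """Overlap between proxy-identified and model-identified patients.

    Returns ``(|proxy ∩ model|, 100·|proxy ∩ model| / |proxy|)``, the
    percentage rounded to 2 decimals.
    """
    if not proxy_positive_ids:
        raise ValueError("proxy set is empty; concordance undefined")
    overlap = len(set(proxy_positive_ids) & set(model_positive_ids))
    return overlap, round(100.0 * overlap / len(proxy_positive_ids), 2)
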