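"""Synthetic claims population with known latent heart-failure status.

Stand-in for the ambulatory (SIA-SUS-like) and mortality (SIM-SUS-like)
extracts: every downstream stage — phenotyping, underreporting estimation,
cohort building, modelling — can be exercised against a population whose
true HF status, coding behaviour and death-certificate masking are planted
and therefore recoverable.

Generative model (per patient):

* latent ``true_hf ~ Bernoulli(true_hf_prevalence)``; onset date uniform
  over the study window.
* a true-HF patient ever receives an I50 code with probability
  ``coding_probability``; if coded, the first I50 event occurs after an
  investigation delay drawn uniform over 0-24 months (clipped to the
  window end), so washout logic is exercised on both sides of the
  boundary.
* comorbidity presence is Bernoulli with a logistic link:
  ``P(code | HF) = expit(logit(base_rate) + log-odds shift)``, which makes
  planted odds ratios directly checkable from a contingency table.
  Present comorbidities emit ``1 + Poisson`` billed events; true-HF
  patients' events are dated before onset (pre-diagnostic trajectory).
* investigation procedures follow the same presence/count scheme.
* deaths occur at ``annual_death_rate`` (multiplied for true HF); every
  true-HF decedent is an HF death, certified with I50 unless masked: with
  probability ``hf_death_masking_probability`` the certificate carries an
  ischaemic/cardiomyopathy code on Part I line A and no I50 anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd

from .records import ICD10_PATTERN, PROCEDURES

__all__ = ["GeneratorConfig", "generate_population", "plant_feature_signal"]

# non-cardiac codes used as billing noise and non-HF causes of death
NOISE_ICDS = ["Z000", "J069", "M545", "E119", "R51", "K297", "N390", "A09", "L309"]
NON_HF_DEATH_ICDS = ["C349", "J189", "E149", "V892", "R99", "G309", "K746", "N179"]
# ICD code justifying a procedure row (observation for suspected CV disease)
PROCEDURE_JUSTIFICATION_ICD = "Z034"

_DEFAULT_COMORBIDITY_RATES = {
    # ambulatory trigger set
    "I21": 0.03, "I25": 0.08, "I42": 0.01, "I48": 0.04,
    # modelling comorbidities: hypertension, diabetes, lipoprotein
    # disorders, chronic kidney disease
    "I10": 0.25, "E11": 0.12, "E78": 0.15, "N18": 0.05,
}
_DEFAULT_COMORBIDITY_HF_SHIFT = {
    "I21": 1.5, "I25": 1.5, "I42": 1.5, "I48": 1.2,
    "I10": 0.8, "E11": 0.6, "E78": 0.6, "N18": 1.0,
}
_DEFAULT_PROCEDURE_RATES = {
    "ECHO": 0.10, "BNP": 0.02, "CATH": 0.01, "ERGO": 0.01,
    "CHAGAS_SERO": 0.02, "ECG": 0.25, "ABPM": 0.03,
}
_DEFAULT_PROCEDURE_HF_SHIFT = {
    "ECHO": 1.8, "BNP": 1.8, "CATH": 1.2, "ERGO": 0.8,
    "CHAGAS_SERO": 0.8, "ECG": 0.8, "ABPM": 0.5,
}
# certificate codes for masked HF deaths; heavily ischaemic, mirroring the
# observed dominance of infarction/ischaemia among potential HF deaths
_DEFAULT_MASKED_CODE_WEIGHTS = {
    "I219": 0.55, "I259": 0.43, "I429": 0.010, "I350": 0.005, "I489": 0.005,
}
_DEFAULT_DEMOGRAPHICS = {
    "age_mean": 61.0, "age_sd": 14.0,
    "height_mean": 1.66, "height_sd": 0.09,
    "weight_mean": 72.0, "weight_sd": 14.0,
    "p_male": 0.52,
    "race_categories": ["parda", "branca", "preta", "amarela", "indigena"],
    "race_probs": [0.45, 0.43, 0.09, 0.02, 0.01],
}
_DEFAULT_MISSINGNESS = {
    "age": 0.01, "sex": 0.005, "race": 0.08, "height": 0.10, "weight": 0.10,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic claims population.

    ``signal_timing`` controls when true-HF patients' comorbidity and
    procedure events occur relative to their first I50 date:
    ``pre_onset`` (default) dates them before HF onset, ``pre_washout``
    strictly more than 365 days before the first I50 code, and
    ``washout_only`` inside the final 365 days before it — the latter two
    exist to probe the leakage guards downstream.
    """

    n_patients: int = 10_000
    study_years: tuple[int, int] = (2018, 2022)
    lookback_years: int = 3
    true_hf_prevalence: float = 0.05
    coding_probability: float = 0.6
    comorbidity_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITY_RATES))
    comorbidity_hf_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITY_HF_SHIFT))
    procedure_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROCEDURE_RATES))
    procedure_hf_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROCEDURE_HF_SHIFT))
    extra_events_mean: float = 1.5
    background_events_per_year: float = 0.8
    annual_death_rate: float = 0.01
    hf_death_rate_multiplier: float = 5.0
    hf_death_masking_probability: float = 0.3
    masked_code_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MASKED_CODE_WEIGHTS))
    non_hf_cardiac_line_rate: float = 0.08
    demographics_spec: Mapping[str, object] = field(
        default_factory=lambda: dict(_DEFAULT_DEMOGRAPHICS))
    missingness_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS))
    signal_timing: str = "pre_onset"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.lookback_years < 0:
            raise ValueError("lookback_years must be >= 0")
        for name in ("true_hf_prevalence", "coding_probability",
                     "hf_death_masking_probability", "annual_death_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.signal_timing not in ("pre_onset", "pre_washout", "washout_only"):
            raise ValueError(f"unknown signal_timing: {self.signal_timing!r}")

    @property
    def window_start(self) -> date:
        return date(self.study_years[0] - self.lookback_years, 1, 1)

    @property
    def study_start(self) -> date:
        return date(self.study_years[0], 1, 1)

    @property
    def window_end(self) -> date:
        return date(self.study_years[1], 12, 31)


def plant_feature_signal(
    config: GeneratorConfig, effect_sizes: Mapping[str, float]
) -> GeneratorConfig:
    """Return a config whose generated data carries the given conditional
    log-odds of true HF per feature.

    Keys are 3-character ICD prefixes (comorbidity presence) or procedure
    identifiers; values are log-odds shifts of feature presence given true
    HF, i.e. the log odds ratio recoverable from a 2x2 table of feature
    presence against latent status. All shifts not named are zeroed, so the
    planted features are the only signal.
    """
    comorb_rates = dict(config.comorbidity_rates)
    comorb_shift = {k: 0.0 for k in comorb_rates}
    proc_rates = dict(config.procedure_rates)
    proc_shift = {k: 0.0 for k in proc_rates}
    for name, beta in effect_sizes.items():
        if name in PROCEDURES:
            proc_rates.setdefault(name, 0.05)
            proc_shift[name] = float(beta)
        elif ICD10_PATTERN.match(name) and len(name) == 3:
            comorb_rates.setdefault(name, 0.05)
            comorb_shift[name] = float(beta)
        else:
            raise KeyError(f"unknown feature name: {name!r}")
    return replace(
        config,
        comorbidity_rates=comorb_rates,
        comorbidity_hf_shift=comorb_shift,
        procedure_rates=proc_rates,
        procedure_hf_shift=proc_shift,
    )


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return math.log(p / (1.0 - p))


def _dates_from_ordinals(ordinals: np.ndarray) -> list[date]:
    return [date.fromordinal(int(o)) for o in ordinals]


def _presence(rng, base_rate, shift, true_hf):
    """Bernoulli presence under a logistic link on latent status."""
    p = _expit(_logit(base_rate) + shift * true_hf.astype(float))
    return rng.random(len(true_hf)) < p


def _event_dates(rng, n_events, owner_lo, owner_hi):
    """Uniform integer ordinals in [lo, hi] per owning patient."""
    return rng.integers(owner_lo, owner_hi + 1)


def generate_population(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a claims population.

    Returns ``(events, deaths, demographics, latent)`` tables. Fully
    reproducible: identical config (including seed) yields byte-identical
    tables. Emits a warning-level note (via the returned latent table
    simply containing zero cases) when ``prevalence * n_patients < 1``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = np.array([f"P{i:07d}" for i in range(n)])

    win_lo = config.window_start.toordinal()
    win_hi = config.window_end.toordinal()
    study_lo = config.study_start.toordinal()

    # ------------------------------------------------------------------ latent
    true_hf = rng.random(n) < config.true_hf_prevalence
    onset = np.where(
        true_hf, rng.integers(study_lo, win_hi + 1, size=n), -1
    )
    coded = true_hf & (rng.random(n) < config.coding_probability)
    delay = rng.integers(0, 731, size=n)  # 0-24 months in days
    first_i50 = np.where(coded, np.minimum(onset + delay, win_hi), -1)

    # ------------------------------------------------------------ demographics
    spec = config.demographics_spec
    age = np.clip(rng.normal(spec["age_mean"], spec["age_sd"], n), 18, 100)
    sex = np.where(rng.random(n) < spec["p_male"], "male", "female")
    race = rng.choice(spec["race_categories"], size=n, p=spec["race_probs"])
    height = np.clip(rng.normal(spec["height_mean"], spec["height_sd"], n), 1.3, 2.1)
    weight = np.clip(rng.normal(spec["weight_mean"], spec["weight_sd"], n), 35, 180)
    demographics = pd.DataFrame({
        "patient_id": ids,
        "age": np.round(age, 1),
        "sex": sex,
        "race": race,
        "height": np.round(height, 2),
        "weight": np.round(weight, 1),
    })
    for col, rate in config.missingness_rates.items():
        if rate > 0 and col in demographics.columns:
            mask = rng.random(n) < rate
            demographics.loc[mask, col] = np.nan if col in ("age", "height", "weight") else None
    demographics["bmi"] = demographics["weight"] / demographics["height"] ** 2

    # --------------------------------------------------------------- ambulatory
    # per-patient date range for signal-carrying (comorbidity/procedure) events
    if config.signal_timing == "pre_onset":
        sig_hi = np.where(true_hf, np.maximum(onset, win_lo), win_hi)
        sig_lo = np.full(n, win_lo)
    elif config.signal_timing == "pre_washout":
        cap = np.where(coded, first_i50 - 366, np.where(true_hf, onset, win_hi))
        sig_hi = np.maximum(cap, win_lo)
        sig_lo = np.full(n, win_lo)
    else:  # washout_only
        sig_hi = np.where(coded, np.maximum(first_i50 - 1, win_lo), win_hi)
        sig_lo = np.where(coded, np.maximum(first_i50 - 365, win_lo), win_lo)
    sig_hi = np.maximum(sig_hi, sig_lo)

    ev_pid, ev_date, ev_icd, ev_proc = [], [], [], []

    def _emit(owner_idx, dates, icds, procs):
        ev_pid.append(ids[owner_idx])
        ev_date.append(dates)
        ev_icd.append(icds)
        ev_proc.append(procs)

    n_years = (win_hi - win_lo + 1) / 365.25

    def _emit_feature(base: float, shift: float, icd_code: str, proc):
        """Additive presence model: a baseline component affecting every
        patient identically (dated uniform over the whole window) plus an
        elevation component only among true HF, dated per signal_timing.
        Overall presence probability among true HF equals
        expit(logit(base) + shift), so the planted presence odds ratio is
        exp(shift)."""
        p_hf = float(_expit(_logit(base) + shift))
        if p_hf >= base:
            present_base = rng.random(n) < base
            extra_prob = (p_hf - base) / (1.0 - base)
            present_extra = true_hf & (rng.random(n) < extra_prob) & ~present_base
        else:  # protective effect: thin the baseline among true HF
            p = np.where(true_hf, p_hf, base)
            present_base = rng.random(n) < p
            present_extra = np.zeros(n, dtype=bool)
        for present, lo, hi in (
            (present_base, np.full(n, win_lo), np.full(n, win_hi)),
            (present_extra, sig_lo, sig_hi),
        ):
            idx = np.flatnonzero(present)
            if not len(idx):
                continue
            counts = 1 + rng.poisson(config.extra_events_mean, size=len(idx))
            owner = np.repeat(idx, counts)
            dates = rng.integers(lo[owner], hi[owner] + 1)
            _emit(owner, dates, np.full(len(owner), icd_code),
                  np.full(len(owner), proc, dtype=object))

    for code in sorted(config.comorbidity_rates):
        _emit_feature(config.comorbidity_rates[code],
                      config.comorbidity_hf_shift.get(code, 0.0),
                      code + "9", None)

    for proc in sorted(config.procedure_rates):
        _emit_feature(config.procedure_rates[proc],
                      config.procedure_hf_shift.get(proc, 0.0),
                      PROCEDURE_JUSTIFICATION_ICD, proc)

    # background billing noise over the whole extraction window
    bg_counts = rng.poisson(config.background_events_per_year * n_years, size=n)
    owner = np.repeat(np.arange(n), bg_counts)
    if len(owner):
        dates = rng.integers(win_lo, win_hi + 1, size=len(owner))
        codes = rng.choice(NOISE_ICDS, size=len(owner))
        _emit(owner, dates, codes, np.full(len(owner), None, dtype=object))

    # I50 events for coded patients: one at first_i50, possible repeats after
    idx = np.flatnonzero(coded)
    if len(idx):
        _emit(idx, first_i50[idx], np.full(len(idx), "I500"),
              np.full(len(idx), None, dtype=object))
        repeats = rng.poisson(1.0, size=len(idx))
        owner = np.repeat(idx, repeats)
        if len(owner):
            lo = np.repeat(first_i50[idx], repeats)
            dates = rng.integers(lo, win_hi + 1)
            _emit(owner, dates, np.full(len(owner), "I500"),
                  np.full(len(owner), None, dtype=object))

    events = pd.DataFrame({
        "patient_id": np.concatenate(ev_pid),
        "event_date": _dates_from_ordinals(np.concatenate(ev_date)),
        "icd10": np.concatenate(ev_icd),
        "procedure": np.concatenate(ev_proc),
    }).sort_values(["patient_id", "event_date"], kind="stable").reset_index(drop=True)

    # ---------------------------------------------------------------- mortality
    span_years = config.study_years[1] - config.study_years[0] + 1
    annual = np.where(
        true_hf,
        np.minimum(config.annual_death_rate * config.hf_death_rate_multiplier, 1.0),
        config.annual_death_rate,
    )
    p_death = 1.0 - (1.0 - annual) ** span_years
    died = rng.random(n) < p_death
    death_lo = np.where(true_hf, np.maximum(onset, study_lo), study_lo)
    death_date = np.where(died, rng.integers(death_lo, win_hi + 1, size=n), -1)
    true_hf_death = died & true_hf
    masked = true_hf_death & (rng.random(n) < config.hf_death_masking_probability)

    masked_codes = np.array(sorted(config.masked_code_weights))
    masked_w = np.array([config.masked_code_weights[c] for c in masked_codes])
    masked_w = masked_w / masked_w.sum()

    d_idx = np.flatnonzero(died)
    underlying = np.empty(len(d_idx), dtype=object)
    line_a = [[] for _ in d_idx]
    part2 = [[] for _ in d_idx]
    for j, i in enumerate(d_idx):
        if true_hf_death[i] and not masked[i]:
            underlying[j] = "I500"
            line_a[j] = ["I500"]
        elif masked[i]:
            code = rng.choice(masked_codes, p=masked_w)
            underlying[j] = code
            line_a[j] = [code]  # mortality-set emission on Part I
        else:
            underlying[j] = rng.choice(NON_HF_DEATH_ICDS)
            if rng.random() < config.non_hf_cardiac_line_rate:
                line_a[j] = [str(rng.choice(masked_codes))]

    age_at_death = np.round(
        np.clip(age[d_idx] + rng.normal(5.0, 3.0, size=len(d_idx)), 18, 110), 1
    )
    deaths = pd.DataFrame({
        "person_id": ids[d_idx],
        "death_date": _dates_from_ordinals(death_date[d_idx]),
        "age_at_death": age_at_death,
        "sex": sex[d_idx],
        "underlying_cause": underlying,
        "line_a": line_a,
        "line_b": [[] for _ in d_idx],
        "line_c": [[] for _ in d_idx],
        "line_d": [[] for _ in d_idx],
        "part2": part2,
    })

    latent = pd.DataFrame({
        "patient_id": ids,
        "true_hf": true_hf,
        "hf_onset_date": [date.fromordinal(int(o)) if o > 0 else None for o in onset],
        "first_i50_date": [date.fromordinal(int(o)) if o > 0 else None for o in first_i50],
        "died": died,
        "true_hf_death": true_hf_death,
    })

    return events, deaths, demographics, latent
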