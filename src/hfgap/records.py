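"""Domain types and tabular I/O for claims and mortality records.

Records mirror the two Brazilian administrative streams this package
models: ambulatory billing events (one row per procedure/consultation,
carrying the justifying ICD-10 code) and death certificates (an underlying
cause plus the Part I causal-chain lines A-D and Part II contributing
conditions). All flowchart logic downstream operates on ICD-10 codes at
the 3-character prefix level; subcodes (e.g. I500) match their parent
prefix (I50).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}([0-9]{1,2})?$")

#: Closed procedure vocabulary used by the synthetic generator and the
#: ambulatory trigger set. Real SIGTAP procedure codes are out of scope.
PROCEDURES = (
    "ECHO",        # transthoracic echocardiography
    "BNP",         # BNP / NT-proBNP assay
    "CATH",        # cardiac catheterisation
    "ERGO",        # ergospirometry
    "CHAGAS_SERO", # Trypanosoma cruzi serology
    "ECG",         # electrocardiogram
    "ABPM",        # ambulatory blood pressure monitoring
    "OTHER",
)

PART1_LINES = ("A", "B", "C", "D")

EVENT_COLUMNS = ["patient_id", "event_date", "icd10", "procedure"]
DEATH_COLUMNS = [
    "person_id", "death_date", "age_at_death", "sex", "underlying_cause",
    "line_a", "line_b", "line_c", "line_d", "part2",
]
DEMOGRAPHICS_COLUMNS = ["patient_id", "age", "sex", "race", "height", "weight"]


class MalformedCodeError(ValueError):
    """Raised for an ICD-10 string that cannot be normalized.

    The offending original string is retained on ``.original``.
    """

    def __init__(self, original: str):
        self.original = original
        super().__init__(f"malformed ICD-10 code: {original!r}")


class SchemaError(ValueError):
    """Raised when a table is missing a mandatory column."""


def normalize_icd(code: str) -> str:
    """Normalize a raw ICD-10 string: uppercase, strip the dot, validate.

    >>> normalize_icd("i50.0")
    'I500'

    Raises :class:`MalformedCodeError` if the result does not match
    ``[A-Z][0-9]{2}([0-9]{1,2})?``. Idempotent on valid input.
    """
    if not isinstance(code, str) or not code.strip():
        raise MalformedCodeError(code)
    cleaned = code.strip().upper().replace(".", "")
    if not ICD10_PATTERN.match(cleaned):
        raise MalformedCodeError(code)
    return cleaned


@dataclass(frozen=True)
class CodeSet:
    """A named set of 3-character ICD-10 prefixes, inclusive prefix ranges,
    and procedure identifiers, used as flowchart trigger criteria."""

    name: str
    prefixes: tuple[str, ...] = ()
    ranges: tuple[tuple[str, str], ...] = ()
    procedures: tuple[str, ...] = ()

    def __post_init__(self):
        for p in self.prefixes:
            if len(p) != 3:
                raise ValueError(f"prefix must be 3 characters: {p!r}")
        for start, end in self.ranges:
            if len(start) != 3 or len(end) != 3:
                raise ValueError(f"range endpoints must be 3 characters: {start!r}-{end!r}")
            if start[0] != end[0]:
                raise ValueError(f"range must stay within one letter block: {start!r}-{end!r}")
            if start > end:
                raise ValueError(f"range start after end: {start!r}-{end!r}")

    def contains_icd(self, code: str) -> bool:
        """True iff the code's 3-character prefix is in the set."""
        prefix = code[:3]
        if prefix in self.prefixes:
            return True
        return any(start <= prefix <= end for start, end in self.ranges)

    def contains_procedure(self, procedure: str) -> bool:
        return procedure in self.procedures

    def all_prefixes(self) -> tuple[str, ...]:
        """Enumerate every 3-character prefix covered by the set."""
        out = list(self.prefixes)
        for start, end in self.ranges:
            letter = start[0]
            for num in range(int(start[1:]), int(end[1:]) + 1):
                out.append(f"{letter}{num:02d}")
        return tuple(dict.fromkeys(out))

    @classmethod
    def from_dict(cls, d: Mapping) -> "CodeSet":
        return cls(
            name=d["name"],
            prefixes=tuple(d.get("prefixes", ())),
            ranges=tuple((s, e) for s, e in d.get("ranges", ())),
            procedures=tuple(d.get("procedures", ())),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "prefixes": list(self.prefixes),
            "ranges": [list(r) for r in self.ranges],
            "procedures": list(self.procedures),
        }


def icd_matches(code: str, cs: CodeSet) -> bool:
    """True iff the normalized code's 3-character prefix is covered by
    ``cs`` (exact prefix or inclusive range)."""
    return cs.contains_icd(code)


def load_codesets(path: str | Path | None = None) -> dict[str, CodeSet]:
    """Load named code sets from a JSON file.

    With no path, loads the package's shipped definitions: the ambulatory
    trigger ICDs (I21, I25, I42, I48), the ambulatory trigger procedures
    (BNP, echocardiography, catheterisation, ergospirometry, Chagas
    serology), and the mortality search set (B57, I05-I08, I21-I25,
    I34-I39, I42-I44, I48, I49, I51).
    """
    if path is None:
        text = resources.files("hfgap.data").joinpath("codesets.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    return {name: CodeSet.from_dict(d) for name, d in raw.items()}


def save_codesets(codesets: Mapping[str, CodeSet], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: v.to_dict() for k, v in codesets.items()}, indent=2)
    )


# ---------------------------------------------------------------------------
# Tabular I/O. Fixed CSV dialect: comma, UTF-8, ISO-8601 dates, header row.
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing mandatory column(s): {missing}")


def _read_table(path: str | Path, fmt: str | None, date_cols: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    fmt = fmt or ("parquet" if path.suffix == ".parquet" else "csv")
    if fmt == "parquet":
        df = pd.read_parquet(path)
    elif fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    else:
        raise ValueError(f"unsupported format: {fmt}")
    for col in date_cols:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col]).dt.date
    return df


def _write_table(df: pd.DataFrame, path: str | Path, fmt: str | None) -> None:
    path = Path(path)
    fmt = fmt or ("parquet" if path.suffix == ".parquet" else "csv")
    if fmt == "parquet":
        df.to_parquet(path, index=False)
    elif fmt == "csv":
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported format: {fmt}")


def read_events(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read an ambulatory event table (patient_id, event_date, icd10,
    procedure); ICD codes are normalized on ingest."""
    df = _read_table(path, fmt, ["event_date"])
    _require_columns(df, ["patient_id", "event_date", "icd10"], "events")
    if "procedure" not in df.columns:
        df["procedure"] = None
    df["procedure"] = df["procedure"].astype(object).where(df["procedure"].notna(), None)
    df["icd10"] = df["icd10"].map(normalize_icd)
    return df[EVENT_COLUMNS]


def write_events(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    _require_columns(df, ["patient_id", "event_date", "icd10"], "events")
    _write_table(df[EVENT_COLUMNS], path, fmt)


def _split_codes(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    if isinstance(cell, list):
        return [normalize_icd(c) for c in cell]
    return [normalize_icd(c) for c in str(cell).split(";") if c]


def read_deaths(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a death-certificate table.

    Part I lines A-D and Part II are stored as semicolon-joined code lists
    in columns ``line_a``..``line_d`` and ``part2``; they come back as
    Python lists of normalized codes.
    """
    df = _read_table(path, fmt, ["death_date"])
    _require_columns(
        df, ["person_id", "death_date", "underlying_cause"], "deaths"
    )
    for col in ["line_a", "line_b", "line_c", "line_d", "part2"]:
        if col not in df.columns:
            df[col] = None
        df[col] = df[col].map(_split_codes)
    df["underlying_cause"] = df["underlying_cause"].map(normalize_icd)
    if "age_at_death" in df.columns:
        df["age_at_death"] = pd.to_numeric(df["age_at_death"])
    for col in DEATH_COLUMNS:
        if col not in df.columns:
            df[col] = None
    return df[DEATH_COLUMNS]


def write_deaths(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    _require_columns(df, ["person_id", "death_date", "underlying_cause"], "deaths")
    out = df.copy()
    for col in ["line_a", "line_b", "line_c", "line_d", "part2"]:
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: ";".join(v) if isinstance(v, (list, tuple)) else (v or "")
            )
    _write_table(out[[c for c in DEATH_COLUMNS if c in out.columns]], path, fmt)


def read_demographics(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a demographics table; derives ``bmi = weight / height**2``
    where both anthropometrics are present."""
    df = _read_table(path, fmt, [])
    _require_columns(df, ["patient_id"], "demographics")
    for col in DEMOGRAPHICS_COLUMNS:
        if col not in df.columns:
            df[col] = None
    for col in ["age", "height", "weight"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df[DEMOGRAPHICS_COLUMNS].copy()
    df["bmi"] = compute_bmi(df["weight"], df["height"])
    return df


def write_demographics(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    _require_columns(df, ["patient_id"], "demographics")
    cols = [c for c in DEMOGRAPHICS_COLUMNS if c in df.columns]
    _write_table(df[cols], path, fmt)


def compute_bmi(weight: pd.Series, height: pd.Series) -> pd.Series:
    """Body-mass index in kg/m² from weight (kg) and height (m)."""
    return weight / (height ** 2)
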