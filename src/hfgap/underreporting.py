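"""Deterministic sensitivity analysis of HF underreporting.

Given a year's diagnosed count D (patients or deaths carrying an I50
code) and potential count P (records meeting the proxy criteria with no
I50), and an assumed identification proportion p — the fraction of
potential records that are genuinely HF — the underestimation rate is

    U(p) = p·P / (D + p·P)

i.e. the share of the assumed true caseload (D + p·P) that official I50
counts miss. p = 0 is the best case (no potential record is real HF,
U = 0) and p = 1 the worst case (U = P / (D + P)). The algebraic form was
reconstructed from the published worked scenario values (12%, 35%, 41%,
63% for the 2018 counts), which it reproduces exactly; this reconstruction
is the module's central assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

ALL_YEARS = "ALL_YEARS"
DEFAULT_PS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class YearlyCounts:
    year: int
    diagnosed: int
    potential: int
    stream: str  # AMBULATORY or MORTALITY

    def __post_init__(self):
        if self.diagnosed < 0 or self.potential < 0:
            raise ValueError("counts must be non-negative")


def underestimation_rate(diagnosed: float, potential: float, p: float) -> float:
    """U(p) = p·P / (D + p·P); raises for an all-zero denominator."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"identification proportion must be in [0, 1]: {p}")
    if diagnosed < 0 or potential < 0:
        raise ValueError("counts must be non-negative")
    denom = diagnosed + p * potential
    if denom == 0:
        raise ZeroDivisionError("D + p*P = 0: underestimation rate undefined")
    return p * potential / denom


def percent_round(fraction: float) -> int:
    """Half-up rounding of a fraction to a whole percent, matching the
    published reporting style."""
    return int(math.floor(fraction * 100 + 0.5))


def load_paper_tables(path: str | Path | None = None) -> pd.DataFrame:
    """Load the published yearly descriptive tables (diagnosed and
    potential counts per stream and year, 2018-2022) shipped with the
    package, or an equivalently shaped CSV."""
    if path is None:
        with resources.files("hfgap.data").joinpath("paper_tables.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def counts_from_table(table: pd.DataFrame) -> list[YearlyCounts]:
    """Pivot a long descriptive table (stream, label, year, n) into
    per-year diagnosed/potential count pairs."""
    out = []
    wide = table.pivot_table(index=["stream", "year"], columns="label",
                             values="n", aggfunc="sum")
    for (stream, year), row in wide.iterrows():
        out.append(YearlyCounts(
            year=int(year),
            diagnosed=int(row["DIAGNOSED"]),
            potential=int(row["POTENTIAL"]),
            stream=stream,
        ))
    return out


def scenario_grid(
    counts: Sequence[YearlyCounts],
    ps: Iterable[float] = DEFAULT_PS,
) -> pd.DataFrame:
    """One row per (stream, year, p) plus a pooled ALL_YEARS row per
    (stream, p) using summed counts; rates reported both as fractions and
    as whole-percent half-up roundings."""
    counts = list(counts)
    if not counts:
        raise ValueError("counts must be non-empty")
    rows = []
    streams = sorted({c.stream for c in counts})
    for stream in streams:
        sub = [c for c in counts if c.stream == stream]
        pooled_d = sum(c.diagnosed for c in sub)
        pooled_p = sum(c.potential for c in sub)
        for p in ps:
            for c in sub:
                u = underestimation_rate(c.diagnosed, c.potential, p)
                rows.append({
                    "stream": stream, "year": c.year, "p": p,
                    "diagnosed": c.diagnosed, "potential": c.potential,
                    "underestimation_rate": u,
                    "underestimation_pct": percent_round(u),
                })
            u = underestimation_rate(pooled_d, pooled_p, p)
            rows.append({
                "stream": stream, "year": ALL_YEARS, "p": p,
                "diagnosed": pooled_d, "potential": pooled_p,
                "underestimation_rate": u,
                "underestimation_pct": percent_round(u),
            })
    return pd.DataFrame(rows)


def validate_against_truth(
    latent: pd.DataFrame,
    phenotypes: pd.DataFrame,
    stream: str = "AMBULATORY",
) -> tuple[float, float]:
    """Close the loop on synthetic data: recover the empirical
    identification proportion and underestimation rate from the latent
    table, and assert the deterministic formula reproduces the brute-force
    count.

    Returns ``(p_hat, empirical_underestimation)`` where p_hat is the
    fraction of POTENTIAL-labelled records that are latently true HF and
    the empirical rate is true-but-uncoded / (coded + true-but-uncoded),
    counting only potential records that are truly HF as uncoded.
    """
    if stream == "AMBULATORY":
        truth_col, pot_label, diag_label = "true_hf", "POTENTIAL_HF", "DIAGNOSED_HF"
        id_col = "patient_id"
    else:
        truth_col, pot_label, diag_label = "true_hf_death", "POTENTIAL_HF_DEATH", "HF_DEATH"
        id_col = "person_id"

    merged = phenotypes.merge(
        latent.rename(columns={"patient_id": id_col}), on=id_col, how="left"
    )
    potential = merged[merged["label"] == pot_label]
    if len(potential) == 0:
        raise ValueError("no potential records: empirical p undefined")
    diagnosed_n = int((merged["label"] == diag_label).sum())
    p_hat = float(potential[truth_col].fillna(False).mean())
    true_uncoded = int(potential[truth_col].fillna(False).sum())
    empirical = true_uncoded / (diagnosed_n + true_uncoded)

    formula = underestimation_rate(diagnosed_n, len(potential), p_hat)
    if not math.isclose(formula, empirical, rel_tol=0, abs_tol=1e-9):
        raise AssertionError(
            f"formula U={formula} disagrees with brute-force count {empirical}"
        )
    return p_hat, empirical
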