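"""Discrimination and calibration metrics, implemented from their
definitions.

Discrimination: ROC AUC (rank/concordance form, ties counted half),
confusion matrices and the derived rates. Calibration: Brier score, ECE
and MCE over probability bins, the Hosmer-Lemeshow grouped chi-square,
recalibration slope/intercept from a logistic fit of outcomes on
logit-transformed predictions, and decile calibration curves. Model-level
diagnostics: learning curves and permutation importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, rankdata

logger = logging.getLogger(__name__)


def _check_scores(scores) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    if s.size and (s.min() < 0 or s.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    return s


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve.

    Computed in the rank (Mann-Whitney) form, which equals both the
    trapezoidal area and the pairwise concordance probability
    P(score_case > score_control) + ½·P(tie). Raises if only one class is
    present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class DiscriminationReport:
    auc: float
    accuracy: float
    recall: float
    precision: float
    f1: float
    specificity: float
    npv: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int


def confusion_and_rates(scores, labels, threshold: float = 0.5) -> DiscriminationReport:
    """Confusion matrix at a threshold and all derived rates.

    Rates with a zero denominator are reported as NaN (not available),
    never as zero.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    def _rate(num, den):
        return num / den if den > 0 else float("nan")

    recall = _rate(tp, tp + fn)
    precision = _rate(tp, tp + fp)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else float("nan"))
    try:
        auc = roc_auc(s, y)
    except ValueError:
        auc = float("nan")
    return DiscriminationReport(
        auc=auc,
        accuracy=_rate(tp + tn, len(y)),
        recall=recall,
        precision=precision,
        f1=f1,
        specificity=_rate(tn, tn + fp),
        npv=_rate(tn, tn + fn),
        threshold=threshold,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def brier(scores, labels) -> float:
    """Mean squared difference between predicted probabilities and
    observed binary outcomes."""
    s = _check_scores(scores)
    y = np.asarray(labels).astype(float)
    return float(np.mean((s - y) ** 2))


def _bin_edges(scores: np.ndarray, n_bins: int, scheme: str) -> np.ndarray:
    if scheme == "equal_width":
        return np.linspace(0.0, 1.0, n_bins + 1)
    if scheme == "quantile":
        edges = np.quantile(scores, np.linspace(0.0, 1.0, n_bins + 1))
        edges[0], edges[-1] = 0.0, 1.0
        return np.unique(edges)
    raise ValueError(f"unknown binning scheme: {scheme!r}")


def ece_mce(scores, labels, n_bins: int = 10, scheme: str = "equal_width") -> tuple[float, float]:
    """Expected and maximum calibration error over probability bins.

    ECE is the bin-size-weighted mean of |mean predicted − observed rate|;
    MCE the maximum of the same deviation over non-empty bins (empty bins
    are skipped). Invariant: ECE ≤ MCE.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    s = _check_scores(scores)
    y = np.asarray(labels).astype(float)
    edges = _bin_edges(s, n_bins, scheme)
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, len(edges) - 2)
    ece, mce = 0.0, 0.0
    n = len(s)
    for b in range(len(edges) - 1):
        mask = idx == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        gap = abs(float(s[mask].mean()) - float(y[mask].mean()))
        ece += nb / n * gap
        mce = max(mce, gap)
    return ece, mce


class CalibrationFit(NamedTuple):
    slope: float
    intercept: float
    #: intercept of the offset model with the slope fixed at 1
    calibration_in_the_large: float


def calibration_slope_intercept(scores, labels, clip: float = 1e-6) -> CalibrationFit:
    """Maximum-likelihood logistic fit of outcomes on logit-transformed
    predictions: label ~ a + b·logit(score).

    (b, a) = (1, 0) is ideal calibration. Also reports
    calibration-in-the-large: the intercept refit with b fixed at 1.
    Scores are clipped to [clip, 1−clip] before the logit; a degenerate
    (constant-logit) design raises.
    """
    s = np.clip(_check_scores(scores), clip, 1.0 - clip)
    y = np.asarray(labels).astype(float)
    lg = np.log(s / (1.0 - s))
    if np.ptp(lg) == 0:
        raise ValueError("degenerate design: all logit-scores identical")
    x = sm.add_constant(lg)
    fit = sm.Logit(y, x).fit(disp=0)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(f"recalibration fit did not converge: {fit.mle_retvals}")
    citl_fit = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                      offset=lg).fit()
    return CalibrationFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        calibration_in_the_large=float(citl_fit.params[0]),
    )


def hosmer_lemeshow(
    scores, labels, groups: int = 10, n_fitted_params: int = 2
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow grouped goodness-of-fit test.

    Groups are score quantiles (ties kept together); per group the
    contribution is (O−E)² / (E·(1−E/n)); groups with E = 0 or E = n are
    merged into their neighbour. Returns (statistic, df, upper-tail
    chi-square p-value).

    ``n_fitted_params`` sets the reference distribution: the conventional
    df = groups − 2 (default) applies when the scores come from a model
    fitted on these same data; for external validation — scores produced
    without estimating anything on the evaluated labels — the statistic is
    referred to χ²(groups), i.e. ``n_fitted_params=0``, which is what
    keeps the p-value uniform under a correctly calibrated model.
    """
    if groups < 3:
        raise ValueError("groups must be >= 3")
    if not 0 <= n_fitted_params < groups:
        raise ValueError("n_fitted_params must be in [0, groups)")
    s = _check_scores(scores)
    y = np.asarray(labels).astype(float)
    bins = pd.qcut(s, q=groups, duplicates="drop")
    table = pd.DataFrame({"s": s, "y": y, "g": bins.codes}).groupby("g").agg(
        n=("y", "size"), obs=("y", "sum"), exp=("s", "sum"))
    # merge degenerate groups (all-expected or none-expected) upward
    merged = []
    for _, row in table.iterrows():
        if merged and (merged[-1]["exp"] <= 0 or merged[-1]["exp"] >= merged[-1]["n"]):
            logger.info("merging degenerate Hosmer-Lemeshow group into neighbour")
            for k in ("n", "obs", "exp"):
                merged[-1][k] += row[k]
        else:
            merged.append(row[["n", "obs", "exp"]].to_dict())
    if len(merged) > 1 and (merged[-1]["exp"] <= 0 or merged[-1]["exp"] >= merged[-1]["n"]):
        last = merged.pop()
        for k in ("n", "obs", "exp"):
            merged[-1][k] += last[k]
    stat = 0.0
    for row in merged:
        e, n, o = row["exp"], row["n"], row["obs"]
        stat += (o - e) ** 2 / (e * (1 - e / n))
    df = len(merged) - n_fitted_params
    return float(stat), int(df), float(chi2.sf(stat, df))


def calibration_curve(scores, labels, groups: int = 10) -> list[tuple[float, float, int]]:
    """Decile calibration curve: (mean predicted, observed rate, n) per
    score-quantile group."""
    s = _check_scores(scores)
    y = np.asarray(labels).astype(float)
    bins = pd.qcut(s, q=groups, duplicates="drop")
    out = []
    for _, grp in pd.DataFrame({"s": s, "y": y, "g": bins.codes}).groupby("g"):
        out.append((float(grp["s"].mean()), float(grp["y"].mean()), int(len(grp))))
    return out


@dataclass(frozen=True)
class CalibrationReport:
    brier: float
    ece: float
    mce: float
    hl_statistic: float
    hl_df: int
    hl_pvalue: float
    slope: float
    intercept: float
    calibration_in_the_large: float
    curve: list = field(default_factory=list)
    n_bins: int = 10
    binning_scheme: str = "equal_width"


def calibration_report(
    scores, labels, n_bins: int = 10, scheme: str = "equal_width",
    hl_groups: int = 10,
) -> CalibrationReport:
    """All calibration metrics in one report; the binning scheme used is
    recorded alongside the values."""
    ece, mce = ece_mce(scores, labels, n_bins=n_bins, scheme=scheme)
    stat, df, p = hosmer_lemeshow(scores, labels, groups=hl_groups)
    fit = calibration_slope_intercept(scores, labels)
    return CalibrationReport(
        brier=brier(scores, labels),
        ece=ece, mce=mce,
        hl_statistic=stat, hl_df=df, hl_pvalue=p,
        slope=fit.slope, intercept=fit.intercept,
        calibration_in_the_large=fit.calibration_in_the_large,
        curve=calibration_curve(scores, labels, groups=hl_groups),
        n_bins=n_bins, binning_scheme=scheme,
    )


def learning_curve(
    features: pd.DataFrame,
    labels,
    spec,
    train_fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    seed: int = 0,
    holdout_fraction: float = 0.25,
) -> pd.DataFrame:
    """Train/validation AUC as a function of training-set size.

    A stratified holdout is fixed once; for each fraction a stratified
    subsample of the remaining rows is used for training. Returns a table
    of (fraction, n_train, train_auc, validation_auc).
    """
    from sklearn.model_selection import train_test_split

    from .model import FittedModel, crossval_train, predict_proba  # noqa: F401 (lazy; avoids cycle)
    from .model import _make_estimator, _matrix
    from .cohort import apply_preprocessor, fit_preprocessor

    y = np.asarray(labels).astype(int)
    idx = np.arange(len(y))
    train_idx, val_idx = train_test_split(
        idx, test_size=holdout_fraction, stratify=y, random_state=seed)
    rows = []
    rng = np.random.default_rng(seed)
    for frac in train_fractions:
        if not 0 < frac <= 1:
            raise ValueError("train fractions must be in (0, 1]")
        if frac < 1.0:
            sub, _ = train_test_split(
                train_idx, train_size=frac, stratify=y[train_idx],
                random_state=int(rng.integers(2**31)))
        else:
            sub = train_idx
        state = fit_preprocessor(features.iloc[sub])
        tr = apply_preprocessor(state, features.iloc[sub])
        va = apply_preprocessor(state, features.iloc[val_idx])
        x_tr, cols = _matrix(tr)
        x_va, _ = _matrix(va, cols)
        est = _make_estimator(spec)
        est.fit(x_tr, y[sub])
        rows.append({
            "fraction": frac,
            "n_train": len(sub),
            "train_auc": roc_auc(est.predict_proba(x_tr)[:, 1], y[sub]),
            "validation_auc": roc_auc(est.predict_proba(x_va)[:, 1], y[val_idx]),
        })
    return pd.DataFrame(rows)


def permutation_importance(
    model, features: pd.DataFrame, labels, n_repeats: int = 5, seed: int = 0,
) -> pd.DataFrame:
    """Mean AUC drop when one raw feature column is shuffled at a time.

    The native attribution method of this package (a SHAP explainer can be
    attached externally via the fitted estimator if desired). Deterministic
    given the seed.
    """
    from .model import predict_proba

    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    baseline = roc_auc(predict_proba(model, features), y)
    cols = [c for c in features.columns if c not in ("patient_id", "label")]
    rows = []
    for col in cols:
        drops = []
        for _ in range(n_repeats):
            shuffled = features.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            drops.append(baseline - roc_auc(predict_proba(model, shuffled), y))
        rows.append({"feature": col, "importance": float(np.mean(drops))})
    return pd.DataFrame(rows).sort_values("importance", ascending=False).reset_index(drop=True)
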