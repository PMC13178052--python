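"""Early-HF classifier training and tuning.

The primary learner is gradient boosting on the untransformed count
features (delegated to XGBoost behind the ``ModelSpec`` interface, with
the boosting hyperparameter vocabulary used throughout this package:
depth, learning_rate, iterations, l2_leaf_reg, border_count). An
L2-penalised logistic regression with class-balanced weights and
standardised predictors serves as the linear baseline.

Hyperparameter optimisation is two-stage: a broad uniform random search
(depth 1-10, learning_rate 0.01-1, iterations 100-1000, l2_leaf_reg
2-100, border_count 10-35) followed by Bayesian refinement on a narrowed
space (depth 5-10 integer, learning_rate 0.01-0.5 log-uniform, iterations
500-1000 integer, l2_leaf_reg 2-35 log-uniform, border_count 10-35
integer), warm-started from the random-search evaluations. The Bayesian
stage maximises expected improvement under a Gaussian-process surrogate.
All model selection uses stratified 5-fold cross-validation with
preprocessing refit inside each training fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .cohort import PreprocessorState, apply_preprocessor, fit_preprocessor
from .evaluation import confusion_and_rates, roc_auc

logger = logging.getLogger(__name__)

GRADIENT_BOOSTING = "GRADIENT_BOOSTING"
LOGISTIC_L2 = "LOGISTIC_L2"

#: the published final boosting configuration, shipped as a named preset
#: for structural reproducibility (not a claim about results on new data)
PAPER_DEFAULT_HYPERPARAMETERS = {
    "learning_rate": 0.083,
    "l2_leaf_reg": 25,
    "iterations": 900,
    "depth": 8,
    "border_count": 30,
}

#: (low, high, type, scale) per tunable; stage-1 broad random space
RANDOM_SPACE = {
    "depth": (1, 10, int, "uniform"),
    "learning_rate": (0.01, 1.0, float, "uniform"),
    "iterations": (100, 1000, int, "uniform"),
    "l2_leaf_reg": (2.0, 100.0, float, "uniform"),
    "border_count": (10, 35, int, "uniform"),
}
#: stage-2 narrowed Bayesian space
BAYESIAN_SPACE = {
    "depth": (5, 10, int, "uniform"),
    "learning_rate": (0.01, 0.5, float, "log-uniform"),
    "iterations": (500, 1000, int, "uniform"),
    "l2_leaf_reg": (2.0, 35.0, float, "log-uniform"),
    "border_count": (10, 35, int, "uniform"),
}

PARAM_ORDER = ("depth", "learning_rate", "iterations", "l2_leaf_reg", "border_count")


@dataclass(frozen=True)
class ModelSpec:
    family: str = GRADIENT_BOOSTING
    hyperparameters: Mapping[str, float] = field(
        default_factory=lambda: dict(PAPER_DEFAULT_HYPERPARAMETERS))
    seed: int = 0


@dataclass
class FittedModel:
    """A trained estimator bundled with the preprocessor state it was
    trained under and the exact feature columns it expects."""

    spec: ModelSpec
    estimator: object
    preprocessor_state: PreprocessorState
    feature_columns: list[str]


PreprocessorFactory = Callable[[pd.DataFrame], PreprocessorState]


def default_preprocessor_factory(standardize: bool = False) -> PreprocessorFactory:
    return lambda train_features: fit_preprocessor(train_features, standardize=standardize)


def _make_estimator(spec: ModelSpec):
    hp = spec.hyperparameters
    if spec.family == GRADIENT_BOOSTING:
        return XGBClassifier(
            max_depth=int(hp.get("depth", 6)),
            learning_rate=float(hp.get("learning_rate", 0.1)),
            n_estimators=int(hp.get("iterations", 300)),
            reg_lambda=float(hp.get("l2_leaf_reg", 3.0)),
            max_bin=max(int(hp.get("border_count", 32)), 2),
            tree_method="hist",
            n_jobs=1,
            random_state=spec.seed,
            eval_metric="logloss",
        )
    if spec.family == LOGISTIC_L2:
        # default penalty is L2; C controls its strength
        return LogisticRegression(
            C=float(hp.get("C", 1.0)),
            class_weight="balanced",
            max_iter=2000,
            random_state=spec.seed,
        )
    raise ValueError(f"unknown model family: {spec.family!r}")


def _matrix(processed: pd.DataFrame, columns: Sequence[str] | None = None) -> np.ndarray:
    cols = [c for c in processed.columns if c not in ("patient_id", "label")]
    if columns is not None:
        missing = [c for c in columns if c not in processed.columns]
        if missing:
            raise ValueError(f"feature table missing model features: {missing}")
        cols = list(columns)
    return processed[cols].to_numpy(dtype=float), cols


def crossval_train(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    spec: ModelSpec,
    preprocessor_factory: PreprocessorFactory | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, FittedModel]:
    """Stratified k-fold cross-validation with fold-internal preprocessing,
    followed by a final fit on all rows.

    ``features`` are raw (pre-imputation) per-patient vectors; the factory
    is called on each training fold so no validation fold's statistics
    ever leak into preprocessing. No rebalancing or resampling is applied
    within folds. Returns (per-fold metric table, final fitted model).
    """
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds minority class count {counts.min()}")
    factory = preprocessor_factory or default_preprocessor_factory(
        standardize=spec.family == LOGISTIC_L2)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, va) in enumerate(skf.split(features, y)):
        state = factory(features.iloc[tr])
        train_proc = apply_preprocessor(state, features.iloc[tr])
        val_proc = apply_preprocessor(state, features.iloc[va])
        x_tr, cols = _matrix(train_proc)
        x_va, _ = _matrix(val_proc, cols)
        est = _make_estimator(spec)
        est.fit(x_tr, y[tr])
        scores = est.predict_proba(x_va)[:, 1]
        rep = confusion_and_rates(scores, y[va])
        rows.append({
            "fold": fold,
            "auc": roc_auc(scores, y[va]),
            "accuracy": rep.accuracy,
            "recall": rep.recall,
            "f1": rep.f1,
        })
    metrics = pd.DataFrame(rows)

    state = factory(features)
    processed = apply_preprocessor(state, features)
    x, cols = _matrix(processed)
    est = _make_estimator(spec)
    est.fit(x, y)
    return metrics, FittedModel(spec, est, state, cols)


def predict_proba(model: FittedModel, features: pd.DataFrame) -> np.ndarray:
    """Score rows with a fitted model using its own preprocessor state.
    Deterministic given model and input; raises when model features are
    absent from the table."""
    state = model.preprocessor_state
    expected = set(state.medians) | set(state.modes)
    missing = sorted(expected - set(features.columns))
    if missing:
        raise ValueError(f"feature table missing model features: {missing}")
    processed = apply_preprocessor(model.preprocessor_state, features)
    x, _ = _matrix(processed, model.feature_columns)
    return model.estimator.predict_proba(x)[:, 1]


def fit_logistic_baseline(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    seed: int = 0,
) -> FittedModel:
    """L2-penalised logistic regression with class-balanced weights on
    standardised predictors. Constant (zero-variance) features are dropped
    with a warning."""
    y = np.asarray(labels).astype(int)
    state = fit_preprocessor(features, standardize=True)
    processed = apply_preprocessor(state, features)
    x, cols = _matrix(processed)
    keep = x.std(axis=0) > 0
    dropped = [c for c, k_ in zip(cols, keep) if not k_]
    if dropped:
        logger.warning("dropping constant feature(s): %s", dropped)
    cols = [c for c, k_ in zip(cols, keep) if k_]
    spec = ModelSpec(family=LOGISTIC_L2, hyperparameters={"C": 1.0}, seed=seed)
    est = _make_estimator(spec)
    est.fit(x[:, keep], y)
    return FittedModel(spec, est, state, cols)


# ---------------------------------------------------------------------------
# Two-stage hyperparameter search
# ---------------------------------------------------------------------------

def _sample_space(space: Mapping, rng: np.random.Generator) -> dict:
    out = {}
    for name, (lo, hi, typ, scale) in space.items():
        if typ is int:
            out[name] = int(rng.integers(lo, hi + 1))
        elif scale == "log-uniform":
            out[name] = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        else:
            out[name] = float(rng.uniform(lo, hi))
    return out


def _to_unit(params: Mapping, space: Mapping) -> np.ndarray:
    x = []
    for name in PARAM_ORDER:
        lo, hi, typ, scale = space[name]
        v = float(params[name])
        if scale == "log-uniform":
            x.append((math.log(v) - math.log(lo)) / (math.log(hi) - math.log(lo)))
        else:
            x.append((v - lo) / (hi - lo))
    return np.clip(x, 0.0, 1.0)


def _from_unit(x: np.ndarray, space: Mapping) -> dict:
    out = {}
    for xi, name in zip(x, PARAM_ORDER):
        lo, hi, typ, scale = space[name]
        if scale == "log-uniform":
            v = math.exp(math.log(lo) + xi * (math.log(hi) - math.log(lo)))
        else:
            v = lo + xi * (hi - lo)
        out[name] = int(round(v)) if typ is int else float(v)
    return out


def two_stage_search(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    budget_random: int = 20,
    budget_bayes: int = 20,
    seed: int = 0,
    k: int = 5,
    random_space: Mapping = RANDOM_SPACE,
    bayesian_space: Mapping = BAYESIAN_SPACE,
    preprocessor_factory: PreprocessorFactory | None = None,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Random search over the broad space, then expected-improvement
    Bayesian refinement over the narrowed space, both scored by mean
    cross-validated AUC. Returns the best boosting spec and the full
    evaluation trace (stage, hyperparameters, mean_auc)."""
    if budget_random < 1 or budget_bayes < 0:
        raise ValueError("budgets must be >= 1 (random) and >= 0 (bayes)")
    rng = np.random.default_rng(seed)
    y = np.asarray(labels).astype(int)
    trace = []

    def _evaluate(params: dict, stage: str) -> float:
        spec = ModelSpec(GRADIENT_BOOSTING, params, seed=seed)
        metrics, _ = crossval_train(
            features, y, spec, preprocessor_factory, k=k, seed=seed)
        mean_auc = float(metrics["auc"].mean())
        trace.append({"stage": stage, **params, "mean_auc": mean_auc})
        return mean_auc

    for _ in range(budget_random):
        _evaluate(_sample_space(random_space, rng), "RANDOM")

    # warm start: project stage-1 evaluations into the narrowed space
    xs, ys = [], []
    for row in trace:
        params = {name: row[name] for name in PARAM_ORDER}
        clipped = {}
        for name in PARAM_ORDER:
            lo, hi, typ, _ = bayesian_space[name]
            v = min(max(params[name], lo), hi)
            clipped[name] = int(round(v)) if typ is int else float(v)
        xs.append(_to_unit(clipped, bayesian_space))
        ys.append(row["mean_auc"])

    for _ in range(budget_bayes):
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), alpha=1e-4, normalize_y=True,
            random_state=int(rng.integers(2**31)))
        gp.fit(np.vstack(xs), np.asarray(ys))
        candidates = rng.random((256, len(PARAM_ORDER)))
        mu, sigma = gp.predict(candidates, return_std=True)
        best = max(ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / sigma
            ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
            ei[sigma <= 0] = 0.0
        x_next = candidates[int(np.argmax(ei))]
        params = _from_unit(x_next, bayesian_space)
        auc = _evaluate(params, "BAYESIAN")
        xs.append(_to_unit(params, bayesian_space))
        ys.append(auc)

    trace_df = pd.DataFrame(trace)
    best_row = trace_df.loc[trace_df["mean_auc"].idxmax()]
    best_params = {name: best_row[name] for name in PARAM_ORDER}
    for name in PARAM_ORDER:
        lo, hi, typ, _ = (random_space | dict(bayesian_space)).get(name)
        if typ is int:
            best_params[name] = int(best_params[name])
    return ModelSpec(GRADIENT_BOOSTING, best_params, seed=seed), trace_df
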