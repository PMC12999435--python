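"""Discrimination, calibration, decision-analytic and internal validation tools.

Implements the standard TRIPOD-style validation layer: ROC analysis with
DeLong confidence intervals and Youden operating points, one-vs-rest
composite classifiers, permutation variable importance, decile-binned
calibration with intercept/slope, decision-curve net benefit, Harrell's
bootstrap optimism correction, and repeated stratified k-fold CV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import logit as _logit
from scipy.stats import norm, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortError

log = logging.getLogger(__name__)


def auc_score(scores, labels) -> float:
    """AUC as probability of concordance with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise CohortError("AUC needs both classes")
    ranks = rankdata(scores)  # midranks handle ties with half credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via midrank structural components."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = rankdata(np.concatenate([pos, neg]))
    r_pos, r_neg = rankdata(pos), rankdata(neg)
    v10 = (all_r[:m] - r_pos) / n  # P(neg < pos_i), ties half-weighted
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_auc(scores, binary_labels, alpha: float = 0.05) -> ROCResult:
    """ROC curve, AUC with DeLong CI, and the Youden-optimal operating point.

    All empirical cutpoints are enumerated; a sample is called positive when
    its score is >= the threshold. Ties in the Youden index resolve to the
    lowest qualifying threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(int)
    auc = auc_score(scores, y)
    var = _delong_variance(scores, y)
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())

    cuts = np.concatenate([np.unique(scores), [np.inf]])
    sens = np.array([(scores[y == 1] >= t).mean() for t in cuts])
    spec = np.array([(scores[y == 0] < t).mean() for t in cuts])
    j = sens + spec - 1.0
    best = int(np.argmax(j))
    return ROCResult(
        thresholds=cuts,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        youden_threshold=float(cuts[best]),
        youden_sensitivity=float(sens[best]),
        youden_specificity=float(spec[best]),
    )


# ---------------------------------------------------------------------------
# Composite models
# ---------------------------------------------------------------------------


@dataclass
class CompositeModel:
    """Fitted classifier with normalized class-probability output."""

    kind: str
    classes_: np.ndarray
    feature_names: list[str]
    _models: object

    def predict_proba(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = (
            features[self.feature_names].to_numpy(dtype=float)
            if isinstance(features, pd.DataFrame)
            else np.asarray(features, dtype=float)
        )
        if self.kind == "ovr_logistic":
            cols = [m.predict_proba(X)[:, 1] for m in self._models]
            probs = np.column_stack(cols)
            probs /= probs.sum(axis=1, keepdims=True)
            return probs
        return self._models.predict_proba(X)

    def predict(self, features) -> np.ndarray:
        probs = self.predict_proba(features)
        return self.classes_[np.argmax(probs, axis=1)]


def fit_composite_model(
    features: pd.DataFrame,
    classes: pd.Series | np.ndarray,
    kind: str = "ovr_logistic",
    seed: int = 0,
) -> CompositeModel:
    """Fit a one-vs-rest logistic or random-forest classifier.

    One-vs-rest logistic fits one binary model per class and renormalizes the
    per-class probabilities to sum to one. Deterministic per seed.
    """
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise CohortError("non-finite feature values")
    y = np.asarray(classes)
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2 or counts.min() < 2:
        raise CohortError("need >=2 classes with >=2 members each")
    if kind == "ovr_logistic":
        models = [
            LogisticRegression(max_iter=2000, random_state=seed).fit(X, (y == c).astype(int))
            for c in labels
        ]
        return CompositeModel("ovr_logistic", labels, list(features.columns), models)
    if kind == "random_forest":
        rf = RandomForestClassifier(n_estimators=200, random_state=seed).fit(X, y)
        return CompositeModel("random_forest", rf.classes_, list(features.columns), rf)
    raise CohortError(f"unknown model kind {kind!r}")


def permutation_importance(
    model: CompositeModel,
    features: pd.DataFrame,
    classes,
    n_perm: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Mean decrease in accuracy when each feature column is permuted."""
    y = np.asarray(classes)
    rng = np.random.default_rng(seed)
    base = float((model.predict(features) == y).mean())
    out = {}
    for col in model.feature_names:
        if col not in features.columns:
            raise CohortError(f"feature {col!r} absent")
        drops = []
        for _ in range(n_perm):
            shuffled = features.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            drops.append(base - float((model.predict(shuffled) == y).mean()))
        out[col] = float(np.mean(drops))
    return pd.Series(out).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Calibration and decision curves
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    bins: pd.DataFrame  # mean_predicted, observed_rate, n
    intercept: float | None
    slope: float | None
    flagged: str | None = None


def calibration(pred_probs, outcomes, n_bins: int = 10) -> CalibrationResult:
    """Decile-binned calibration table plus logistic intercept and slope.

    Intercept and slope come from a logistic fit of the outcome on the logit
    of the prediction; for a perfectly calibrated model they approach 0 and
    1. Predictions at exactly 0/1 are clipped to [1e-6, 1-1e-6] (logged).
    Constant predictions leave the slope undefined; the result is flagged.
    """
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(outcomes).astype(int)
    if ((p <= 0) | (p >= 1)).any():
        log.warning("clipping %d predictions at the [0,1] boundary", int(((p <= 0) | (p >= 1)).sum()))
        p = np.clip(p, 1e-6, 1 - 1e-6)

    order = np.argsort(p, kind="stable")
    rows = []
    for chunk in np.array_split(order, min(n_bins, len(p))):
        rows.append(
            {
                "mean_predicted": float(p[chunk].mean()),
                "observed_rate": float(y[chunk].mean()),
                "n": int(len(chunk)),
            }
        )
    bins = pd.DataFrame(rows)

    if np.ptp(p) == 0:
        return CalibrationResult(bins, None, None, flagged="constant predictions")
    import statsmodels.api as sm

    X = sm.add_constant(_logit(p))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        intercept, slope = float(fit.params[0]), float(fit.params[1])
        return CalibrationResult(bins, intercept, slope)
    except Exception as exc:  # separation or non-convergence
        return CalibrationResult(bins, None, None, flagged=str(exc))


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "net_benefit_model": self.model,
                "net_benefit_treat_all": self.treat_all,
                "net_benefit_treat_none": self.treat_none,
            }
        )


def decision_curve(pred_probs, outcomes, thresholds) -> NetBenefitCurve:
    """Net benefit NB = TP/n - (FP/n) * p_t / (1 - p_t) across thresholds."""
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(outcomes).astype(int)
    ts = np.asarray(thresholds, dtype=float)
    if ts.size == 0:
        raise CohortError("empty threshold grid")
    if ((ts <= 0) | (ts >= 1)).any():
        raise CohortError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    nb_model, nb_all = [], []
    for t in ts:
        w = t / (1 - t)
        pos = p >= t
        nb_model.append(((pos & (y == 1)).sum() - w * (pos & (y == 0)).sum()) / n)
        nb_all.append(((y == 1).sum() - w * (y == 0).sum()) / n)
    return NetBenefitCurve(
        thresholds=ts,
        model=np.array(nb_model),
        treat_all=np.array(nb_all),
        treat_none=np.zeros_like(ts),
    )


# ---------------------------------------------------------------------------
# Internal validation: bootstrap optimism and repeated CV
# ---------------------------------------------------------------------------

#: A model spec is a callable (X, y, seed) -> object with predict_proba(X).
ModelSpec = Callable[[np.ndarray, np.ndarray, int], object]


def logistic_spec(X: np.ndarray, y: np.ndarray, seed: int):
    return LogisticRegression(max_iter=2000, random_state=seed).fit(X, y)


def random_forest_spec(X: np.ndarray, y: np.ndarray, seed: int):
    return RandomForestClassifier(n_estimators=200, random_state=seed).fit(X, y)


def _binary_prob(model, X: np.ndarray) -> np.ndarray:
    probs = model.predict_proba(X)
    pos_col = int(np.argmax(model.classes_)) if hasattr(model, "classes_") else 1
    return probs[:, pos_col]


def _evaluate(metric: str, model, X: np.ndarray, y: np.ndarray) -> float:
    if metric == "auc":
        return auc_score(_binary_prob(model, X), y)
    if metric == "accuracy":
        probs = model.predict_proba(X)
        pred = model.classes_[np.argmax(probs, axis=1)]
        return float((pred == y).mean())
    if metric in ("slope", "intercept"):
        cal = calibration(np.clip(_binary_prob(model, X), 1e-6, 1 - 1e-6), y)
        val = cal.slope if metric == "slope" else cal.intercept
        if val is None:
            raise CohortError(f"calibration {metric} undefined")
        return val
    raise CohortError(f"unknown metric {metric!r}")


@dataclass
class ValidationReport:
    metric: str
    apparent: float
    optimism: float
    corrected: float
    n_boot: int
    n_failed: int
    seed: int
    cv_mean: float | None = None
    cv_sd: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "apparent": self.apparent,
            "optimism": self.optimism,
            "corrected": self.corrected,
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
            **self.extra,
        }


def bootstrap_optimism(
    model_spec: ModelSpec,
    X,
    y,
    metric: str = "auc",
    B: int = 500,
    seed: int = 0,
) -> ValidationReport:
    """Harrell's bootstrap optimism correction of an apparent metric.

    For each bootstrap resample: refit, compute the metric on the resample
    and on the original data; optimism is the mean difference and
    corrected = apparent - mean(optimism). Draws on which the model fails
    (e.g. a one-class resample) are skipped and counted.
    """
    if B < 200:
        raise CohortError("B must be >= 200")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    apparent = _evaluate(metric, model_spec(X, y, seed), X, y)
    optimisms, failed = [], 0
    n = len(y)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            m = model_spec(X[idx], y[idx], seed + b + 1)
            optimisms.append(
                _evaluate(metric, m, X[idx], y[idx]) - _evaluate(metric, m, X, y)
            )
        except Exception:
            failed += 1
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return ValidationReport(
        metric=metric,
        apparent=float(apparent),
        optimism=optimism,
        corrected=float(apparent - optimism),
        n_boot=len(optimisms),
        n_failed=failed,
        seed=seed,
    )


def repeated_cv(
    model_spec: ModelSpec,
    X,
    y,
    k: int = 10,
    repeats: int = 5,
    metric: str = "auc",
    seed: int = 0,
) -> dict:
    """Repeated stratified k-fold CV; out-of-fold metric per fold.

    k is reduced (with a warning) when the smallest class has fewer than k
    members; an error is raised when even 2-fold stratification is
    infeasible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    k_eff = min(k, int(counts.min()))
    if k_eff < 2:
        raise CohortError("stratified CV infeasible: a class has < 2 members")
    if k_eff < k:
        log.warning("reducing folds from %d to %d (smallest class)", k, k_eff)
    values = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed + rep)
        for train, test in skf.split(X, y):
            try:
                m = model_spec(X[train], y[train], seed + rep)
                values.append(_evaluate(metric, m, X[test], y[test]))
            except CohortError:
                continue
    values = np.asarray(values, dtype=float)
    return {
        "metric": metric,
        "values": values,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "k": k_eff,
        "repeats": repeats,
        "seed": seed,
    }
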