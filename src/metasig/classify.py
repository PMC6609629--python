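"""Metastasis stratification: stepwise-AIC logistic regression and ROC analysis.

A multivariable logistic regression over signature genes predicts the
probability that a sample is metastatic rather than primary (normals are
excluded). Variable selection is bidirectional stepwise search minimizing
AIC. The decision threshold on the predicted probability maximizes balanced
accuracy on the training cohort, and the frozen model + threshold transfer
to independent cohorts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn import metrics as _skm

from .data_model import ExpressionMatrix, SampleAnnotation

__all__ = [
    "StratificationModel",
    "ROCCurve",
    "EvaluationReport",
    "fit_logistic",
    "stepwise_aic_select",
    "roc_auc",
    "choose_threshold",
    "evaluate_on_cohort",
]


@dataclass
class StratificationModel:
    """Frozen logistic model: intercept, per-gene coefficients, AIC, and
    (after ``choose_threshold``) the probability cutoff for calling a sample
    metastatic."""

    intercept: float
    coefficients: dict[str, float]
    aic: float
    threshold: float | None = None
    training_cohort: str = ""
    ridge_fallback: bool = False
    resubstitution: bool = True

    def predict_proba(self, m: ExpressionMatrix, samples: Sequence[str] | None = None) -> pd.Series:
        samples = list(samples) if samples is not None else m.sample_ids
        missing = [g for g in self.coefficients if g not in m.values.index]
        if missing:
            raise KeyError(f"model genes absent from cohort matrix: {missing}")
        eta = np.full(len(samples), self.intercept)
        sub = m.values[samples]
        for g, beta in self.coefficients.items():
            eta = eta + beta * sub.loc[g].to_numpy(float)
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=samples)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "aic": self.aic,
            "threshold": self.threshold,
            "training_cohort": self.training_cohort,
            "ridge_fallback": self.ridge_fallback,
            "resubstitution": self.resubstitution,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "StratificationModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray  # descending
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class EvaluationReport:
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
        }


# ---------------------------------------------------------------------------


def _design(m: ExpressionMatrix, ann: SampleAnnotation, genes: Sequence[str]):
    """Metastatic-vs-primary design matrix; normals excluded."""
    samples = ann.samples_of("primary", "metastatic")
    samples = [s for s in samples if s in set(m.sample_ids)]
    y = (ann.classes().loc[samples] == "metastatic").to_numpy(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need >= 2 samples in each of primary and metastatic")
    x = m.values.loc[list(genes), samples].to_numpy(float).T if genes else np.empty((len(samples), 0))
    return x, y, samples


def _ridge_logistic(x: np.ndarray, y: np.ndarray, lam: float = 1e-4, n_iter: int = 200):
    """IRLS for L2-penalized logistic regression (intercept unpenalized).

    Fallback when the unpenalized MLE does not exist (complete separation).
    """
    xd = np.column_stack([np.ones(len(y)), x])
    p = xd.shape[1]
    beta = np.zeros(p)
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0
    for _ in range(n_iter):
        eta = xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = xd.T @ (y - mu) - pen @ beta
        hess = (xd * w[:, None]).T @ xd + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = xd @ beta
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, loglik


def fit_logistic(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    genes: Sequence[str],
    cohort: str = "",
) -> StratificationModel:
    """Maximum-likelihood logistic fit of metastatic status on gene expression.

    AIC = 2k - 2 loglik with k = number of fitted parameters (intercept
    included). Complete separation triggers a small-ridge (lambda = 1e-4)
    IRLS fallback with a warning, so coefficients stay finite.
    """
    genes = list(genes)
    x, y, _ = _design(m, ann, genes)
    xd = sm.add_constant(x, has_constant="add")
    k = xd.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, xd).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 1e4:
            raise sm.tools.sm_exceptions.PerfectSeparationError("huge coefficients")
        params = np.asarray(res.params)
        aic = float(res.aic)
        ridge = False
    except Exception:
        warnings.warn("complete separation detected; fitting with ridge penalty 1e-4")
        params, loglik = _ridge_logistic(x, y)
        aic = float(2 * k - 2 * loglik)
        ridge = True
    return StratificationModel(
        intercept=float(params[0]),
        coefficients={g: float(b) for g, b in zip(genes, params[1:])},
        aic=aic,
        training_cohort=cohort,
        ridge_fallback=ridge,
    )


def stepwise_aic_select(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    candidate_genes: Sequence[str],
    cohort: str = "",
    direction: str = "both",
) -> StratificationModel:
    """Bidirectional stepwise AIC search from the intercept-only model.

    Each round evaluates every single-gene addition (and removal, when
    ``direction="both"``); the move with the lowest AIC is applied if it
    improves on the current AIC, with lexicographic tie-breaks on the gene
    id. Stops at a local minimum, so the result never has AIC above the
    intercept-only model.
    """
    candidates = sorted(set(candidate_genes))
    if not candidates:
        raise ValueError("candidate_genes must be nonempty")
    current: list[str] = []
    best = fit_logistic(m, ann, current, cohort)
    while True:
        moves: list[tuple[float, str, str]] = []  # (aic, gene, op)
        for g in candidates:
            if g not in current:
                trial = fit_logistic(m, ann, sorted(current + [g]), cohort)
                moves.append((trial.aic, g, "add"))
        if direction == "both":
            for g in current:
                trial = fit_logistic(m, ann, [x for x in current if x != g], cohort)
                moves.append((trial.aic, g, "drop"))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[1]))
        aic, gene, op = moves[0]
        if aic >= best.aic - 1e-10:
            break
        current = sorted(current + [gene]) if op == "add" else [x for x in current if x != gene]
        best = fit_logistic(m, ann, current, cohort)
    return best


# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve over all distinct score thresholds with tie-aware AUC.

    AUC equals the Mann-Whitney concordance (tied scores contribute half);
    the curve itself is the usual staircase from scikit-learn.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain exactly two classes")
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(_skm.roc_auc_score(labels, scores))
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def _report_at(scores: np.ndarray, labels: np.ndarray, threshold: float, auc: float) -> EvaluationReport:
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & neg))
    fp = int(np.sum(pred & neg))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return EvaluationReport(
        balanced_accuracy=(sens + spec) / 2,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def choose_threshold(scores, labels) -> tuple[float, EvaluationReport]:
    """Probability cutoff maximizing balanced accuracy, ties to the smaller cutoff.

    Scans every distinct score as a candidate threshold (prediction rule:
    call positive when score >= threshold).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    curve = roc_auc(scores, labels)
    candidates = np.unique(scores)
    best_thr, best_ba = None, -1.0
    for thr in candidates:  # ascending, so first max is the smallest threshold
        rep = _report_at(scores, labels, thr, curve.auc)
        if rep.balanced_accuracy > best_ba + 1e-12:
            best_ba = rep.balanced_accuracy
            best_thr = float(thr)
    return best_thr, _report_at(scores, labels, best_thr, curve.auc)


def evaluate_on_cohort(
    model: StratificationModel, m: ExpressionMatrix, ann: SampleAnnotation
) -> EvaluationReport:
    """Apply frozen coefficients + threshold to a cohort (normals excluded)."""
    if model.threshold is None:
        raise ValueError("model threshold not set; run choose_threshold first")
    _, y, samples = _design(m, ann, list(model.coefficients))
    probs = model.predict_proba(m, samples).to_numpy()
    auc = roc_auc(probs, y).auc
    return _report_at(probs, y, model.threshold, auc)


def train_stratification_model(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    candidate_genes: Sequence[str],
    cohort: str = "",
) -> tuple[StratificationModel, EvaluationReport]:
    """Stepwise selection + threshold choice on one training cohort."""
    model = stepwise_aic_select(m, ann, candidate_genes, cohort)
    _, y, samples = _design(m, ann, list(model.coefficients))
    probs = model.predict_proba(m, samples).to_numpy()
    thr, report = choose_threshold(probs, y)
    model.threshold = thr
    return model, report
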