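"""Greedy stepwise LDA feature selection ranked by Wilks' Λ.

Wilks' Λ for a feature subset is det(W)/det(T), the ratio of the
within-class to the total scatter determinant — small values mean strong
class separation.  Forward selection adds, at each step, the candidate
whose inclusion minimizes Λ on the training data, then refits the
shrinkage-LDA engine on the selected subset and records test-set metrics,
producing an ordered trace of the most identifying anatomical measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifiers
from .errors import ValidationError
from .feature_tables import FeatureSchema, FeatureTable
from .identification import IdentificationReport, compute_metrics

#: stop when the best candidate reduces lambda by no more than this
LAMBDA_TOLERANCE = 1e-12


@dataclass
class StepwiseTrace:
    """Ordered selected features with per-step test metrics."""

    features: list[str] = field(default_factory=list)
    lambdas: list[float] = field(default_factory=list)
    reports: list[IdentificationReport] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, (f, lam, r) in enumerate(zip(self.features, self.lambdas, self.reports), 1):
            rows.append(
                {
                    "Step": i,
                    "Feature": f,
                    "WilksLambda": lam,
                    "ACC": r.accuracy,
                    "SENS": r.sensitivity,
                    "SPEC": r.specificity,
                    "F1": r.f1,
                }
            )
        return pd.DataFrame(rows)


def _scatter_matrices(train: FeatureTable) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Full within-class and total scatter over all columns of ``train``."""
    X = train.values
    labels = sorted(set(train.subject_ids))
    lab_index = {lab: i for i, lab in enumerate(labels)}
    y = np.array([lab_index[s] for s in train.subject_ids])
    if len(labels) < 2:
        raise ValidationError("need at least 2 classes")
    grand = X.mean(axis=0)
    Xc = X - grand
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for k in range(len(labels)):
        Xk = X[y == k]
        D = Xk - Xk.mean(axis=0)
        W += D.T @ D
    return W, T, X.shape[0], len(labels)


def _lambda_from_scatter(
    W: np.ndarray, T: np.ndarray, cols: list[int], n: int, K: int,
    shrinkage: float,
) -> float:
    Ws = W[np.ix_(cols, cols)]
    Ts = T[np.ix_(cols, cols)]
    p = len(cols)
    if p > n - K:
        # within scatter cannot be full rank: shrink both towards identity
        lam = shrinkage if shrinkage > 0 else classifiers.DEFAULT_SHRINKAGE
        Ws = (1 - lam) * Ws + lam * (np.trace(Ws) / p) * np.eye(p)
        Ts = (1 - lam) * Ts + lam * (np.trace(Ts) / p) * np.eye(p)
    sT, ldT = np.linalg.slogdet(Ts)
    if sT <= 0:
        raise ValidationError("total scatter matrix is singular on this subset")
    sW, ldW = np.linalg.slogdet(Ws)
    if sW <= 0:
        return 0.0  # zero within-class variance: perfect separation
    return float(np.exp(ldW - ldT))


def wilks_lambda(
    train: FeatureTable,
    features: list[str],
    shrinkage: float = 0.0,
) -> float:
    """Wilks' Λ = det(W)/det(T) for a named feature subset of ``train``.

    When the subset dimension exceeds the within-scatter rank bound n−K the
    classifier's identity-target shrinkage is applied to both scatter
    matrices (otherwise Λ would be identically zero for every subset).
    """
    if not features:
        raise ValidationError("feature subset must be non-empty")
    pos = {f: j for j, f in enumerate(train.feature_names)}
    missing = [f for f in features if f not in pos]
    if missing:
        raise ValidationError(f"features absent from table: {missing}")
    W, T, n, K = _scatter_matrices(train)
    return _lambda_from_scatter(W, T, [pos[f] for f in features], n, K, shrinkage)


def stepwise_lda(
    train: FeatureTable,
    test: FeatureTable,
    schema: FeatureSchema | None = None,
    set_name: str = "ALL",
    cap: int = 11,
    engine_params: dict | None = None,
) -> StepwiseTrace:
    """Forward Wilks-Λ selection with per-step test metrics.

    ``train``/``test`` are the already-split (and, typically, already
    scaled) tables.  At each step the candidate minimizing Λ of the
    augmented subset joins; selection stops at ``cap`` features or when no
    candidate improves Λ by more than :data:`LAMBDA_TOLERANCE`.  After each
    step the shrinkage-LDA engine is refit on the selected columns and the
    held-out scans are re-identified, giving the per-step ACC/SENS/SPEC/F1.
    """
    params = dict(engine_params or {})
    shrink = params.get("shrinkage", classifiers.DEFAULT_SHRINKAGE)
    names = (
        list(train.feature_names)
        if schema is None
        else [n for n in schema.feature_set(set_name)]
    )
    missing = [n for n in names if n not in train.feature_names]
    if missing:
        raise ValidationError(f"candidate features absent from training table: {missing[:10]}")
    if not 1 <= cap <= len(names):
        raise ValidationError(f"cap must lie in [1, {len(names)}]")

    tr = train.select_columns(names)
    te = test.select_columns(names)
    W, T, n, K = _scatter_matrices(tr)
    pos = {f: j for j, f in enumerate(names)}

    trace = StepwiseTrace()
    selected: list[int] = []
    current_lambda = 1.0
    remaining = list(range(len(names)))
    while len(selected) < cap and remaining:
        best_j, best_lam = None, np.inf
        for j in remaining:
            try:
                lam = _lambda_from_scatter(W, T, selected + [j], n, K, shrink)
            except ValidationError:
                continue  # singular total scatter (e.g. collinear duplicate)
            if lam < best_lam:
                best_j, best_lam = j, lam
        if best_j is None or current_lambda - best_lam <= LAMBDA_TOLERANCE:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        current_lambda = best_lam

        subset_names = [names[j] for j in selected]
        model = classifiers.fit_lda(tr.select_columns(subset_names), shrinkage=shrink)
        predicted = classifiers.predict_lda(model, te.select_columns(subset_names))
        report = compute_metrics(list(te.subject_ids), predicted)
        report.engine = "lda"
        report.dataset = set_name
        trace.features.append(names[best_j])
        trace.lambdas.append(best_lam)
        trace.reports.append(report)
    return trace
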