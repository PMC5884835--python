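"""Identification engines: shrinkage LDA and distance-weighted KNN.

Identification differs from ordinary classification in that every subject
is a class: a model trained on a subject's earlier scans must pick that
subject out of the full cohort from a later scan.  Two engines are
provided:

* multi-class linear discriminant analysis with a pooled within-class
  covariance shrunk towards a scaled identity, scored by the Gaussian
  discriminant  δ_k(x) = xᵀ S_λ⁻¹ μ_k − ½ μ_kᵀ S_λ⁻¹ μ_k + log π_k ;
* weighted k-nearest-neighbour voting in which each neighbour's vote
  counts 1/d² (inverse squared Euclidean distance), with an exact match
  (d = 0) winning outright.

Both engines are deterministic, and all tie-breaks are resolved by label
order so that permuting training rows never changes a prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, LinAlgError
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .feature_tables import FeatureTable

DEFAULT_SHRINKAGE = 0.1
DEFAULT_K = 3


def _labels_and_matrix(train: FeatureTable) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels = sorted(set(train.subject_ids))
    lab_index = {lab: i for i, lab in enumerate(labels)}
    y = np.array([lab_index[s] for s in train.subject_ids], dtype=int)
    return labels, y, train.values


@dataclass
class LDAModel:
    class_labels: list[str]
    class_means: np.ndarray            # (K, p)
    pooled_covariance: np.ndarray      # (p, p) after shrinkage
    shrinkage_lambda: float
    priors: np.ndarray                 # (K,)
    feature_names: list[str]

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValidationError("class priors must sum to 1")
        if self.class_means.shape[0] != len(self.class_labels):
            raise ValidationError("one mean per class required")
        try:
            self._chol = cho_factor(self.pooled_covariance, lower=True)
        except (LinAlgError, np.linalg.LinAlgError):
            raise ValidationError(
                "shrunk pooled covariance is numerically singular; "
                "refit with a larger shrinkage lambda"
            ) from None

    def to_json(self) -> str:
        return json.dumps(
            {
                "engine": "lda",
                "class_labels": self.class_labels,
                "shrinkage_lambda": self.shrinkage_lambda,
                "priors": self.priors.tolist(),
                "feature_names": self.feature_names,
                "class_means": self.class_means.tolist(),
                "pooled_covariance": self.pooled_covariance.tolist(),
            }
        )


def fit_lda(
    train: FeatureTable,
    shrinkage: float = DEFAULT_SHRINKAGE,
    priors: np.ndarray | None = None,
) -> LDAModel:
    """Fit multi-class LDA with identity-target covariance shrinkage.

    The pooled within-class covariance uses divisor ``n − K``; the model
    factorizes  S_λ = (1−λ)·S + λ·(tr(S)/p)·I .  Classes are the subject
    identifiers of ``train``.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValidationError("shrinkage lambda must lie in [0, 1]")
    labels, y, X = _labels_and_matrix(train)
    K, (n, p) = len(labels), X.shape
    if K < 2:
        raise ValidationError("need at least 2 classes (subjects)")
    means = np.empty((K, p))
    scatter = np.zeros((p, p))
    for k in range(K):
        Xk = X[y == k]
        if Xk.shape[0] == 0:
            raise ValidationError(f"class {labels[k]} has no training rows")
        means[k] = Xk.mean(axis=0)
        if Xk.shape[0] > 1:
            D = Xk - means[k]
            scatter += D.T @ D
    S = scatter / (n - K) if n > K else np.zeros((p, p))
    # identity-target scale; unit scale in the zero-within-variance limit,
    # where shrunk LDA degenerates to nearest-class-mean
    target = np.trace(S) / p if np.trace(S) > 0 else 1.0
    S_lam = (1.0 - shrinkage) * S + shrinkage * target * np.eye(p)
    pri = np.full(K, 1.0 / K) if priors is None else np.asarray(priors, dtype=float)
    return LDAModel(
        class_labels=labels,
        class_means=means,
        pooled_covariance=S_lam,
        shrinkage_lambda=float(shrinkage),
        priors=pri,
        feature_names=list(train.feature_names),
    )


def lda_scores(model: LDAModel, x: np.ndarray) -> np.ndarray:
    """Per-class discriminant values δ_k(x) for one row or a matrix of rows."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.class_means.shape[1]:
        raise ValidationError(
            f"feature dimension mismatch: got {x.shape[1]}, "
            f"model expects {model.class_means.shape[1]}"
        )
    # LU solve (S_λ is PD; Cholesky validated it at fit time) keeps simple
    # rational examples bit-exact, so score ties resolve deterministically
    A = np.linalg.solve(model.pooled_covariance, model.class_means.T)  # S_λ⁻¹ μ_kᵀ
    quad = 0.5 * np.sum(model.class_means * A.T, axis=1)  # ½ μ_k S_λ⁻¹ μ_k
    scores = x @ A - quad + np.log(model.priors)
    return scores[0] if single else scores


def predict_lda(model: LDAModel, test: FeatureTable) -> list[str]:
    """Argmax of the discriminants; ties go to the earliest class label."""
    if test.feature_names != model.feature_names:
        raise ValidationError("test table features differ from the model's")
    scores = np.atleast_2d(lda_scores(model, test.values))
    return [model.class_labels[i] for i in np.argmax(scores, axis=1)]


@dataclass
class WKNNModel:
    exemplars: np.ndarray        # (n, p) training rows stored verbatim
    exemplar_labels: list[str]
    k: int
    feature_names: list[str]

    def __post_init__(self) -> None:
        if len(self.exemplar_labels) != self.exemplars.shape[0]:
            raise ValidationError("exemplar count != label count")
        if not 1 <= self.k <= self.exemplars.shape[0]:
            raise ValidationError(
                f"k={self.k} out of range [1, {self.exemplars.shape[0]}]"
            )

    @property
    def class_labels(self) -> list[str]:
        return sorted(set(self.exemplar_labels))

    def to_json(self) -> str:
        return json.dumps(
            {
                "engine": "wknn",
                "k": self.k,
                "exemplar_labels": self.exemplar_labels,
                "feature_names": self.feature_names,
                "exemplars": self.exemplars.tolist(),
            }
        )


def fit_wknn(train: FeatureTable, k: int = DEFAULT_K) -> WKNNModel:
    """Store the training rows verbatim as exemplars."""
    return WKNNModel(
        exemplars=train.values.copy(),
        exemplar_labels=list(train.subject_ids),
        k=int(k),
        feature_names=list(train.feature_names),
    )


def predict_wknn(model: WKNNModel, test: FeatureTable) -> list[str]:
    """Inverse-squared-distance weighted vote over the k nearest exemplars.

    Neighbourhoods include every exemplar tied with the k-th smallest
    distance.  An exact match (zero distance) wins immediately (infinite
    weight).  Vote ties are broken by the smallest single neighbour
    distance within the tied classes, then by label order.
    """
    if test.feature_names != model.feature_names:
        raise ValidationError("test table features differ from the model's")
    labels = model.class_labels
    lab_index = {lab: i for i, lab in enumerate(labels)}
    ex_lab = np.array([lab_index[s] for s in model.exemplar_labels], dtype=int)
    d2 = cdist(test.values, model.exemplars, metric="sqeuclidean")
    out: list[str] = []
    K = len(labels)
    for r in range(d2.shape[0]):
        dr = d2[r]
        if dr.min() == 0.0:
            zero = np.flatnonzero(dr == 0.0)
            out.append(labels[int(ex_lab[zero].min())])
            continue
        kth = np.partition(dr, model.k - 1)[model.k - 1]
        nb = np.flatnonzero(dr <= kth)
        votes = np.zeros(K)
        np.add.at(votes, ex_lab[nb], 1.0 / dr[nb])
        best = votes.max()
        tied = np.flatnonzero(votes == best)
        if len(tied) == 1:
            out.append(labels[int(tied[0])])
            continue
        # nearest single neighbour among each tied class, then label order
        min_d = np.full(K, np.inf)
        np.minimum.at(min_d, ex_lab[nb], dr[nb])
        out.append(labels[int(tied[np.argmin(min_d[tied])])])
    return out
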