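"""ERBNet: Dirichlet-searched weighted averaging of per-dose models.

Five classifiers, one per dose level, each output a nodule probability;
the ensemble prediction is a convex combination of those probabilities.
The weight vector is chosen by sampling the K-simplex with a Dirichlet
distribution (alpha = 1 gives the uniform measure), scoring every
candidate on a labeled tuning set, and keeping the argmax.  The K
one-hot vectors are appended to the candidate list, so on the tuning set
the ensemble can never do worse than its best constituent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import metrics as _metrics

__all__ = ["ProbabilitySet", "EnsembleWeights", "sample_dirichlet_weights",
           "weighted_average", "search_best_weights", "predict_ensemble",
           "DirichletEnsemble"]

DEFAULT_N_CANDIDATES = 20_000


@dataclass
class ProbabilitySet:
    """Per-model probabilities for a common sample set (K models x N)."""

    probs: np.ndarray
    model_keys: tuple = ()
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2:
            raise ValueError("probs must be K x N")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.probs.shape[1],):
                raise ValueError("labels length must match the sample axis")

    @property
    def n_models(self) -> int:
        return self.probs.shape[0]


@dataclass
class EnsembleWeights:
    """A point on the K-simplex plus provenance of the search."""

    weights: np.ndarray
    tuning_score: float = float("nan")
    n_candidates: int = 0
    seed: int | None = None
    model_keys: tuple = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1 (within 1e-9)")


def sample_dirichlet_weights(K: int, n_samples: int, alpha: float = 1.0,
                             seed=None) -> np.ndarray:
    """Draw ``n_samples`` weight vectors from Dirichlet(alpha, ..., alpha)."""
    if K < 1 or n_samples < 1:
        raise ValueError("K and n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = rng.dirichlet(np.full(K, float(alpha)), size=n_samples)
    return w


def weighted_average(pset: ProbabilitySet | np.ndarray, w) -> np.ndarray:
    """Convex combination of per-model probabilities, one value per sample."""
    probs = pset.probs if isinstance(pset, ProbabilitySet) else np.asarray(pset, dtype=np.float64)
    wv = w.weights if isinstance(w, EnsembleWeights) else np.asarray(w, dtype=np.float64)
    if probs.shape[0] != wv.shape[-1]:
        raise ValueError(f"dimension mismatch: {probs.shape[0]} models vs {wv.shape[-1]} weights")
    return wv @ probs


def _score_candidates(W: np.ndarray, probs: np.ndarray, labels: np.ndarray,
                      metric: str) -> np.ndarray:
    if metric == "accuracy":
        preds = (W @ probs) >= 0.5
        return (preds == labels[None, :]).mean(axis=1)
    if metric == "auc":
        return np.array([_metrics.auc(row, labels) for row in W @ probs])
    raise ValueError(f"unknown selection metric {metric!r}")


def search_best_weights(pset: ProbabilitySet, n_samples: int = DEFAULT_N_CANDIDATES,
                        alpha: float = 1.0, selection_metric: str = "accuracy",
                        seed=None, include_one_hot: bool = True) -> EnsembleWeights:
    """Pick the simplex point maximizing a tuning-set metric.

    Candidates are ``n_samples`` Dirichlet draws plus (by default) the K
    one-hot vectors; ties break to the first occurrence in sample order.
    """
    if pset.labels is None:
        raise ValueError("tuning set must carry labels")
    labels = np.asarray(pset.labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("tuning labels must contain both classes")
    K = pset.n_models
    W = sample_dirichlet_weights(K, n_samples, alpha=alpha, seed=seed)
    if include_one_hot:
        W = np.vstack([W, np.eye(K)])
    scores = _score_candidates(W, pset.probs, labels, selection_metric)
    best = int(np.argmax(scores))  # argmax takes the first maximum
    return EnsembleWeights(W[best], tuning_score=float(scores[best]),
                           n_candidates=W.shape[0],
                           seed=seed if not isinstance(seed, np.random.Generator) else None,
                           model_keys=tuple(pset.model_keys))


def predict_ensemble(registry: Mapping, w: EnsembleWeights, patches) -> np.ndarray:
    """Weighted-average nodule probability over a model registry.

    ``registry`` keys must match ``w.model_keys`` (order defines the
    weight order).
    """
    keys = tuple(w.model_keys) if w.model_keys else tuple(registry.keys())
    if set(keys) != set(registry.keys()) or len(keys) != len(w.weights):
        raise ValueError(f"registry keys {tuple(registry.keys())} do not match "
                         f"weight keys {keys}")
    probs = np.stack([registry[k].predict_proba(patches)[:, 1] for k in keys])
    return weighted_average(probs, w.weights)


class DirichletEnsemble(ClassifierMixin, BaseEstimator):
    """Scikit-learn meta-estimator over precomputed model probabilities.

    ``fit`` takes an ``(n_samples, K)`` matrix of per-model nodule
    probabilities and binary labels, runs the Dirichlet weight search,
    and stores ``weights_``; ``predict_proba`` combines new probability
    matrices with the learned weights.
    """

    def __init__(self, n_candidates: int = DEFAULT_N_CANDIDATES, alpha: float = 1.0,
                 selection_metric: str = "accuracy", include_one_hot: bool = True,
                 random_state: int = 0):
        self.n_candidates = n_candidates
        self.alpha = alpha
        self.selection_metric = selection_metric
        self.include_one_hot = include_one_hot
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, K) model probabilities")
        pset = ProbabilitySet(X.T, labels=np.asarray(y))
        res = search_best_weights(pset, n_samples=self.n_candidates,
                                  alpha=self.alpha,
                                  selection_metric=self.selection_metric,
                                  seed=self.random_state,
                                  include_one_hot=self.include_one_hot)
        self.weights_ = res.weights
        self.tuning_score_ = res.tuning_score
        self.n_candidates_ = res.n_candidates
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        p1 = weighted_average(np.asarray(X, dtype=np.float64).T, self.weights_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
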