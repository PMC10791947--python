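"""Classifiers: fit on a training set, emit per-class decision values.

Every classifier follows the same contract: ``fit(X, y)`` learns from a
labeled feature matrix, and ``decision_function(X)`` returns an
``(n_test, n_classes)`` array of real-valued confidences where higher
means more confident, with classes in ``self.classes_`` order (sorted
unique training labels). Prediction takes the argmax; exact ties are
broken by a uniform random draw from the argmax set using the caller's
seeded generator so that degenerate inputs (e.g. all-zero time bins)
still yield chance-level accuracy rather than a bias toward the first
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .errors import ClassifierError

__all__ = [
    "PredictionRecord",
    "MaxCorrelation",
    "PoissonNaiveBayes",
    "SvmAdapter",
    "predict_from_decision_values",
    "max_correlation_predict",
    "poisson_nb_predict",
    "make_classifier",
]


@dataclass
class PredictionRecord:
    """One test point's outcome: true class, chosen class, all confidences."""

    actual_class: object
    predicted_class: object
    decision_values: dict = field(default_factory=dict)
    tie_flag: bool = False


def predict_from_decision_values(
    dv: np.ndarray, classes, rng: Optional[np.random.Generator] = None
):
    """Argmax with randomized tie-breaking.

    Returns ``(predicted_indices, tie_flags)``. Ties are exact equalities
    of the maximal decision value; when present the winner is drawn
    uniformly from the argmax set using ``rng`` (a fresh default
    generator if omitted, but callers that need reproducibility must pass
    their own seeded substream).
    """
    dv = np.asarray(dv, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    maxima = dv.max(axis=1, keepdims=True)
    is_max = dv == maxima
    n_max = is_max.sum(axis=1)
    predicted = np.argmax(dv, axis=1)
    ties = n_max > 1
    for i in np.nonzero(ties)[0]:
        predicted[i] = rng.choice(np.nonzero(is_max[i])[0])
    return predicted, ties


def _records(dv, classes, actual, rng) -> list:
    predicted, ties = predict_from_decision_values(dv, classes, rng)
    classes = list(classes)
    out = []
    for i in range(dv.shape[0]):
        out.append(PredictionRecord(
            actual_class=None if actual is None else actual[i],
            predicted_class=classes[predicted[i]],
            decision_values=dict(zip(classes, dv[i])),
            tie_flag=bool(ties[i]),
        ))
    return out


class MaxCorrelation:
    """Maximum correlation coefficient classifier.

    Training computes one prototype per class (the mean of its training
    vectors); the decision value for (test point, class) is the Pearson
    correlation across features between the test vector and the
    prototype. Zero-variance test vectors or prototypes give a decision
    value of 0 for the affected pairs. Requires >= 2 features.
    """

    name = "max_correlation"

    def fit(self, X: np.ndarray, y) -> "MaxCorrelation":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] < 2:
            raise ClassifierError(
                "max_correlation needs >= 2 features: Pearson correlation "
                "across features is undefined for a single feature")
        self.classes_, inv = np.unique(y, return_inverse=True)
        counts = np.bincount(inv).astype(float)
        if (counts < 1).any():  # pragma: no cover - unique() precludes this
            raise ClassifierError("every class needs at least one training point")
        sums = np.zeros((len(self.classes_), X.shape[1]))
        np.add.at(sums, inv, X)
        self.prototypes_ = sums / counts[:, None]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        protos = self.prototypes_
        xc = X - X.mean(axis=1, keepdims=True)
        pc = protos - protos.mean(axis=1, keepdims=True)
        xn = np.linalg.norm(xc, axis=1)
        pn = np.linalg.norm(pc, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (xc @ pc.T) / np.outer(xn, pn)
        corr[~np.isfinite(corr)] = 0.0
        return corr

    def params(self) -> dict:
        return {"type": "max_correlation"}


class PoissonNaiveBayes:
    """Poisson naive Bayes classifier on spike counts.

    Each (class c, feature f) gets an estimated rate
    ``lambda_cf = (sum of training counts + smoothing) / n_c`` where
    ``n_c`` is the number of training points of class c and ``smoothing``
    (default 0.5) is an add-constant that keeps rates positive for silent
    neurons. The decision value of a test vector x for class c is the
    log-likelihood under independent Poissons with equal class priors:
    ``sum_f [x_f * log(lambda_cf) - lambda_cf - log(x_f!)]``.

    Inputs must be nonnegative counts; non-integer values are rejected
    unless ``allow_rounding=True`` (they are then rounded to the nearest
    integer).
    """

    name = "poisson_naive_bayes"

    def __init__(self, smoothing: float = 0.5, allow_rounding: bool = False):
        if smoothing < 0:
            raise ClassifierError(f"smoothing must be >= 0, got {smoothing}")
        self.smoothing = float(smoothing)
        self.allow_rounding = bool(allow_rounding)

    def _check_counts(self, X: np.ndarray, what: str) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if (X < 0).any():
            raise ClassifierError(f"{what} contains negative counts")
        if not np.allclose(X, np.round(X)):
            if not self.allow_rounding:
                raise ClassifierError(
                    f"{what} contains non-integer values; the Poisson model "
                    "needs counts (bin with aggregate='sum', or set "
                    "allow_rounding=True to round)")
            X = np.round(X)
        return X

    def fit(self, X: np.ndarray, y) -> "PoissonNaiveBayes":
        X = self._check_counts(X, "training data")
        y = np.asarray(y)
        self.classes_, inv = np.unique(y, return_inverse=True)
        counts = np.bincount(inv).astype(float)
        sums = np.zeros((len(self.classes_), X.shape[1]))
        np.add.at(sums, inv, X)
        lam = (sums + self.smoothing) / counts[:, None]
        if (lam <= 0).any():
            raise ClassifierError(
                "a class has all-zero training counts for some feature and "
                "smoothing is 0; use smoothing > 0 to avoid log(0)")
        self.rates_ = lam
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = self._check_counts(X, "test data")
        log_lam = np.log(self.rates_)
        ll = X @ log_lam.T - self.rates_.sum(axis=1)[None, :]
        ll = ll - gammaln(X + 1).sum(axis=1)[:, None]
        return ll

    def params(self) -> dict:
        return {"type": "poisson_naive_bayes", "smoothing": self.smoothing,
                "allow_rounding": self.allow_rounding}


class SvmAdapter:
    """Thin optional wrapper around scikit-learn's SVC (one-vs-rest scores).

    Provided for completeness; not covered by the oracle test suite.
    """

    name = "svm"

    def __init__(self, **options):
        self.options = options

    def fit(self, X, y) -> "SvmAdapter":
        try:
            from sklearn.svm import SVC
        except ImportError as exc:  # pragma: no cover
            raise ClassifierError(
                "the svm classifier requires scikit-learn") from exc
        self._svc = SVC(decision_function_shape="ovr", **self.options)
        self._svc.fit(np.asarray(X, dtype=float), np.asarray(y))
        self.classes_ = self._svc.classes_
        return self

    def decision_function(self, X) -> np.ndarray:
        dv = self._svc.decision_function(np.asarray(X, dtype=float))
        if dv.ndim == 1:  # binary: expand to per-class columns
            dv = np.column_stack([-dv, dv])
        return dv

    def params(self) -> dict:
        return {"type": "svm", **self.options}


def max_correlation_predict(train_X, train_y, test_X, test_y=None, rng=None) -> list:
    """Functional one-shot interface returning PredictionRecords."""
    clf = MaxCorrelation().fit(train_X, train_y)
    dv = clf.decision_function(test_X)
    return _records(dv, clf.classes_, test_y, rng)


def poisson_nb_predict(train_X, train_y, test_X, test_y=None,
                       smoothing: float = 0.5, rng=None) -> list:
    """Functional one-shot interface returning PredictionRecords."""
    clf = PoissonNaiveBayes(smoothing=smoothing).fit(train_X, train_y)
    dv = clf.decision_function(test_X)
    return _records(dv, clf.classes_, test_y, rng)


def make_classifier(spec: dict):
    """Build a classifier from a config mapping like {'type': 'max_correlation'}."""
    from .errors import ConfigError

    kind = spec.get("type")
    if kind == "max_correlation":
        extra = set(spec) - {"type"}
        if extra:
            raise ConfigError(f"unknown keys for max_correlation: {sorted(extra)}")
        return MaxCorrelation()
    if kind == "poisson_naive_bayes":
        extra = set(spec) - {"type", "smoothing", "allow_rounding"}
        if extra:
            raise ConfigError(f"unknown keys for poisson_naive_bayes: {sorted(extra)}")
        return PoissonNaiveBayes(
            smoothing=spec.get("smoothing", 0.5),
            allow_rounding=spec.get("allow_rounding", False))
    if kind == "svm":
        return SvmAdapter(**{k: v for k, v in spec.items() if k != "type"})
    raise ConfigError(f"unknown classifier type {kind!r}")
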