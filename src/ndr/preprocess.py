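"""Feature preprocessors: fit on training data only, apply to train and test.

Two preprocessors are provided. ``zscore`` normalizes each feature using
the training-set mean and standard deviation. ``select_k_features`` keeps
the k features with the largest one-way ANOVA F statistic of feature vs
class label on the training set (the working definition of "most
selective") and drops the rest from both sets.

Preprocessors never look at the test set when estimating their state, so
perturbing test data cannot change the fitted transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "ZScoreState",
    "FeatureSelectState",
    "zscore_fit_apply",
    "select_k_features_fit_apply",
    "anova_f_scores",
    "ZScore",
    "SelectKFeatures",
    "make_preprocessor",
]


@dataclass
class ZScoreState:
    mean: np.ndarray  # per-feature training mean
    sd: np.ndarray    # per-feature training sd (ddof=1)


@dataclass
class FeatureSelectState:
    k: int
    scores: np.ndarray            # per-feature F statistic
    kept_feature_indices: np.ndarray  # ascending, length k


def _check_feature_match(train: np.ndarray, test: np.ndarray) -> None:
    if train.shape[1] != test.shape[1]:
        raise ValueError(
            f"train has {train.shape[1]} features but test has "
            f"{test.shape[1]}; feature sets must match")


def zscore_fit_apply(train: np.ndarray, test: np.ndarray):
    """Z-score train and test using train-estimated mean and sd.

    Standard deviation uses the sample (n-1) denominator. Features whose
    training sd is 0 map to 0 in both outputs.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] == 0:
        raise ValueError("training set is empty")
    _check_feature_match(train, test)
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1) if train.shape[0] > 1 else np.zeros(train.shape[1])
    # an exactly-constant column must map to 0, not blow up on ~1e-16 sd
    sd = np.where(np.all(train == train[:1], axis=0), 0.0, sd)
    state = ZScoreState(mean=mean, sd=sd)
    safe = np.where(sd > 0, sd, 1.0)
    train_z = np.where(sd > 0, (train - mean) / safe, 0.0)
    test_z = np.where(sd > 0, (test - mean) / safe, 0.0)
    return train_z, test_z, state


def anova_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA F statistic per feature (column of X).

    Degenerate features are ranked deterministically: zero within-class
    variance with nonzero between-class variance gives F = +inf (a
    perfectly selective feature); an all-constant feature gives F = 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, inv = np.unique(y, return_inverse=True)
    n_classes = len(classes)
    if n_classes < 2:
        raise ValueError("ANOVA F requires at least 2 classes in the training set")
    n = X.shape[0]
    grand_mean = X.mean(axis=0)

    group_counts = np.bincount(inv, minlength=n_classes).astype(float)
    group_sums = np.zeros((n_classes, X.shape[1]))
    np.add.at(group_sums, inv, X)
    group_means = group_sums / group_counts[:, None]

    ss_between = (group_counts[:, None] * (group_means - grand_mean) ** 2).sum(axis=0)
    ss_total = ((X - grand_mean) ** 2).sum(axis=0)
    ss_within = ss_total - ss_between
    ss_within = np.maximum(ss_within, 0.0)  # guard tiny negative rounding

    df_between = n_classes - 1
    df_within = n - n_classes
    if df_within < 1:
        raise ValueError(
            "every class needs enough training observations for a pooled "
            "within-class variance (n - n_classes >= 1)")

    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    f = np.where(ss_within <= 0, np.where(ss_between > 0, np.inf, 0.0), f)
    return f


def select_k_features_fit_apply(train: np.ndarray, train_labels, test: np.ndarray,
                                k: int):
    """Keep the k features with the largest training-set F statistics.

    Ties are broken in favor of the lower feature index. Both outputs
    preserve the original relative feature order.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    _check_feature_match(train, test)
    n_features = train.shape[1]
    if not 1 <= k <= n_features:
        raise ValueError(f"k must be in [1, {n_features}], got {k}")
    scores = anova_f_scores(train, train_labels)
    # stable sort on -score keeps lower indices first among ties
    top = np.argsort(-scores, kind="stable")[:k]
    kept = np.sort(top)
    state = FeatureSelectState(k=k, scores=scores, kept_feature_indices=kept)
    return train[:, kept], test[:, kept], state


class ZScore:
    """Stateful z-score preprocessor for the cross-validation pipeline."""

    name = "zscore"

    def fit(self, X: np.ndarray, y) -> "ZScore":
        X = np.asarray(X, dtype=float)
        sd = (X.std(axis=0, ddof=1) if X.shape[0] > 1
              else np.zeros(X.shape[1]))
        sd = np.where(np.all(X == X[:1], axis=0), 0.0, sd)
        self.state = ZScoreState(mean=X.mean(axis=0), sd=sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sd = self.state.sd
        safe = np.where(sd > 0, sd, 1.0)
        return np.where(sd > 0, (X - self.state.mean) / safe, 0.0)

    def params(self) -> dict:
        return {"type": "zscore"}


class SelectKFeatures:
    """Stateful top-k ANOVA-F feature selector for the pipeline."""

    name = "select_k_features"

    def __init__(self, k: int):
        self.k = int(k)

    def fit(self, X: np.ndarray, y) -> "SelectKFeatures":
        scores = anova_f_scores(X, y)
        top = np.argsort(-scores, kind="stable")[:self.k]
        self.state = FeatureSelectState(
            k=self.k, scores=scores, kept_feature_indices=np.sort(top))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.state.kept_feature_indices]

    def params(self) -> dict:
        return {"type": "select_k_features", "k": self.k}


def make_preprocessor(spec: dict):
    """Build a preprocessor from a config mapping like {'type': 'zscore'}."""
    kind = spec.get("type")
    if kind == "zscore":
        extra = set(spec) - {"type"}
        if extra:
            raise ConfigError(f"unknown keys for zscore preprocessor: {sorted(extra)}")
        return ZScore()
    if kind == "select_k_features":
        extra = set(spec) - {"type", "k"}
        if extra:
            raise ConfigError(
                f"unknown keys for select_k_features preprocessor: {sorted(extra)}")
        if "k" not in spec:
            raise ConfigError("select_k_features preprocessor requires 'k'")
        return SelectKFeatures(k=spec["k"])
    raise ConfigError(f"unknown preprocessor type {kind!r}")
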