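"""Shrinkage-LDA classification under leave-two-landings-out cross-validation.

Per subject: 8 landings x 12 epochs = 96 examples, two balanced classes. Each
cross-validation fold holds out one landing of each condition (all 4 x 4 = 16
combinations), trains on the remaining 72 epochs and tests on 24. Features
are z-scored with parameters estimated on the training fold only (a global,
leakage-prone variant is available behind a flag for fidelity comparisons).

The classifier is a two-class linear discriminant with the pooled within-
class covariance shrunk toward a scaled identity,

    C(gamma) = (1 - gamma) * S + gamma * (trace(S)/p) * I,

with gamma either the analytic Ledoit-Wolf estimate (default) or a fixed
override; C(gamma) is positive-definite for any gamma > 0, so the rule is
well-defined even when dimensions exceed training examples.

Decoding significance uses the exact binomial chance level: the smallest
integer k with BinomCDF(k; n, 1/c) >= 1 - alpha, reported as 100*k/n percent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.covariance import ledoit_wolf


# ---------------------------------------------------------------------------
# normalization

@dataclass
class Normalizer:
    """Per-dimension z-scoring parameters estimated on a training set."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask of retained (nonzero-sd) dimensions


def fit_normalizer(train: np.ndarray) -> Normalizer:
    train = np.asarray(train, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    # constant columns show up with sd ~ eps*|mean|, not exactly zero; the
    # threshold is relative so legitimately tiny-valued features (molar
    # variances ~1e-14) are retained
    kept = sd > 1e-12 * np.abs(mean)
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} zero-variance dimension(s)",
            RuntimeWarning, stacklevel=2)
    return Normalizer(mean=mean, sd=sd, kept=kept)


def apply_normalizer(norm: Normalizer, rows: np.ndarray) -> np.ndarray:
    rows = np.asarray(rows, dtype=float)
    return (rows[:, norm.kept] - norm.mean[norm.kept]) / norm.sd[norm.kept]


# ---------------------------------------------------------------------------
# folds

@dataclass(frozen=True)
class FoldSpec:
    """One leave-two-landings-out fold (one held-out landing per class)."""

    held_out: tuple[int, int]
    train_idx: np.ndarray
    test_idx: np.ndarray


def make_folds(landing_ids: np.ndarray, labels: np.ndarray) -> list[FoldSpec]:
    """All (landing of class A) x (landing of class B) held-out combinations.

    With 4 + 4 landings of 12 epochs each this yields 16 folds of 72 training
    and 24 test epochs; each fold's test set is class-balanced by
    construction.
    """
    landing_ids = np.asarray(landing_ids)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    per_class = []
    for c in classes:
        lnds = np.unique(landing_ids[labels == c])
        if len(lnds) < 2:
            raise ValueError(f"class {c!r} needs >= 2 landings")
        per_class.append(lnds)
    folds = []
    for a, b in itertools.product(per_class[0], per_class[1]):
        test = np.isin(landing_ids, [a, b])
        folds.append(FoldSpec(held_out=(a, b),
                              train_idx=np.flatnonzero(~test),
                              test_idx=np.flatnonzero(test)))
    return folds


# ---------------------------------------------------------------------------
# shrinkage LDA

@dataclass
class ShrinkageLDAModel:
    classes: np.ndarray
    means: np.ndarray        # (2, p) class means
    covariance: np.ndarray   # (p, p) shrunk pooled covariance
    shrinkage: float
    weights: np.ndarray      # (p,)
    bias: float


def fit_shrinkage_lda(X: np.ndarray, y: np.ndarray,
                      shrinkage: float | None = None) -> ShrinkageLDAModel:
    """Fit the two-class shrinkage LDA.

    ``shrinkage=None`` uses the analytic Ledoit-Wolf intensity estimated on
    the pooled class-centered training data; a float in [0, 1] fixes it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("training set must contain exactly 2 classes")
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} needs >= 2 training rows")
    centered = X.copy()
    for i, c in enumerate(classes):
        centered[y == c] -= means[i]
    p = X.shape[1]
    S = centered.T @ centered / max(1, len(X) - 2)
    mu = np.trace(S) / p
    if shrinkage is None:
        _, gamma = ledoit_wolf(centered, assume_centered=True)
        gamma = float(np.clip(gamma, 1e-6, 1.0))
    else:
        if not 0.0 <= shrinkage <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
        gamma = float(shrinkage)
    C = (1.0 - gamma) * S + gamma * mu * np.eye(p)
    w = np.linalg.solve(C, means[1] - means[0])
    b = -0.5 * float(w @ (means[0] + means[1]))
    return ShrinkageLDAModel(classes=classes, means=means, covariance=C,
                             shrinkage=gamma, weights=w, bias=b)


def predict(model: ShrinkageLDAModel, rows: np.ndarray) -> np.ndarray:
    """Linear decision rule; a score of exactly 0 goes to the first class."""
    rows = np.asarray(rows, dtype=float)
    score = rows @ model.weights + model.bias
    return np.where(score > 0, model.classes[1], model.classes[0])


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class CVResult:
    feature_set: str
    chromophore: str
    subject_id: str
    fold_accuracies: np.ndarray
    n_folds: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_folds = len(self.fold_accuracies)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def cross_validate(X: np.ndarray, y: np.ndarray, folds: list[FoldSpec],
                   shrinkage: float | None = None,
                   global_zscore: bool = False) -> np.ndarray:
    """Per-fold test accuracies: z-score (train-fit), fit LDA, predict.

    ``global_zscore=True`` fits the normalizer on all rows before splitting —
    the leakage-prone variant some studies use — and exists only for
    comparison; the default is fold-wise fitting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    # undefined feature values exclude the dimension, never the epoch
    finite = np.isfinite(X).all(axis=0)
    if not finite.all():
        warnings.warn(
            f"excluding {int((~finite).sum())} non-finite feature dimension(s)",
            RuntimeWarning, stacklevel=2)
        X = X[:, finite]
    accs = []
    if global_zscore:
        norm_all = fit_normalizer(X)
    for fold in folds:
        if global_zscore:
            norm = norm_all
        else:
            norm = fit_normalizer(X[fold.train_idx])
        Xtr = apply_normalizer(norm, X[fold.train_idx])
        Xte = apply_normalizer(norm, X[fold.test_idx])
        model = fit_shrinkage_lda(Xtr, y[fold.train_idx], shrinkage=shrinkage)
        pred = predict(model, Xte)
        accs.append(float(np.mean(pred == y[fold.test_idx])))
    return np.asarray(accs)


def evaluate(feature_blocks: dict[str, np.ndarray], y: np.ndarray,
             landing_ids: np.ndarray, chromophore: str = "HbO",
             subject_id: str = "S01", pairs: bool = True,
             shrinkage: float | None = None,
             global_zscore: bool = False) -> list[CVResult]:
    """Evaluate every single feature and (optionally) every unordered pair.

    ``feature_blocks`` maps feature name -> (n_epochs, dims) matrix; feature
    pairs are column-wise concatenations before normalization. With the 12
    features of the full pipeline this yields 12 + C(12,2) = 78 results per
    chromophore.
    """
    folds = make_folds(landing_ids, y)
    names = list(feature_blocks)
    results = []
    for name in names:
        accs = cross_validate(feature_blocks[name], y, folds,
                              shrinkage=shrinkage, global_zscore=global_zscore)
        results.append(CVResult(name, chromophore, subject_id, accs))
    if pairs:
        for a, b in itertools.combinations(names, 2):
            X = np.concatenate([feature_blocks[a], feature_blocks[b]], axis=1)
            accs = cross_validate(X, y, folds, shrinkage=shrinkage,
                                  global_zscore=global_zscore)
            results.append(CVResult(f"{a}+{b}", chromophore, subject_id, accs))
    return results


# ---------------------------------------------------------------------------
# chance level

@dataclass(frozen=True)
class SignificanceSpec:
    n: int = 96
    n_classes: int = 2
    alpha: float = 0.05


def chance_threshold(spec: SignificanceSpec) -> float:
    """Exact binomial chance-level threshold, in percent.

    Smallest integer k with BinomCDF(k; n, 1/c) >= 1 - alpha, returned as
    100*k/n. For n = 96, c = 2, alpha = 0.05 this gives 58.33%; as n grows
    the threshold approaches the theoretical 100/c.
    """
    if spec.n < 1:
        raise ValueError("n must be >= 1")
    if spec.n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not 0.0 < spec.alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    k = int(stats.binom.ppf(1.0 - spec.alpha, spec.n, 1.0 / spec.n_classes))
    return 100.0 * k / spec.n
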