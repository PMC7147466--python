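"""Per-patient supervised learning and model selection.

Each candidate model is a subset of the 11 feature groups fed to either a
support vector machine (RBF kernel) or a small multilayer perceptron.  A
candidate is scored by repeated stratified k-fold cross-validation: per
repetition the k folds' held-out confusion counts are pooled into one
confusion matrix (stable even when a class has very few members), metrics
are computed from the pooled counts, and the final score is the arithmetic
mean over repetitions of the per-repetition geometric mean of sensitivity
and specificity,

    Gmean = sqrt(SN * SP),

which weighs missed hypoglycemic nights and false alarms equally.  The
exhaustive search enumerates all 2^11 = 2048 group masks (the empty mask
is skipped) and returns them ranked by mean Gmean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .instances import GROUP_INDICES, GROUP_NAMES, N_GROUPS

log = logging.getLogger(__name__)

N_MASKS = 2**N_GROUPS  # 2048 candidate feature vectors


class StratificationError(ValueError):
    """A class is too small for the requested number of folds."""


def gmean(sn: float, sp: float) -> float:
    """Geometric mean of sensitivity and specificity (percent scale)."""
    for name, v in (("sn", sn), ("sp", sp)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    return float(np.sqrt(sn * sp))


@dataclass(frozen=True)
class MetricSet:
    """Confusion counts and the derived percentage metrics."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sn(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else 0.0

    @property
    def sp(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else 0.0

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else 0.0

    @property
    def gmean(self) -> float:
        return gmean(self.sn, self.sp)


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified cross-validation settings."""

    k: int = 5
    repetitions: int = 100
    base_seed: int = 0
    classifier: str = "svm"  # or "mlp"
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.classifier not in ("svm", "mlp"):
            raise ValueError(f"unknown classifier {self.classifier!r}")


def make_classifier(cv: CVConfig, seed: int):
    """Fresh estimator with the configured hyperparameters."""
    if cv.classifier == "svm":
        params = {"kernel": "rbf", "C": 1.0, "gamma": "scale", "class_weight": "balanced"}
        params.update(cv.hyperparams)
        return SVC(**params)
    params = {
        "hidden_layer_sizes": (8,),
        "activation": "logistic",
        "max_iter": 500,
        "random_state": seed,
    }
    params.update(cv.hyperparams)
    return MLPClassifier(**params)


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per instance).

    Every fold's per-class count differs from the proportional share by
    less than one instance.  Raises if any class has fewer than k members.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    for c, n in zip(classes, counts):
        if n < k:
            raise StratificationError(f"class {c} has only {n} member(s) but k={k}")
    folds = np.empty(len(labels), dtype=int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold_id, (_, test_idx) in enumerate(splitter.split(np.zeros((len(labels), 1)), labels)):
        folds[test_idx] = fold_id
    return folds


def effective_k(labels: np.ndarray, k: int) -> int:
    """Fold count usable for this label vector: k capped at the minority
    class size (patients with very few positive nights)."""
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=2)
    minority = int(counts.min())
    if minority < 2:
        raise StratificationError(f"minority class has {minority} member(s); need >= 2")
    if minority < k:
        log.info("reducing k from %d to minority class size %d", k, minority)
        return minority
    return k


def mask_to_columns(mask: int) -> np.ndarray:
    """Feature-column indices selected by an 11-bit group mask."""
    if not 0 < mask < N_MASKS:
        raise ValueError(f"mask must be in [1, {N_MASKS - 1}], got {mask}")
    cols = [GROUP_INDICES[GROUP_NAMES[b]] for b in range(N_GROUPS) if mask >> b & 1]
    return np.concatenate(cols)


def mask_groups(mask: int) -> tuple[str, ...]:
    return tuple(GROUP_NAMES[b] for b in range(N_GROUPS) if mask >> b & 1)


@dataclass
class SubsetResult:
    """Cross-validated performance of one feature-group subset."""

    mask: int
    groups: tuple[str, ...]
    n_features: int
    per_repetition: list[MetricSet]
    mean_sn: float
    mean_sp: float
    mean_accuracy: float
    mean_gmean: float


def _summarize(mask: int, metrics: list[MetricSet]) -> SubsetResult:
    return SubsetResult(
        mask=mask,
        groups=mask_groups(mask),
        n_features=len(mask_to_columns(mask)),
        per_repetition=metrics,
        mean_sn=float(np.mean([m.sn for m in metrics])),
        mean_sp=float(np.mean([m.sp for m in metrics])),
        mean_accuracy=float(np.mean([m.accuracy for m in metrics])),
        # NB: mean of per-repetition Gmeans, not the Gmean of the means
        mean_gmean=float(np.mean([m.gmean for m in metrics])),
    )


def _zscore_pair(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z-score both parts with the training part's mean/sd (sd 0 -> left as-is),
    matching ``StandardScaler`` semantics."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def repetition_folds(y: np.ndarray, k: int, cv: CVConfig) -> list[np.ndarray]:
    """Fold assignments for every repetition (seed = base_seed + r).

    The assignment depends only on (labels, k, seed), so it is shared by
    every feature subset evaluated under the same CVConfig.
    """
    return [stratified_folds(y, k, cv.base_seed + r) for r in range(cv.repetitions)]


def evaluate_subset(X: np.ndarray, y: np.ndarray, mask: int, cv: CVConfig,
                    folds_per_rep: list[np.ndarray] | None = None) -> SubsetResult:
    """Repeated stratified k-fold evaluation of one group mask.

    Per repetition r (fold seed = ``base_seed + r``): features are
    z-scored on each training part, the classifier is fit and applied to
    the held-out fold, and the k folds' confusion counts are pooled.
    Repetitions with a degenerate (single-class) training fold are skipped
    and logged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cols = mask_to_columns(mask)
    Xm = X[:, cols]
    k = effective_k(y, cv.k)
    if folds_per_rep is None:
        folds_per_rep = repetition_folds(y, k, cv)
    metrics: list[MetricSet] = []
    for r, folds in enumerate(folds_per_rep):
        seed = cv.base_seed + r
        tp = fn = tn = fp = 0
        degenerate = False
        for fold_id in range(k):
            test = folds == fold_id
            train = ~test
            if len(np.unique(y[train])) < 2:
                degenerate = True
                break
            Xtr, Xte = _zscore_pair(Xm[train], Xm[test])
            clf = make_classifier(cv, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xtr, y[train])
                pred = clf.predict(Xte)
            truth = y[test]
            tp += int(((pred == 1) & (truth == 1)).sum())
            fn += int(((pred == 0) & (truth == 1)).sum())
            tn += int(((pred == 0) & (truth == 0)).sum())
            fp += int(((pred == 1) & (truth == 0)).sum())
        if degenerate:
            log.warning("repetition %d skipped: single-class training fold", r)
            continue
        metrics.append(MetricSet(tp=tp, fn=fn, tn=tn, fp=fp))
    if not metrics:
        raise StratificationError("all repetitions degenerate; cannot evaluate subset")
    return _summarize(mask, metrics)


def rank_results(results: list[SubsetResult]) -> list[SubsetResult]:
    """Best first: higher mean Gmean, then fewer features, then lower mask."""
    return sorted(results, key=lambda s: (-s.mean_gmean, s.n_features, s.mask))


def exhaustive_search(X: np.ndarray, y: np.ndarray, cv: CVConfig,
                      progress_every: int = 0) -> tuple[list[SubsetResult], SubsetResult]:
    """Evaluate all 2048 group masks (2047 after skipping the empty one).

    Returns the ranked result list and the best subset.  Fold assignments
    are functions of (labels, k, repetition seed) only and are therefore
    shared across masks.
    """
    y = np.asarray(y, dtype=int)
    folds_per_rep = repetition_folds(y, effective_k(y, cv.k), cv)
    results: list[SubsetResult] = []
    for mask in range(1, N_MASKS):
        results.append(evaluate_subset(X, y, mask, cv, folds_per_rep=folds_per_rep))
        if progress_every and mask % progress_every == 0:
            log.info("evaluated %d/%d masks (best Gmean so far %.2f)",
                     mask, N_MASKS - 1, max(r.mean_gmean for r in results))
    ranked = rank_results(results)
    return ranked, ranked[0]
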