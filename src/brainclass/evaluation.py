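"""Repeated k-fold cross-validation, modal-scenario selection, and confusion
matrix / tensor summaries with sensitivity and specificity.

Count percentages are reported against a caller-supplied cohort size with
half-up rounding to two decimals.  The four-group summary keys its cells by
the diagnosis-by-sex design; a "published-style" rendering with the FP/FN
labels swapped relative to convention is available from the summary object.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .exceptions import ConfigurationError, InvalidInputError
from .preprocess import apply_standardization, fit_pca, project, standardize
from .svm import (
    KernelSpec,
    TrainingConfig,
    decision_values,
    predict_ovo,
    train_binary_svm,
    train_ovo,
    two_group_config,
    four_group_config,
)

__all__ = [
    "CVSettings",
    "CVRunSet",
    "ConfusionSummary",
    "make_cv_folds",
    "run_repeated_cv",
    "most_frequent_scenario",
    "confusion_summary",
    "group_labels",
]

FOUR_GROUPS = ("ASD_M", "ASD_F", "TD_M", "TD_F")


def group_labels(cohort: pd.DataFrame, mode: str) -> np.ndarray:
    """Classification target per subject: diagnosis or diagnosis-by-sex."""
    if mode == "two_group":
        return cohort["diagnosis"].astype(str).to_numpy()
    if mode == "four_group":
        return (
            cohort["diagnosis"].astype(str) + "_" + cohort["sex"].astype(str)
        ).to_numpy()
    raise ConfigurationError("mode must be 'two_group' or 'four_group'")


@dataclass(frozen=True)
class CVSettings:
    """Configuration of one repeated-CV experiment."""

    mode: str = "two_group"
    n_folds: int = 10
    stratify: bool = False
    kernel: KernelSpec | None = None
    training: TrainingConfig | None = None
    pca_threshold: float | None = 0.95
    pca_scope: str = "fold"  # fit PCA inside each training fold, or 'global'

    def __post_init__(self) -> None:
        if self.mode not in ("two_group", "four_group"):
            raise ConfigurationError("mode must be 'two_group' or 'four_group'")
        if self.pca_scope not in ("fold", "global"):
            raise ConfigurationError("pca_scope must be 'fold' or 'global'")

    def resolved_kernel(self) -> KernelSpec:
        if self.kernel is not None:
            return self.kernel
        if self.mode == "two_group":
            return KernelSpec(kind="linear")
        return KernelSpec(kind="polynomial", degree=2, offset=1.0)

    def resolved_training(self) -> TrainingConfig:
        if self.training is not None:
            return self.training
        return two_group_config() if self.mode == "two_group" else four_group_config()


@dataclass(eq=False)
class CVRunSet:
    """Fold assignments, out-of-fold predictions, and accuracies per repetition."""

    fold_assignments: np.ndarray  # (reps, n) int
    predictions: np.ndarray  # (reps, n) object
    true_labels: np.ndarray  # (n,) object
    accuracies: np.ndarray  # (reps,)
    settings: CVSettings
    base_seed: int

    @property
    def n_repetitions(self) -> int:
        return self.fold_assignments.shape[0]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        """Across-repetition SD (n-1 denominator); 0 for a single repetition."""
        if self.n_repetitions < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1))

    @property
    def single_repetition(self) -> bool:
        return self.n_repetitions < 2

    def scenario_keys(self) -> list[tuple]:
        return [tuple(row) for row in self.predictions]


def make_cv_folds(
    n: int,
    k: int = 10,
    seed: int = 0,
    stratify_by: np.ndarray | None = None,
) -> np.ndarray:
    """Random disjoint fold assignment: fold id in [0, k) per subject.

    Fold sizes differ by at most one.  With ``stratify_by``, members of each
    group are dealt round-robin so per-group proportions are preserved within
    one subject per fold.
    """
    if k < 1 or k > n:
        raise ConfigurationError("need 1 <= k <= n")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if stratify_by is None:
        perm = rng.permutation(n)
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        stop = np.cumsum(sizes)
        start = stop - sizes
        for f in range(k):
            folds[perm[start[f] : stop[f]]] = f
        return folds
    groups = np.asarray(stratify_by)
    pointer = 0
    for g in pd.unique(groups):
        members = np.flatnonzero(groups == g)
        members = rng.permutation(members)
        for m in members:
            folds[m] = pointer % k
            pointer += 1
    return folds


def _fit_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    settings: CVSettings,
    seed: int,
) -> np.ndarray:
    """Standardize -> (optional PCA) -> train -> predict one held-out fold."""
    xt, stz = standardize(x_train)
    xs = apply_standardization(x_test, stz)
    if settings.pca_threshold is not None and settings.pca_scope == "fold":
        model = fit_pca(xt, settings.pca_threshold)
        xt = project(model, xt)
        xs = project(model, xs)
    kernel = settings.resolved_kernel()
    training = settings.resolved_training()
    if settings.mode == "two_group":
        y = np.where(y_train == "ASD", 1.0, -1.0)
        model = train_binary_svm(xt, y, training, kernel, seed)
        c = decision_values(model, xs)
        return np.where(c >= 0, "ASD", "TD").astype(object)
    clf = train_ovo(xt, y_train, training, kernel, seed)
    return predict_ovo(clf, xs)


def run_repeated_cv(
    features: pd.DataFrame | np.ndarray,
    cohort: pd.DataFrame,
    settings: CVSettings = CVSettings(),
    n_repetitions: int = 500,
    base_seed: int = 0,
) -> CVRunSet:
    """Repeat k-fold CV with fresh fold assignments per repetition.

    Repetition r uses fold seed ``base_seed + r``.  Preprocessing is fitted
    on the training folds only (unless ``pca_scope='global'``, which mirrors
    whole-sample fitting).
    """
    x = np.asarray(features, dtype=float)
    labels = group_labels(cohort, settings.mode)
    n = x.shape[0]
    if n != len(cohort):
        raise InvalidInputError("features and cohort disagree on subject count")
    eff = settings
    if settings.pca_threshold is not None and settings.pca_scope == "global":
        xs, _ = standardize(x)
        model = fit_pca(xs, settings.pca_threshold)
        x = project(model, xs)
        eff = replace(settings, pca_threshold=None)
    k = settings.n_folds
    fold_assignments = np.empty((n_repetitions, n), dtype=int)
    predictions = np.empty((n_repetitions, n), dtype=object)
    accuracies = np.empty(n_repetitions)
    for r in range(n_repetitions):
        seed = base_seed + r
        folds = make_cv_folds(
            n, k, seed=seed, stratify_by=labels if settings.stratify else None
        )
        fold_assignments[r] = folds
        for f in range(k):
            test = folds == f
            try:
                predictions[r, test] = _fit_predict(
                    x[~test], labels[~test], x[test], eff, seed
                )
            except Exception as exc:  # noqa: BLE001 - annotate origin, re-raise
                raise type(exc)(f"repetition {r}, fold {f}: {exc}") from exc
        accuracies[r] = np.mean(predictions[r] == labels)
    return CVRunSet(
        fold_assignments, predictions, labels, accuracies, settings, base_seed
    )


def most_frequent_scenario(runs: CVRunSet) -> tuple[tuple, int, int]:
    """Modal out-of-fold prediction vector across repetitions.

    Returns (scenario key, number of matching repetitions, representative
    repetition index).  Ties go to the scenario seen earliest.
    """
    if runs.n_repetitions < 1:
        raise InvalidInputError("need at least one repetition")
    keys = runs.scenario_keys()
    counts = Counter(keys)
    best_count = max(counts.values())
    for idx, key in enumerate(keys):
        if counts[key] == best_count:
            return key, best_count, idx
    raise AssertionError("unreachable")


@dataclass(eq=False)
class ConfusionSummary:
    """Counts, cohort percentages, sensitivity, and specificity.

    Standard conventions are stored (FN = positive misclassified as
    negative, FP = negative misclassified as positive); ``published_view`` emits
    the published-style rendering with those two labels swapped.
    """

    mode: str
    counts: dict[str, int]
    n_total: int
    sensitivity: float
    specificity: float
    percentages: dict[str, float] = field(default_factory=dict)

    def published_view(self) -> dict[str, int]:
        swap = {"FN": "FP", "FP": "FN"}
        out = {}
        for key, v in self.counts.items():
            head = key.split("_")[0]
            if head in swap:
                out[swap[head] + key[2:]] = v
            else:
                out[key] = v
        return out


def confusion_summary(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    mode: str = "two_group",
    n_total: int | None = None,
    positive: str = "ASD",
) -> ConfusionSummary:
    """Confusion counts and the derived sensitivity/specificity percentages.

    two_group: sensitivity = 100 TP / (TP + FN), specificity = 100 TN /
    (TN + FP).  four_group: sensitivity = 100 (TP_M + TP_F) / (total true
    positive-diagnosis subjects), specificity analogously over the negatives;
    the counts dict carries the eight diagnosis cells plus any sex-only
    confusions so that all counts sum to the number classified.
    """
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if t.shape != p.shape:
        raise InvalidInputError("label vectors must have equal length")
    n_total = int(n_total) if n_total is not None else len(t)
    if mode == "two_group":
        valid = {positive, "TD"}
        if not (set(t) | set(p)) <= valid:
            raise InvalidInputError(f"unknown labels: {sorted((set(t) | set(p)) - valid)}")
        tp = int(np.sum((t == positive) & (p == positive)))
        tn = int(np.sum((t != positive) & (p != positive)))
        fn = int(np.sum((t == positive) & (p != positive)))
        fp = int(np.sum((t != positive) & (p == positive)))
        counts = {"TP": tp, "TN": tn, "FN": fn, "FP": fp}
        sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    elif mode == "four_group":
        valid = set(FOUR_GROUPS)
        if not (set(t) | set(p)) <= valid:
            raise InvalidInputError(f"unknown labels: {sorted((set(t) | set(p)) - valid)}")
        tdx = np.array([s.split("_")[0] for s in t])
        pdx = np.array([s.split("_")[0] for s in p])
        sex = np.array([s.split("_")[1] for s in t])
        counts = {}
        for sx in ("M", "F"):
            is_sx = sex == sx
            counts[f"TP_{sx}"] = int(np.sum(is_sx & (t == p) & (tdx == "ASD")))
            counts[f"TN_{sx}"] = int(np.sum(is_sx & (t == p) & (tdx == "TD")))
            counts[f"FN_{sx}"] = int(np.sum(is_sx & (tdx == "ASD") & (pdx == "TD")))
            counts[f"FP_{sx}"] = int(np.sum(is_sx & (tdx == "TD") & (pdx == "ASD")))
            counts[f"SEXERR_{sx}"] = int(
                np.sum(is_sx & (tdx == pdx) & (t != p))
            )
        n_pos = int(np.sum(tdx == "ASD"))
        n_neg = int(np.sum(tdx == "TD"))
        sens = 100.0 * (counts["TP_M"] + counts["TP_F"]) / n_pos if n_pos else 0.0
        spec = 100.0 * (counts["TN_M"] + counts["TN_F"]) / n_neg if n_neg else 0.0
    else:
        raise ConfigurationError("mode must be 'two_group' or 'four_group'")
    percentages = {
        key: round_half_up(100.0 * v / n_total) for key, v in counts.items()
    }
    return ConfusionSummary(
        mode=mode,
        counts=counts,
        n_total=n_total,
        sensitivity=round_half_up(sens),
        specificity=round_half_up(spec),
        percentages=percentages,
    )
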