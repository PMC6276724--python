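"""From-scratch soft-margin kernel SVM trained by sequential minimal
optimization (SMO), with per-class box constraints for unbalanced designs and
a one-vs-one multiclass ensemble.

The dual problem solved is

    min_a  1/2 a' Q a - e' a    s.t.  y' a = 0,  0 <= a_i <= C_i,

with Q_ij = y_i y_j k(x_i, x_j).  The working-set selection is the classic
maximal-violating-pair rule; convergence is declared when the KKT violation
gap m(a) - M(a) drops below the configured tolerance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError, ConvergenceError, InvalidInputError

__all__ = [
    "KernelSpec",
    "TrainingConfig",
    "SVMModel",
    "OVOClassifier",
    "kernel_eval",
    "kernel_matrix",
    "class_box_constraints",
    "train_binary_svm",
    "check_kkt",
    "decision_value",
    "decision_values",
    "train_ovo",
    "predict_ovo",
    "two_group_config",
    "four_group_config",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    linear: <x, y>; rbf: exp(-||x - y||^2 / (2 sigma^2));
    polynomial: (<x, y> + offset)^degree.
    """

    kind: str = "linear"
    sigma: float = 1.0
    degree: int = 2
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf", "polynomial"):
            raise ConfigurationError(f"unknown kernel kind {self.kind!r}")
        if self.sigma <= 0:
            raise ConfigurationError("rbf sigma must be positive")
        if int(self.degree) != self.degree or self.degree < 1:
            raise ConfigurationError("polynomial degree must be an integer >= 1")


@dataclass(frozen=True)
class TrainingConfig:
    """SMO training knobs.

    ``box_scale`` multiplies every per-class box constraint (the four-group
    misclassification penalty parameter); ``gamma`` is the optional
    grid-search axis value retained for provenance; ``box_scheme`` chooses
    between the balanced (C inversely proportional to class size) and the
    literal printed assignment of class constraints.
    """

    kkt_tol: float = 1e-3
    box_scale: float = 1.0
    gamma: float = 0.25
    box_scheme: str = "balanced"
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if self.kkt_tol <= 0 or self.box_scale <= 0 or self.gamma <= 0:
            raise ConfigurationError("tolerances and scales must be positive")
        if self.box_scheme not in ("balanced", "literal"):
            raise ConfigurationError("box_scheme must be 'balanced' or 'literal'")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")


def two_group_config(**overrides) -> TrainingConfig:
    """Defaults for two-group training: KKT tolerance 0.001."""
    return replace(TrainingConfig(kkt_tol=1e-3), **overrides)


def four_group_config(**overrides) -> TrainingConfig:
    """Defaults for four-group training: tolerance 2^-0.77, penalty 2^-16,
    grid parameter gamma = 0.25."""
    cfg = TrainingConfig(kkt_tol=2.0**-0.77, box_scale=2.0**-16, gamma=0.25)
    return replace(cfg, **overrides)


def kernel_eval(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> float:
    """Evaluate the kernel on a single pair of vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("kernel arguments must share a dimension")
    return float(kernel_matrix(spec, x[None, :], y[None, :])[0, 0])


def kernel_matrix(spec: KernelSpec, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise InvalidInputError("kernel arguments must share a dimension")
    if spec.kind == "linear":
        return a @ b.T
    if spec.kind == "polynomial":
        return (a @ b.T + spec.offset) ** spec.degree
    sq = (
        np.sum(a**2, axis=1)[:, None]
        + np.sum(b**2, axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return np.exp(-np.maximum(sq, 0.0) / (2.0 * spec.sigma**2))


def class_box_constraints(
    n_first: int, n_second: int, scheme: str = "balanced"
) -> tuple[float, float]:
    """Per-class box constraints (C_first, C_second) for an unbalanced pair.

    balanced: C_class = N / (2 n_class), so the smaller class receives the
    larger constraint.  literal: the printed assignment, i.e., the two values
    swapped between the classes.
    """
    if n_first < 1 or n_second < 1:
        raise ConfigurationError("class counts must be >= 1")
    n = n_first + n_second
    if scheme == "balanced":
        return n / (2.0 * n_first), n / (2.0 * n_second)
    if scheme == "literal":
        return n / (2.0 * n_second), n / (2.0 * n_first)
    raise ConfigurationError("scheme must be 'balanced' or 'literal'")


@dataclass(eq=False)
class SVMModel:
    """Trained decision function c(x) = sum_i a_i k(s_i, x) + b.

    ``weights`` are the signed dual coefficients a_i = alpha_i y_i of the
    support vectors ``support_vectors``.  The full training-time dual
    solution is kept for KKT verification.
    """

    support_vectors: np.ndarray
    weights: np.ndarray
    bias: float
    kernel: KernelSpec
    first_label: object = 1
    second_label: object = -1
    alpha: np.ndarray | None = None
    box: np.ndarray | None = None
    dual_objective: float | None = None

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]


def _box_per_sample(y: np.ndarray, config: TrainingConfig) -> np.ndarray:
    c_pos, c_neg = class_box_constraints(
        int(np.sum(y > 0)), int(np.sum(y < 0)), config.box_scheme
    )
    return config.box_scale * np.where(y > 0, c_pos, c_neg)


def train_binary_svm(
    scores: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig | None = None,
    kernel: KernelSpec | None = None,
    seed: int = 0,
) -> SVMModel:
    """Maximize the soft-margin dual by SMO under per-class box constraints.

    ``labels`` must be in {+1, -1} with both classes present.  Training is
    deterministic: the maximal-violating-pair selection has no random
    component and ``seed`` is accepted only for interface uniformity.
    """
    del seed  # deterministic algorithm
    config = config or TrainingConfig()
    kernel = kernel or KernelSpec()
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 2 or y.shape != (x.shape[0],):
        raise InvalidInputError("scores must be (n, d) with one label per row")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise InvalidInputError("labels must be +1 or -1")
    if not np.isfinite(x).all():
        raise InvalidInputError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes must be present")

    c = _box_per_sample(y, config)
    k = kernel_matrix(kernel, x, x)
    q = (y[:, None] * y[None, :]) * k
    n = x.shape[0]
    alpha = np.zeros(n)
    grad = -np.ones(n)  # grad = Q a - e
    tol = config.kkt_tol

    for _ in range(config.max_iter):
        up = ((y > 0) & (alpha < c)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < c))
        neg_yg = -y * grad
        m_val = np.max(neg_yg[up])
        big_m = np.min(neg_yg[low])
        if m_val - big_m <= tol:
            break
        i = int(np.flatnonzero(up)[np.argmax(neg_yg[up])])
        j = int(np.flatnonzero(low)[np.argmin(neg_yg[low])])
        # line search along a_i += y_i t, a_j -= y_j t
        quad = k[i, i] + k[j, j] - 2.0 * k[i, j]
        t = (neg_yg[i] - neg_yg[j]) / max(quad, 1e-12)
        t_lo_i, t_hi_i = sorted(((0 - alpha[i]) * y[i], (c[i] - alpha[i]) * y[i]))
        t_lo_j, t_hi_j = sorted(((alpha[j] - c[j]) * y[j], (alpha[j] - 0) * y[j]))
        t = float(np.clip(t, max(t_lo_i, t_lo_j), min(t_hi_i, t_hi_j)))
        if t == 0.0:
            break
        alpha[i] += y[i] * t
        alpha[j] -= y[j] * t
        grad += t * (y[i] * q[:, i] - y[j] * q[:, j])
    else:
        raise ConvergenceError(
            f"SMO did not converge in {config.max_iter} iterations",
            worst_violation=float(m_val - big_m),
        )

    free = (alpha > 1e-10) & (alpha < c - 1e-10)
    if np.any(free):
        bias = float(np.mean((-y * grad)[free]))
    else:
        bias = float((m_val + big_m) / 2.0)
    sv = alpha > 1e-10
    dual = float(np.sum(alpha) - 0.5 * alpha @ q @ alpha)
    return SVMModel(
        support_vectors=x[sv].copy(),
        weights=(alpha * y)[sv].copy(),
        bias=bias,
        kernel=kernel,
        alpha=alpha,
        box=c,
        dual_objective=dual,
    )


def decision_value(model: SVMModel, x: np.ndarray) -> tuple[float, object]:
    """Decision value c(x) and the winning label (first group iff c >= 0)."""
    c = float(decision_values(model, np.atleast_2d(np.asarray(x, float)))[0])
    return c, (model.first_label if c >= 0 else model.second_label)


def decision_values(model: SVMModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if model.n_support == 0:
        return np.full(x.shape[0], model.bias)
    if x.shape[1] != model.support_vectors.shape[1]:
        raise InvalidInputError("dimension does not match the trained model")
    return kernel_matrix(model.kernel, x, model.support_vectors) @ model.weights + model.bias


def check_kkt(
    model: SVMModel,
    scores: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig,
) -> tuple[bool, float]:
    """Case-wise KKT verification of a trained model on its training set.

    alpha = 0  =>  y f(x) >= 1 - tol;  0 < alpha < C  =>  |y f(x) - 1| <= tol;
    alpha = C  =>  y f(x) <= 1 + tol;  and |sum_i a_i| <= tol.
    Returns (all satisfied, worst violation).
    """
    if model.alpha is None or model.box is None:
        raise InvalidInputError("model lacks its training-time dual solution")
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    f = decision_values(model, x)
    yf = y * f
    alpha, c = model.alpha, model.box
    tol = config.kkt_tol
    eps = 1e-10
    violations = [abs(float(np.sum(alpha * y)))]
    at_zero = alpha <= eps
    at_c = alpha >= c - eps
    interior = ~at_zero & ~at_c
    if np.any(at_zero):
        violations.append(float(np.max(1.0 - yf[at_zero], initial=0.0)))
    if np.any(interior):
        violations.append(float(np.max(np.abs(yf[interior] - 1.0), initial=0.0)))
    if np.any(at_c):
        violations.append(float(np.max(yf[at_c] - 1.0, initial=0.0)))
    worst = max(violations)
    return worst <= tol, worst


@dataclass(eq=False)
class OVOClassifier:
    """One binary model per unordered class pair, combined by majority vote."""

    models: tuple[tuple[tuple[object, object], SVMModel], ...]
    classes: tuple[object, ...]

    def __post_init__(self) -> None:
        m = len(self.classes)
        if len(self.models) != m * (m - 1) // 2:
            raise ConfigurationError("OVO requires one model per class pair")


def train_ovo(
    scores: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig | None = None,
    kernel: KernelSpec | None = None,
    seed: int = 0,
) -> OVOClassifier:
    """Train C(m, 2) pairwise binary SVMs with per-pair box constraints.

    Class order follows first appearance in ``labels``; within a pair, the
    earlier class is the "first group" mapped to +1.
    """
    config = config or four_group_config()
    kernel = kernel or KernelSpec(kind="polynomial", degree=2, offset=1.0)
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(dict.fromkeys(labels.tolist()))
    if len(classes) < 2:
        raise InvalidInputError("need at least two classes")
    counts = {cl: int(np.sum(labels == cl)) for cl in classes}
    thin = [cl for cl, ct in counts.items() if ct < 2]
    if thin:
        raise InvalidInputError(f"classes with fewer than 2 members: {thin}")
    models = []
    for a, b in itertools.combinations(classes, 2):
        mask = (labels == a) | (labels == b)
        y = np.where(labels[mask] == a, 1.0, -1.0)
        model = train_binary_svm(x[mask], y, config, kernel, seed)
        model.first_label = a
        model.second_label = b
        models.append(((a, b), model))
    return OVOClassifier(tuple(models), classes)


def predict_ovo(classifier: OVOClassifier, x: np.ndarray) -> np.ndarray:
    """Majority vote over pairwise decisions for each row of ``x``.

    Ties are broken by the largest summed |decision value| among the tied
    classes, then by class order.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    classes = classifier.classes
    votes = {cl: np.zeros(n) for cl in classes}
    strength = {cl: np.zeros(n) for cl in classes}
    for (a, b), model in classifier.models:
        c = decision_values(model, x)
        win_a = c >= 0
        votes[a] += win_a
        votes[b] += ~win_a
        strength[a] += np.where(win_a, np.abs(c), 0.0)
        strength[b] += np.where(win_a, 0.0, np.abs(c))
    out = np.empty(n, dtype=object)
    for r in range(n):
        best = max(
            classes,
            key=lambda cl: (
                votes[cl][r],
                strength[cl][r],
                -classes.index(cl),
            ),
        )
        out[r] = best
    return out
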