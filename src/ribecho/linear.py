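"""Linear classifiers on the 70-entry feature vectors.

Both fitters minimize an L2-regularized mean surrogate loss over the
affine score ``f(x) = w.x + b``:

* logistic regression — the deviance loss ``log(1 + exp(-y f))``,
* linear SVM — the hinge loss ``max(0, 1 - y f)`` with regularization
  ``1 / (C n)`` so that C plays the usual box-constraint role.

Optimization runs a deterministic quasi-Newton solver from a zero start,
so fits are reproducible and invariant to sample order. The ternary task
uses a one-vs-one ensemble of three pairwise binary models with majority-
vote decoding; ties fall to the class with the largest summed absolute
margin. Class imbalance is handled by seeded undersampling to the
minority-class count before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import ConfigurationError, ContractError, DataError, FittingError
from .features import FEATURE_NAMES, SCHEMA_HASH

_GTOL = 1e-8
_MAXITER = 10_000


@dataclass
class LinearModel:
    """One binary affine classifier: predict positive iff w.x + b >= 0."""

    weights: np.ndarray
    bias: float
    loss: str                       # "logistic" | "hinge"
    reg_strength: float
    label_pair: tuple[str, str]     # (negative, positive)
    feature_subset: tuple[str, ...] = FEATURE_NAMES
    schema_hash: str = SCHEMA_HASH

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.feature_subset),):
            raise ContractError("weight count must match feature_subset")
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise FittingError("non-finite model parameters")

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.weights + self.bias


@dataclass
class OvoEnsemble:
    """One-vs-one ternary ensemble with majority-vote decoding."""

    classes: tuple[str, str, str]
    members: list[LinearModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) != 3:
            raise ContractError("one-vs-one ternary ensemble needs 3 members")
        subsets = {m.feature_subset for m in self.members}
        losses = {m.loss for m in self.members}
        if len(subsets) != 1 or len(losses) != 1:
            raise ContractError("members must share feature_subset and loss")

    @property
    def feature_subset(self) -> tuple[str, ...]:
        return self.members[0].feature_subset

    @property
    def loss(self) -> str:
        return self.members[0].loss


def balance_classes(labels, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subset (undersampled without replacement).

    Each class is randomly reduced to the minority-class count under the
    seed; the returned indices are sorted, so an already balanced input
    comes back as the identity permutation.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any() or classes.size < 2:
        raise DataError("balancing requires at least two nonempty classes")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


def _prepare(X, labels, positive_class):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise DataError("features must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise DataError("features must be finite")
    classes = sorted(np.unique(labels).tolist())
    if len(classes) != 2:
        raise DataError(f"binary fit requires 2 classes, got {len(classes)}")
    if positive_class is None:
        positive_class = classes[1]
    if positive_class not in classes:
        raise DataError(f"positive class {positive_class!r} not in labels")
    negative_class = classes[0] if classes[1] == positive_class else classes[1]
    y = np.where(labels == positive_class, 1.0, -1.0)
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise DataError("need at least 2 samples per class")
    return X, y, (negative_class, positive_class)


def _minimize(objective, n_features, require_convergence: bool):
    x0 = np.zeros(n_features + 1)
    res = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": _MAXITER, "gtol": _GTOL, "ftol": 1e-14},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if not np.all(np.isfinite(res.x)):
        raise FittingError("solver produced non-finite parameters")
    if require_convergence and not res.success and grad_norm > 1e-4:
        raise FittingError(
            f"solver did not converge (final gradient norm {grad_norm:.2e})")
    return res.x[:-1], float(res.x[-1])


def fit_logistic(X, labels, reg_strength: float | None = None,
                 positive_class: str | None = None,
                 feature_subset: tuple[str, ...] = FEATURE_NAMES,
                 ) -> LinearModel:
    """L2-regularized logistic regression (deviance loss), lambda = 1/n."""
    X, y, pair = _prepare(X, labels, positive_class)
    lam = 1.0 / X.shape[0] if reg_strength is None else reg_strength
    if lam < 0:
        raise ConfigurationError("reg_strength must be >= 0")

    def objective(params):
        w, b = params[:-1], params[-1]
        margin = y * (X @ w + b)
        loss = np.mean(np.logaddexp(0.0, -margin)) + 0.5 * lam * w @ w
        sig = 1.0 / (1.0 + np.exp(np.clip(margin, -500, 500)))
        coef = -y * sig / y.size
        return loss, np.concatenate([X.T @ coef + lam * w, [coef.sum()]])

    w, b = _minimize(objective, X.shape[1], require_convergence=True)
    return LinearModel(w, b, "logistic", lam, pair, feature_subset)


def fit_svm(X, labels, box_constraint: float = 1.0,
            positive_class: str | None = None,
            feature_subset: tuple[str, ...] = FEATURE_NAMES) -> LinearModel:
    """Linear SVM: L2-regularized mean hinge loss, lambda = 1/(C n)."""
    if box_constraint <= 0:
        raise ConfigurationError("box_constraint must be > 0")
    X, y, pair = _prepare(X, labels, positive_class)
    lam = 1.0 / (box_constraint * X.shape[0])

    def objective(params):
        w, b = params[:-1], params[-1]
        margin = y * (X @ w + b)
        gap = 1.0 - margin
        active = gap > 0
        loss = np.mean(np.where(active, gap, 0.0)) + 0.5 * lam * w @ w
        coef = np.where(active, -y, 0.0) / y.size
        return loss, np.concatenate([X.T @ coef + lam * w, [coef.sum()]])

    # The hinge is non-smooth at the margin, so the gradient-norm stopping
    # test is advisory rather than enforced.
    w, b = _minimize(objective, X.shape[1], require_convergence=False)
    return LinearModel(w, b, "hinge", lam, pair, feature_subset)


def fit_ternary(fitter, X, labels, seed: int = 0, **fit_kwargs) -> OvoEnsemble:
    """One-vs-one ensemble: one balanced pairwise binary fit per class pair."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) != 3:
        raise DataError(f"ternary fit requires 3 classes, got {len(classes)}")
    members = []
    for a_i in range(3):
        for b_i in range(a_i + 1, 3):
            neg, pos = classes[a_i], classes[b_i]
            mask = np.isin(labels, (neg, pos))
            idx = np.nonzero(mask)[0]
            sub = idx[balance_classes(labels[idx], seed=seed)]
            members.append(fitter(X[sub], labels[sub], positive_class=pos,
                                  **fit_kwargs))
    return OvoEnsemble(tuple(classes), members)


def predict(model: LinearModel | OvoEnsemble, X) -> np.ndarray:
    """Labels for each feature row; a score of exactly 0 is positive."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.feature_subset):
        raise ContractError(
            f"feature count {X.shape[1]} != model subset "
            f"{len(model.feature_subset)}")
    if isinstance(model, LinearModel):
        scores = model.score(X)
        return np.where(scores >= 0, model.label_pair[1], model.label_pair[0])

    votes = np.zeros((X.shape[0], 3))
    margins = np.zeros((X.shape[0], 3))
    index = {c: i for i, c in enumerate(model.classes)}
    for member in model.members:
        s = member.score(X)
        winner = np.where(s >= 0, index[member.label_pair[1]],
                          index[member.label_pair[0]])
        rows = np.arange(X.shape[0])
        votes[rows, winner] += 1
        margins[rows, winner] += np.abs(s)
    # majority vote; ties resolved toward the largest summed |margin|.
    order = votes + margins / (1.0 + margins.max(initial=0.0, axis=None))
    return np.array([model.classes[i] for i in np.argmax(order, axis=1)])


def rank_features(X, labels, feature_names: tuple[str, ...] = FEATURE_NAMES,
                  ) -> np.ndarray:
    """Feature indices ordered by descending |weight| of a full logistic fit.

    For a ternary label set the three pairwise logistic fits are averaged.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size == 2:
        w = np.abs(fit_logistic(X, labels, feature_subset=feature_names).weights)
    else:
        ens = fit_ternary(fit_logistic, X, labels, feature_subset=feature_names)
        w = np.mean([np.abs(m.weights) for m in ens.members], axis=0)
    return np.argsort(-w, kind="stable")


def reduce_features(X, labels, k: int, fitter,
                    feature_names: tuple[str, ...] = FEATURE_NAMES,
                    **fit_kwargs):
    """Retrain on the top-k features ranked by full-model |weight|.

    Returns the reduced model (binary or one-vs-one ensemble); the model's
    ``feature_subset`` records the retained names in schema order.
    """
    if not 1 <= k <= len(feature_names):
        raise ConfigurationError(
            f"k must lie in [1, {len(feature_names)}], got {k}")
    X = np.asarray(X, dtype=float)
    top = np.sort(rank_features(X, labels, feature_names)[:k])
    subset = tuple(feature_names[i] for i in top)
    labels = np.asarray(labels)
    if np.unique(labels).size == 2:
        return fitter(X[:, top], labels, feature_subset=subset, **fit_kwargs)
    return fit_ternary(fitter, X[:, top], labels, feature_subset=subset,
                       **fit_kwargs)
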