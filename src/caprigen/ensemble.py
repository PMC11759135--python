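"""Machine-learning genomic predictors: kernel ridge regression and the
Adaboost.RT boosting committee.

Both predictors consume rows of the genomic relationship matrix as
features: the feature vector of an individual is its vector of genomic
relationships to the training animals. This keeps the input dimension at
the number of training individuals rather than the marker count, and makes
KRR with a linear *precomputed* kernel exactly equivalent to GBLUP on the
training set (K = G_train, ridge = residual/genetic variance ratio).

Adaboost.RT thresholds the absolute relative error (ARE) of each weak
learner at phi: samples with ARE above phi count as mis-predicted, the
round's error rate is the mis-predicted probability mass
eps_t = sum_{ARE > phi} D_t(i), weights of correctly predicted samples are
multiplied by eps_t before renormalization, and the committee combines the
weak learners with weights log(1/eps_t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg
from sklearn.metrics.pairwise import pairwise_kernels
from sklearn.tree import DecisionTreeRegressor

from .datatypes import RelationshipMatrix

EPS_CLAMP = (1e-10, 1.0 - 1e-10)


# ---------------------------------------------------------------------------
# kernel ridge regression

@dataclass
class KernelSpec:
    """Kernel family + hyperparameters: 'linear', 'rbf' (gamma),
    'polynomial' (degree), or 'precomputed' (features are the Gram matrix)."""

    name: str = "linear"
    gamma: float | None = None
    degree: int = 3

    def gram(self, x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        if self.name == "precomputed":
            return x if y is None else x
        params: dict = {}
        if self.name == "rbf":
            params["gamma"] = self.gamma
        elif self.name == "polynomial":
            params["degree"] = self.degree
            params["gamma"] = self.gamma
        elif self.name != "linear":
            raise ValueError(f"unknown kernel {self.name!r}")
        return pairwise_kernels(x, y, metric=self.name, **params)

    def label(self) -> str:
        if self.name == "rbf":
            return f"rbf(gamma={self.gamma})"
        if self.name == "polynomial":
            return f"polynomial(degree={self.degree})"
        return self.name


@dataclass
class KRRModel:
    kernel_spec: KernelSpec
    alpha: float
    dual_coefficients: np.ndarray
    training_features: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.kernel_spec.name == "precomputed":
            k = np.asarray(x, dtype=float)
        else:
            k = self.kernel_spec.gram(np.asarray(x, dtype=float),
                                      self.training_features)
        return k @ self.dual_coefficients


def krr_fit(
    features: np.ndarray,
    y: np.ndarray,
    kernel_spec: KernelSpec | str = "linear",
    alpha: float = 1.0,
) -> KRRModel:
    """Solve (K + alpha I) c = y on the training Gram matrix.

    Predictions are f(x) = k(x, X_train) @ c. With ``kernel_spec``
    'precomputed', ``features`` must be the training Gram matrix itself and
    prediction inputs the query-vs-training kernel rows.
    """
    if isinstance(kernel_spec, str):
        kernel_spec = KernelSpec(kernel_spec)
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("need at least 2 training individuals")
    K = kernel_spec.gram(features)
    A = K + alpha * np.eye(K.shape[0])
    try:
        c = linalg.solve(A, y, assume_a="sym")
    except linalg.LinAlgError as e:
        raise linalg.LinAlgError(f"K + alpha*I is singular: {e}")
    return KRRModel(kernel_spec, float(alpha), c, features)


def default_kernel_grid(n_features: int) -> list[KernelSpec]:
    """Grid searched per training split: linear, three RBF bandwidths around
    the 1/d heuristic, and a quadratic polynomial kernel."""
    g0 = 1.0 / max(n_features, 1)
    return [
        KernelSpec("linear"),
        KernelSpec("rbf", gamma=g0 / 10),
        KernelSpec("rbf", gamma=g0),
        KernelSpec("rbf", gamma=g0 * 10),
        KernelSpec("polynomial", gamma=g0, degree=2),
    ]


def kernel_grid_search(
    features: np.ndarray,
    y: np.ndarray,
    candidate_grid: Sequence[KernelSpec] | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    alpha: float = 1.0,
) -> KernelSpec:
    """Pick the kernel maximizing mean inner-CV prediction correlation.

    Ties (including degenerate all-constant targets, where every candidate
    scores the sentinel -inf) resolve to the earliest grid entry.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    n = features.shape[0]
    if candidate_grid is None:
        candidate_grid = default_kernel_grid(features.shape[1])
    if len(candidate_grid) == 0:
        raise ValueError("empty kernel grid")
    if len(candidate_grid) == 1:
        return candidate_grid[0]
    if n < 2 * inner_folds:
        raise ValueError(f"n={n} too small for {inner_folds}-fold inner CV")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, inner_folds)
    best_spec, best_score = candidate_grid[0], -np.inf
    for spec in candidate_grid:
        scores = []
        for hold in folds:
            train = np.setdiff1d(perm, hold, assume_unique=True)
            model = krr_fit(features[train], y[train], spec, alpha=alpha)
            pred = model.predict(features[hold])
            if np.std(pred) == 0.0 or np.std(y[hold]) == 0.0:
                continue
            scores.append(np.corrcoef(pred, y[hold])[0, 1])
        score = np.mean(scores) if scores else -np.inf
        if score > best_score:
            best_spec, best_score = spec, score
    return best_spec


# ---------------------------------------------------------------------------
# Adaboost.RT

WeakLearnerFactory = Callable[[np.ndarray, np.ndarray, np.random.Generator], object]


def _tree_factory(max_depth: int = 3) -> WeakLearnerFactory:
    def fit(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
            sample_weight: np.ndarray | None = None):
        tree = DecisionTreeRegressor(
            max_depth=max_depth, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(x, y, sample_weight=sample_weight)
        return tree

    return fit


@dataclass
class BoostEnsemble:
    learners: list = field(default_factory=list)
    error_rates: list[float] = field(default_factory=list)
    phi: float = 0.1
    are_guard: float = 1e-8

    @property
    def weights(self) -> np.ndarray:
        return np.log(1.0 / np.asarray(self.error_rates))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return adaboost_rt_predict(self, x)


def _are(pred: np.ndarray, y: np.ndarray, guard: float) -> np.ndarray:
    return np.abs(pred - y) / np.maximum(np.abs(y), guard)


def adaboost_rt_fit(
    features: np.ndarray,
    y: np.ndarray,
    n_estimators: int = 100,
    phi: float = 0.1,
    seed: int = 0,
    base_learner: WeakLearnerFactory | None = None,
) -> BoostEnsemble:
    """Train the Adaboost.RT committee.

    Round t: fit a weak learner on a D_t-weighted bootstrap resample,
    compute per-sample absolute relative errors ARE_ti, take
    eps_t = sum of D_t over samples with ARE_ti > phi (clamped away from 0
    and 1), multiply the weight of each correctly predicted sample by eps_t,
    renormalize to get D_{t+1}, and store the committee weight log(1/eps_t).

    The ARE denominator is floored at max(|y_i|, 0.1*SD(y)) because the
    regression targets here are fixed-effect-adjusted (near-centered)
    phenotypes, for which a raw relative error blows up around zero.
    ``base_learner`` may be any (x, y, rng) -> fitted-regressor callable;
    the default is a depth-3 regression tree.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    n = features.shape[0]
    if phi <= 0.0:
        raise ValueError("phi must be positive")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 distinct target values")
    if base_learner is None:
        if n < 10:
            raise ValueError("need at least 10 training samples")
        base_learner = _tree_factory()

    rng = np.random.default_rng(seed)
    guard = max(0.1 * float(np.std(y)), 1e-12)
    D = np.full(n, 1.0 / n)
    ens = BoostEnsemble(phi=phi, are_guard=guard)
    accepts_weights = base_learner.__code__.co_argcount >= 4 if hasattr(
        base_learner, "__code__") else False
    for _ in range(n_estimators):
        idx = rng.choice(n, size=n, replace=True, p=D)
        if accepts_weights:
            # repeated bootstrap rows collapsed into integer sample weights:
            # identical fit, much cheaper
            uniq, counts = np.unique(idx, return_counts=True)
            learner = base_learner(features[uniq], y[uniq], rng,
                                   counts.astype(float))
        else:
            learner = base_learner(features[idx], y[idx], rng)
        pred = np.asarray(learner.predict(features), dtype=float)
        are = _are(pred, y, guard)
        miss = are > phi
        eps = float(np.clip(D[miss].sum(), *EPS_CLAMP))
        D = D * np.where(miss, 1.0, eps)
        D = D / D.sum()
        ens.learners.append(learner)
        ens.error_rates.append(eps)
    ens.distribution_ = D  # final weights, exposed for diagnostics/tests
    return ens


def adaboost_rt_predict(ens: BoostEnsemble, x: np.ndarray) -> np.ndarray:
    """Committee output: sum_t log(1/eps_t) f_t(x) / sum_t log(1/eps_t)."""
    if not ens.learners:
        raise ValueError("empty ensemble")
    x = np.asarray(x, dtype=float)
    w = ens.weights
    preds = np.stack([np.asarray(l.predict(x), dtype=float) for l in ens.learners])
    return (w @ preds) / w.sum()


def committee_training_error(ens: BoostEnsemble, features: np.ndarray,
                             y: np.ndarray) -> float:
    """Fraction of training samples whose committee ARE exceeds phi."""
    are = _are(adaboost_rt_predict(ens, features), np.asarray(y, float),
               ens.are_guard)
    return float(np.mean(are > ens.phi))


# ---------------------------------------------------------------------------
# feature extraction

def relationship_features(
    G: RelationshipMatrix, train_ids: Sequence[str], query_ids: Sequence[str]
) -> np.ndarray:
    """G-rows of the query animals restricted to the training columns.

    Column order is fixed by ``train_ids``; a query animal that is itself in
    training sees its own diagonal entry at its own column.
    """
    return G.submatrix(query_ids, train_ids)


# ---------------------------------------------------------------------------
# model serialization (JSON container)

class _TreePredictor:
    """Minimal regression-tree evaluator reconstructed from node arrays."""

    def __init__(self, children_left, children_right, feature, threshold, value):
        self.children_left = np.asarray(children_left, dtype=int)
        self.children_right = np.asarray(children_right, dtype=int)
        self.feature = np.asarray(feature, dtype=int)
        self.threshold = np.asarray(threshold, dtype=float)
        self.value = np.asarray(value, dtype=float)

    def predict(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty(x.shape[0])
        for i, row in enumerate(x):
            node = 0
            while self.children_left[node] != -1:
                if row[self.feature[node]] <= self.threshold[node]:
                    node = self.children_left[node]
                else:
                    node = self.children_right[node]
            out[i] = self.value[node]
        return out


def _dump_tree(tree) -> dict:
    t = tree.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value.reshape(-1).tolist(),
    }


def save_model(model, path) -> None:
    """Serialize a fitted KRRModel or BoostEnsemble to a JSON container."""
    import json

    if isinstance(model, KRRModel):
        payload = {
            "type": "krr",
            "kernel": {"name": model.kernel_spec.name,
                       "gamma": model.kernel_spec.gamma,
                       "degree": model.kernel_spec.degree},
            "alpha": model.alpha,
            "dual_coefficients": model.dual_coefficients.tolist(),
            "training_features": model.training_features.tolist(),
        }
    elif isinstance(model, BoostEnsemble):
        trees = []
        for learner in model.learners:
            if isinstance(learner, _TreePredictor):
                trees.append({
                    "children_left": learner.children_left.tolist(),
                    "children_right": learner.children_right.tolist(),
                    "feature": learner.feature.tolist(),
                    "threshold": learner.threshold.tolist(),
                    "value": learner.value.tolist(),
                })
            elif isinstance(learner, DecisionTreeRegressor):
                trees.append(_dump_tree(learner))
            else:
                raise TypeError(
                    f"cannot serialize weak learner of type {type(learner).__name__}"
                )
        payload = {
            "type": "adaboost_rt",
            "phi": model.phi,
            "are_guard": model.are_guard,
            "error_rates": list(model.error_rates),
            "trees": trees,
        }
    else:
        raise TypeError(f"unknown model type {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    """Load a model written by :func:`save_model`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    if payload["type"] == "krr":
        ks = payload["kernel"]
        return KRRModel(
            KernelSpec(ks["name"], gamma=ks["gamma"], degree=ks["degree"]),
            float(payload["alpha"]),
            np.asarray(payload["dual_coefficients"], dtype=float),
            np.asarray(payload["training_features"], dtype=float),
        )
    if payload["type"] == "adaboost_rt":
        ens = BoostEnsemble(phi=float(payload["phi"]),
                            are_guard=float(payload["are_guard"]),
                            error_rates=[float(e) for e in payload["error_rates"]])
        ens.learners = [_TreePredictor(**t) for t in payload["trees"]]
        return ens
    raise ValueError(f"unknown model type {payload['type']!r}")
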