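"""Problem-transformation classifiers for count-valued labelsets.

Each billing code j is a multi-class target over {0..K_j} (the code can
be charged up to K_j times per exam).  Three transformation methods are
provided over a pluggable base-classifier factory (MLP, RBF SVM, random
forest):

* binary relevance — one independent classifier per code; assumes label
  independence;
* classifier chain — classifiers arranged along a label order, each
  consuming the preceding labels (true values at training time, the
  chain's own predictions at inference);
* ensemble of classifier chains (ECC) — several chains with random
  label orders, combined per label by majority vote; ties break toward
  the smallest count (conservative: prefer undercoding a tie over
  overcoding).

sklearn's built-in chain supports binary labels only, so the chaining,
voting and count semantics live here; sklearn supplies the base
classifiers and scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .labels import CodeDefinition, Labelset

__all__ = [
    "BaseClassifierSpec",
    "BinaryRelevance",
    "ClassifierChain",
    "EnsembleOfChains",
    "labelsets_to_frame",
    "frame_to_labelsets",
    "micro_f1_counts",
    "tune",
]

FAMILIES = ("mlp", "svm_rbf", "random_forest")


@dataclass(frozen=True)
class BaseClassifierSpec:
    """Base-classifier family plus hyperparameters and seed."""

    family: str = "mlp"
    hyperparameters: Mapping = field(default_factory=dict)
    random_seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unsupported family {self.family!r}")


def _make_base(spec: BaseClassifierSpec, seed: int):
    """Instantiate one per-label classifier.

    MLP and SVM get a z-score scaler fitted inside the pipeline (so CV
    folds scale on training data only); trees are left unscaled.
    """
    hp = dict(spec.hyperparameters)
    if spec.family == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (32,)),
            max_iter=hp.pop("max_iter", 300),
            random_state=seed,
            **hp,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if spec.family == "svm_rbf":
        clf = SVC(
            kernel="rbf",
            C=hp.pop("C", 1.0),
            gamma=hp.pop("gamma", "scale"),
            random_state=seed,
            **hp,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    clf = RandomForestClassifier(
        n_estimators=hp.pop("n_estimators", 100),
        random_state=seed,
        **hp,
    )
    return clf


class _ConstantClassifier:
    """Predictor for a label with a single observed training class."""

    def __init__(self, value: int):
        self.value = int(value)

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.value, dtype=int)


def labelsets_to_frame(
    labelsets: Sequence[Labelset], codes: Sequence[str]
) -> pd.DataFrame:
    """Labelsets -> integer count matrix with one column per code."""
    data = {c: [ls.get(c, 0) for ls in labelsets] for c in codes}
    return pd.DataFrame(data, columns=list(codes))


def frame_to_labelsets(Y: np.ndarray | pd.DataFrame, codes: Sequence[str]) -> list:
    arr = np.asarray(Y)
    return [Labelset({c: int(v) for c, v in zip(codes, row)}) for row in arr]


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _clip_counts(values: np.ndarray, code: str, code_defs) -> np.ndarray:
    cap = code_defs[code].max_count if code in code_defs else None
    out = np.clip(values, 0, cap if cap is not None else None)
    return out.astype(int)


class _MultiOutputBase:
    """Shared plumbing: code list, K_j lookup, labelset conversion."""

    def __init__(self, code_defs: Mapping[str, CodeDefinition],
                 spec: BaseClassifierSpec | None = None):
        self.code_defs = dict(code_defs)
        self.spec = spec or BaseClassifierSpec()
        self.codes_: list[str] | None = None
        self.n_features_: int | None = None

    def _start_fit(self, X, Y):
        X = _as_array(X)
        if isinstance(Y, pd.DataFrame):
            self.codes_ = list(Y.columns)
            Y = Y.to_numpy()
        else:
            raise TypeError("Y must be a DataFrame with one column per code")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        self.n_features_ = X.shape[1]
        return X, Y.astype(int)

    def _check_predict(self, X) -> np.ndarray:
        if self.codes_ is None:
            raise RuntimeError("model is not fitted")
        X = _as_array(X)
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"feature length mismatch: got {X.shape[1]}, "
                f"expected {self.n_features_}"
            )
        return X

    def predict_labelsets(self, X) -> list:
        return frame_to_labelsets(self.predict(X), self.codes_)


class BinaryRelevance(_MultiOutputBase):
    """One independent multi-class classifier per billing code."""

    def fit(self, X, Y):
        X, Y = self._start_fit(X, Y)
        self.estimators_ = []
        for j, code in enumerate(self.codes_):
            y = Y[:, j]
            if len(np.unique(y)) < 2:
                est = _ConstantClassifier(y[0])
            else:
                est = _make_base(self.spec, seed=self.spec.random_seed + j)
                est.fit(X, y)
            self.estimators_.append(est)
        return self

    def predict(self, X) -> np.ndarray:
        X = self._check_predict(X)
        cols = []
        for code, est in zip(self.codes_, self.estimators_):
            cols.append(_clip_counts(est.predict(X), code, self.code_defs))
        return np.column_stack(cols)


class ClassifierChain(_MultiOutputBase):
    """Classifiers along a label order, each fed the preceding labels.

    Training augments the feature matrix with the *true* values of the
    preceding labels; prediction feeds the chain's own (hard) label
    predictions forward, sequentially.
    """

    def __init__(self, code_defs, spec=None, label_order: Sequence[str] | None = None):
        super().__init__(code_defs, spec)
        self.label_order = list(label_order) if label_order is not None else None

    def fit(self, X, Y):
        X, Yarr = self._start_fit(X, Y)
        order = self.label_order or list(self.codes_)
        if sorted(order) != sorted(self.codes_):
            raise ValueError("label_order must be a permutation of the code list")
        self.order_ = list(order)
        col_of = {c: i for i, c in enumerate(self.codes_)}
        self.estimators_ = []
        augmented = X
        for pos, code in enumerate(self.order_):
            y = Yarr[:, col_of[code]]
            if len(np.unique(y)) < 2:
                est = _ConstantClassifier(y[0])
            else:
                est = _make_base(self.spec, seed=self.spec.random_seed + pos)
                est.fit(augmented, y)
            self.estimators_.append(est)
            augmented = np.column_stack([augmented, y])
        return self

    def predict(self, X) -> np.ndarray:
        X = self._check_predict(X)
        preds: dict[str, np.ndarray] = {}
        augmented = X
        for code, est in zip(self.order_, self.estimators_):
            yhat = _clip_counts(est.predict(augmented), code, self.code_defs)
            preds[code] = yhat
            augmented = np.column_stack([augmented, yhat])
        return np.column_stack([preds[c] for c in self.codes_])


class EnsembleOfChains(_MultiOutputBase):
    """Ensemble of classifier chains with random label orders.

    Per-label predictions are combined by majority vote over the chains;
    vote ties resolve to the smallest tied count value.  Duplicate
    orders across chains are permitted.
    """

    def __init__(self, code_defs, spec=None, n_chains: int = 10, seed: int = 0):
        super().__init__(code_defs, spec)
        if n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        self.n_chains = n_chains
        self.seed = seed

    def fit(self, X, Y):
        _, _ = self._start_fit(X, Y)
        rng = np.random.default_rng(self.seed)
        codes = list(Y.columns)
        self.chains_ = []
        for k in range(self.n_chains):
            order = list(rng.permutation(codes))
            chain = ClassifierChain(
                self.code_defs,
                replace(self.spec, random_seed=self.spec.random_seed + 1000 * k),
                label_order=order,
            )
            chain.fit(X, Y)
            self.chains_.append(chain)
        return self

    def predict(self, X) -> np.ndarray:
        X = self._check_predict(X)
        stack = np.stack([chain.predict(X) for chain in self.chains_])  # (k, n, q)
        k, n, q = stack.shape
        out = np.zeros((n, q), dtype=int)
        for j in range(q):
            votes = stack[:, :, j]
            for i in range(n):
                values, counts = np.unique(votes[:, i], return_counts=True)
                winners = values[counts == counts.max()]
                out[i, j] = winners.min()  # tie -> smallest count
        return out


# ---------------------------------------------------------------------------
# Hyperparameter tuning


def micro_f1_counts(Y_true: np.ndarray, Y_pred: np.ndarray) -> float:
    """Micro F1 under the charged-unit counting convention."""
    t = np.asarray(Y_true, dtype=int)
    p = np.asarray(Y_pred, dtype=int)
    tp = np.minimum(t, p).sum()
    fp = np.maximum(0, p - t).sum()
    fn = np.maximum(0, t - p).sum()
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


def tune(
    X,
    Y: pd.DataFrame,
    code_defs: Mapping[str, CodeDefinition],
    grid: Sequence[BaseClassifierSpec],
    method: str = "binary_relevance",
    folds: int = 10,
    seed: int = 0,
    n_chains: int = 10,
) -> tuple[BaseClassifierSpec, pd.DataFrame]:
    """Exhaustive grid search by mean micro F1 over k-fold CV.

    Returns the winning spec and the full CV table (one row per spec,
    per-fold scores plus the mean).  Deterministic for fixed
    (data, grid, seed).
    """
    X = _as_array(X)
    if not len(grid):
        raise ValueError("empty spec grid")
    if X.shape[0] < folds:
        raise ValueError("fewer training rows than folds")
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    split_idx = list(splitter.split(X))
    rows = []
    for spec_i, spec in enumerate(grid):
        scores = []
        for train_idx, val_idx in split_idx:
            model = _build(method, code_defs, spec, seed=seed, n_chains=n_chains)
            model.fit(X[train_idx], Y.iloc[train_idx])
            pred = model.predict(X[val_idx])
            scores.append(micro_f1_counts(Y.iloc[val_idx].to_numpy(), pred))
        rows.append(
            {"spec_index": spec_i, "family": spec.family,
             "hyperparameters": dict(spec.hyperparameters),
             **{f"fold{k}": s for k, s in enumerate(scores)},
             "mean_micro_f1": float(np.mean(scores))}
        )
    table = pd.DataFrame(rows)
    best = table["mean_micro_f1"].idxmax()
    return grid[int(table.loc[best, "spec_index"])], table


def _build(method, code_defs, spec, seed=0, n_chains=10):
    if method == "binary_relevance":
        return BinaryRelevance(code_defs, spec)
    if method == "chain":
        return ClassifierChain(code_defs, spec)
    if method == "ecc":
        return EnsembleOfChains(code_defs, spec, n_chains=n_chains, seed=seed)
    raise ValueError(f"unknown method {method!r}")
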