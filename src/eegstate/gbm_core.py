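"""Multiclass gradient boosting machine, implemented from first principles.

The model is a staged additive ensemble.  Raw per-class scores start at
the log class proportions; at every stage, for every class, a small
regression tree is fitted by least squares to that class's component of
the negative gradient of the multinomial deviance,

    L(Y, F) = - sum_i sum_k Y_ik log softmax(F_i)_k ,
    -dL/dF_ik = Y_ik - softmax(F_i)_k ,

and its leaf values are replaced by one-step Newton estimates of the
optimal per-leaf step (Friedman's K-class formula), scaled by the
learning rate.  Trees are exact greedy CART: every split is the best
squared-error-reducing threshold among midpoints of consecutive sorted
unique feature values.  There is no row or feature subsampling, so
fitting is fully deterministic given the input order.

Class codes follow the EEG labelling convention (-1 healthy, 0
interictal, 1 ictal) but any label set works.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class GBMConfig:
    """Boosting hyperparameters.

    ``n_stages`` (M) and ``learning_rate`` (nu) are the two the grid
    search tunes; tree shape parameters are fixed defaults.  ``seed`` is
    carried for interface symmetry — with no subsampling the fit is
    deterministic and the seed changes nothing.
    """

    n_stages: int = 100
    learning_rate: float = 0.1
    max_depth: int = 3
    min_samples_leaf: int = 1
    loss: str = "multinomial_deviance"
    seed: int = 0

    def validate(self) -> None:
        if self.n_stages < 0:
            raise ValueError(f"n_stages must be >= 0, got {self.n_stages}")
        if not 0 < self.learning_rate <= 1:
            raise ValueError(
                f"learning_rate must lie in (0, 1], got {self.learning_rate}")
        if self.max_depth < 1:
            raise ValueError(f"max_depth must be >= 1, got {self.max_depth}")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.loss != "multinomial_deviance":
            raise ValueError(f"unsupported loss {self.loss!r}")


def one_hot(labels: Sequence[int], classes: Sequence[int]) -> np.ndarray:
    """Indicator matrix with one column per class, rows summing to 1."""
    classes = list(classes)
    index = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        if l not in index:
            raise ValueError(f"label {l!r} not among classes {classes}")
        Y[i, index[l]] = 1.0
    return Y


def loss_and_negative_gradient(Y: np.ndarray, F: np.ndarray
                               ) -> tuple[float, np.ndarray]:
    """Multinomial deviance and its negative gradient Y - softmax(F)."""
    Y = np.asarray(Y, dtype=float)
    F = np.asarray(F, dtype=float)
    if Y.shape != F.shape:
        raise ValueError(f"shape mismatch: Y {Y.shape} vs F {F.shape}")
    if not np.isfinite(F).all():
        raise ValueError("non-finite scores")
    Fs = F - F.max(axis=1, keepdims=True)  # stabilized softmax
    logZ = np.log(np.exp(Fs).sum(axis=1, keepdims=True))
    log_p = Fs - logZ
    loss = float(-(Y * log_p).sum())
    residuals = Y - np.exp(log_p)
    return loss, residuals


# ---------------------------------------------------------------------------
# Regression trees (exact greedy CART on squared error)

@dataclass
class _Node:
    feature: int = -1          # -1 marks a leaf
    threshold: float = 0.0
    left: int = -1
    right: int = -1
    value: float = 0.0
    #: training-sample indices reaching the node, kept only on leaves
    indices: np.ndarray | None = None


@dataclass
class RegressionTree:
    """Axis-aligned binary regression tree stored as a flat node list."""

    nodes: list[_Node] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            out[i] = self._leaf_for(row).value
        return out

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node index for each row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0], dtype=int)
        for i, row in enumerate(X):
            out[i] = self._leaf_index_for(row)
        return out

    def _leaf_index_for(self, row: np.ndarray) -> int:
        j = 0
        node = self.nodes[0]
        while node.feature >= 0:
            j = node.left if row[node.feature] <= node.threshold else node.right
            node = self.nodes[j]
        return j

    def _leaf_for(self, row: np.ndarray) -> _Node:
        return self.nodes[self._leaf_index_for(row)]

    @property
    def leaf_indices(self) -> list[int]:
        return [j for j, n in enumerate(self.nodes) if n.feature < 0]

    def to_dict(self) -> dict:
        return {"nodes": [
            {"feature": n.feature, "threshold": n.threshold, "left": n.left,
             "right": n.right, "value": n.value} for n in self.nodes]}

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(nodes=[_Node(**nd) for nd in d["nodes"]])


def _best_split(X: np.ndarray, r: np.ndarray, min_leaf: int
                ) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gain) by exhaustive scan, or None.

    Gain is the squared-error reduction.  Candidate thresholds are the
    midpoints of consecutive distinct sorted values of each feature.  Ties
    in gain resolve to the lowest feature index, then lowest threshold
    (scan order), making fits order-independent.
    """
    n = len(r)
    total_sum = r.sum()
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        rs = r[order]
        csum = np.cumsum(rs)
        # split after position i (1-based count i+1 on the left)
        left_n = np.arange(1, n)
        valid = xs[:-1] != xs[1:]
        valid &= (left_n >= min_leaf) & (n - left_n >= min_leaf)
        if not valid.any():
            continue
        left_sum = csum[:-1]
        gain = left_sum ** 2 / left_n + (total_sum - left_sum) ** 2 / (n - left_n)
        gain = gain - total_sum ** 2 / n
        gain = np.where(valid, gain, -np.inf)
        i = int(np.argmax(gain))
        if gain[i] <= 1e-12:
            continue
        # first threshold within floating noise of the max (lowest wins ties)
        i = int(np.argmax(gain >= gain[i] - 1e-9 * (1.0 + abs(gain[i]))))
        thr = 0.5 * (xs[i] + xs[i + 1])
        # gains equal up to floating noise count as ties -> earlier feature wins
        tol = 1e-9 * (1.0 + abs(gain[i]))
        if best is None or gain[i] > best[2] + tol:
            best = (j, float(thr), float(gain[i]))
    return best


def fit_tree(X: np.ndarray, r: np.ndarray, cfg: GBMConfig) -> RegressionTree:
    """Greedy CART regression tree on residuals ``r``.

    Recursion stops at ``max_depth``, ``min_samples_leaf``, or when no
    split reduces the squared error (e.g. constant residuals).  Leaf
    values are residual means; boosting later overwrites them with Newton
    steps.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = np.asarray(r, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != len(r):
        raise ValueError(f"X has {X.shape[0]} rows but r has {len(r)}")
    tree = RegressionTree()

    def grow(idx: np.ndarray, depth: int) -> int:
        node = _Node(value=float(r[idx].mean()))
        pos = len(tree.nodes)
        tree.nodes.append(node)
        if depth < cfg.max_depth and len(idx) >= 2 * cfg.min_samples_leaf:
            split = _best_split(X[idx], r[idx], cfg.min_samples_leaf)
            if split is not None:
                j, thr, _ = split
                mask = X[idx, j] <= thr
                node.feature = j
                node.threshold = thr
                node.left = grow(idx[mask], depth + 1)
                node.right = grow(idx[~mask], depth + 1)
                return pos
        node.indices = idx
        return pos

    grow(np.arange(X.shape[0]), 0)
    return tree


# ---------------------------------------------------------------------------
# Boosting

@dataclass
class GBMModel:
    """Fitted staged ensemble: priors + per-stage, per-class trees."""

    classes: list[int]
    priors: np.ndarray
    stages: list[list[RegressionTree]]
    config: GBMConfig
    train_loss_path: list[float] = field(default_factory=list)
    n_features: int = 0

    def decision_function(self, X: np.ndarray, n_stages: int | None = None
                          ) -> np.ndarray:
        """Raw additive scores after the first ``n_stages`` stages (all by
        default)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}")
        use = len(self.stages) if n_stages is None else min(n_stages,
                                                            len(self.stages))
        F = np.tile(self.priors, (X.shape[0], 1))
        for stage in self.stages[:use]:
            for k, tree in enumerate(stage):
                F[:, k] += tree.predict(X)
        return F

    def staged_decision(self, X: np.ndarray):
        """Yield raw scores after 0, 1, ..., M stages (for staged evaluation)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        F = np.tile(self.priors, (X.shape[0], 1))
        yield F.copy()
        for stage in self.stages:
            for k, tree in enumerate(stage):
                F[:, k] += tree.predict(X)
            yield F.copy()

    def to_json(self) -> str:
        return json.dumps({
            "format": "eegstate-gbm", "version": 1,
            "classes": self.classes,
            "priors": self.priors.tolist(),
            "config": self.config.__dict__,
            "train_loss_path": self.train_loss_path,
            "n_features": self.n_features,
            "stages": [[t.to_dict() for t in stage] for stage in self.stages],
        })

    @classmethod
    def from_json(cls, text: str) -> "GBMModel":
        d = json.loads(text)
        if d.get("format") != "eegstate-gbm":
            raise ValueError("not an eegstate GBM model file")
        return cls(classes=list(d["classes"]),
                   priors=np.asarray(d["priors"], dtype=float),
                   stages=[[RegressionTree.from_dict(td) for td in stage]
                           for stage in d["stages"]],
                   config=GBMConfig(**d["config"]),
                   train_loss_path=list(d["train_loss_path"]),
                   n_features=int(d["n_features"]))


def _softmax(F: np.ndarray) -> np.ndarray:
    Fs = F - F.max(axis=1, keepdims=True)
    e = np.exp(Fs)
    return e / e.sum(axis=1, keepdims=True)


def fit(X: np.ndarray, labels: Sequence[int], cfg: GBMConfig | None = None,
        classes: Sequence[int] | None = None) -> GBMModel:
    """Fit the boosted ensemble.

    Scores initialise to log class proportions.  Each stage fits one tree
    per class to the negative-gradient column, then replaces each leaf
    value with the one-step Newton estimate

        gamma = (K-1)/K * sum(r_i) / sum(|r_i| (1 - |r_i|))

    over the leaf's samples and adds ``learning_rate * gamma`` to that
    class's score for samples in the leaf.  The recorded training-loss
    path is nonincreasing.
    """
    cfg = cfg or GBMConfig()
    cfg.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels)
    if X.shape[0] != len(y):
        raise ValueError("X and labels disagree in length")
    if classes is None:
        classes = sorted(np.unique(y).tolist())
    classes = list(classes)
    K = len(classes)
    Y = one_hot(y, classes)
    props = Y.mean(axis=0)
    # log-proportion priors; absent classes pinned to a large negative score
    with np.errstate(divide="ignore"):
        priors = np.where(props > 0, np.log(np.clip(props, 1e-300, None)), -30.0)
    model = GBMModel(classes=classes, priors=priors, stages=[], config=cfg,
                     n_features=X.shape[1])
    F = np.tile(priors, (X.shape[0], 1))
    loss, _ = loss_and_negative_gradient(Y, F)
    model.train_loss_path.append(loss)
    if K < 2:
        # single-class data: the prior already predicts it with certainty
        return model
    nu = cfg.learning_rate
    for _ in range(cfg.n_stages):
        _, R = loss_and_negative_gradient(Y, F)
        stage: list[RegressionTree] = []
        for k in range(K):
            r = R[:, k]
            tree = fit_tree(X, r, cfg)
            for j in tree.leaf_indices:
                node = tree.nodes[j]
                idx = node.indices
                rr = r[idx]
                denom = np.sum(np.abs(rr) * (1.0 - np.abs(rr)))
                if denom < 1e-150:
                    gamma = 0.0
                else:
                    gamma = (K - 1) / K * rr.sum() / denom
                # clip extreme Newton steps for numerical safety
                node.value = float(np.clip(gamma, -10.0, 10.0))
                F[idx, k] += nu * node.value
                node.value *= nu
                node.indices = None
            stage.append(tree)
        model.stages.append(stage)
        loss, _ = loss_and_negative_gradient(Y, F)
        model.train_loss_path.append(loss)
    return model


def predict_proba(model: GBMModel, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities; rows sum to 1."""
    return _softmax(model.decision_function(X))


def predict(model: GBMModel, X: np.ndarray) -> np.ndarray:
    """Class codes by highest probability; ties go to the smaller code."""
    P = predict_proba(model, X)
    cls = np.asarray(model.classes)
    order = np.argsort(cls)  # scan classes ascending so ties pick the smaller
    best = order[np.argmax(P[:, order], axis=1)]
    return cls[best]
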