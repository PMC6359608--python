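"""Coarse-to-fine grid search over boosting hyperparameters, scored by
10-fold cross-validated misclassification error.

The search runs in two passes: a wide coarse grid over stage count and
learning rate, then a refined grid centred on the coarse winner (stage
step 10, learning-rate step 0.01, bounded by the winner's coarse
neighbours).  The selection score is the CV error CVe = mean over folds
of the fold misclassification rate; ties resolve to the least complex
configuration (smallest stage count, then smallest learning rate).

Fold assembly is seeded and, by default, stratified so every fold keeps
the class ratios within one sample.  Any per-fold preprocessing (PCA,
scaling) is fitted on the training portion only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .features import pca_fit, pca_transform
from .gbm_core import GBMConfig, fit as gbm_fit, predict as gbm_predict, _softmax

logger = logging.getLogger(__name__)


@dataclass
class CVPlan:
    """A k-fold partition: disjoint index sets covering 0..n-1."""

    folds: list[np.ndarray]
    k: int
    seed: int

    def validate(self, n: int) -> None:
        all_idx = np.concatenate(self.folds) if self.folds else np.array([], int)
        if len(self.folds) != self.k:
            raise ValueError(f"expected {self.k} folds, got {len(self.folds)}")
        if len(all_idx) != n or len(np.unique(all_idx)) != n:
            raise ValueError("folds must partition the index range exactly")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes must differ by at most 1, got {sizes}")


def make_folds(n: int, k: int = 10, seed: int = 0,
               labels: Sequence[int] | None = None) -> CVPlan:
    """Seeded k-fold partition, stratified by class when labels are given.

    Without labels: shuffle 0..n-1 and slice into k nearly equal chunks.
    With labels: shuffle within each class and deal members round-robin
    to folds, preserving class ratios within one sample per fold.
    """
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    if labels is None:
        perm = rng.permutation(n)
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        folds = []
        pos = 0
        for s in sizes:
            folds.append(np.sort(perm[pos:pos + s]))
            pos += s
    else:
        y = np.asarray(labels)
        if len(y) != n:
            raise ValueError("labels length must equal n")
        assignment = np.empty(n, dtype=int)
        offset = 0
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            idx = rng.permutation(idx)
            # round-robin with a rotating start so small classes don't all
            # overload fold 0
            assignment[idx] = (np.arange(len(idx)) + offset) % k
            offset += len(idx)
        folds = [np.flatnonzero(assignment == q) for q in range(k)]
        if min(len(f) for f in folds) == 0:
            raise ValueError("stratified folds left a fold empty; reduce k")
    plan = CVPlan(folds=folds, k=k, seed=seed)
    plan.validate(n)
    return plan


def _pca_fitter(variance_keep: float | None):
    if variance_keep is None:
        return lambda Xtr: (Xtr, lambda Xte: Xte)

    def fit_fold(Xtr):
        model = pca_fit(Xtr, variance_keep=variance_keep)
        return pca_transform(model, Xtr), lambda Xte: pca_transform(model, Xte)

    return fit_fold


def cv_error(X: np.ndarray, y: Sequence[int], cfg: GBMConfig, plan: CVPlan,
             variance_keep: float | None = None,
             fit_predict: Callable | None = None) -> tuple[float, float]:
    """(CVe, accuracy): mean fold misclassification rate and its complement.

    For every fold the model trains on the complement and is scored on
    the fold; PCA (when enabled) is refitted inside each training fold.
    ``fit_predict(Xtr, ytr, Xte) -> predictions`` swaps in an alternative
    classifier back-end; the default is the package's boosting machine.
    A fold whose training complement holds a single class is skipped with
    a warning and the average renormalised over the remaining folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    plan.validate(len(y))
    prep = _pca_fitter(variance_keep)
    errors = []
    for q, fold in enumerate(plan.folds):
        mask = np.ones(len(y), dtype=bool)
        mask[fold] = False
        ytr = y[mask]
        if len(np.unique(ytr)) < 2:
            logger.warning("fold %d: training split has a single class; skipped", q)
            continue
        Xtr, transform = prep(X[mask])
        Xte = transform(X[fold])
        if fit_predict is not None:
            pred = np.asarray(fit_predict(Xtr, ytr, Xte))
        else:
            model = gbm_fit(Xtr, ytr, cfg)
            pred = gbm_predict(model, Xte)
        errors.append(float(np.mean(pred != y[fold])))
    if not errors:
        raise ValueError("no usable folds")
    cve = float(np.mean(errors))
    return cve, 1.0 - cve


def cv_predictions(X: np.ndarray, y: Sequence[int], cfg: GBMConfig,
                   plan: CVPlan, variance_keep: float | None = None,
                   classes: Sequence[int] = (-1, 0, 1)
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold predictions and class probabilities.

    Every sample is scored by the model trained on its fold's complement,
    giving one honest prediction (and probability row, columns ordered as
    ``classes``) per sample for downstream ROC/PRC analysis.
    """
    from .gbm_core import predict_proba as gbm_predict_proba
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    plan.validate(len(y))
    classes = list(classes)
    prep = _pca_fitter(variance_keep)
    y_pred = np.empty(len(y), dtype=int)
    proba = np.full((len(y), len(classes)), np.nan)
    for fold in plan.folds:
        mask = np.ones(len(y), dtype=bool)
        mask[fold] = False
        Xtr, transform = prep(X[mask])
        model = gbm_fit(Xtr, y[mask], cfg, classes=classes)
        P = gbm_predict_proba(model, transform(X[fold]))
        proba[fold] = P
        cls = np.asarray(classes)
        order = np.argsort(cls)
        y_pred[fold] = cls[order[np.argmax(P[:, order], axis=1)]]
    return y_pred, proba


@dataclass
class GridSpec:
    """Candidate stage counts and learning rates (explicit lists)."""

    stages: list[int]
    learning_rates: list[float]

    @classmethod
    def coarse_default(cls) -> "GridSpec":
        return cls(stages=list(range(50, 501, 50)),
                   learning_rates=[0.05, 0.10, 0.15, 0.20])

    @classmethod
    def from_ranges(cls, stages, learning_rates) -> "GridSpec":
        """Each argument: an explicit list or a (min, max, step) triple."""
        def expand(spec, cast):
            spec = list(spec)
            if len(spec) == 3 and all(np.isscalar(v) for v in spec):
                lo, hi, step = spec
                vals = np.arange(lo, hi + step * 1e-9, step)
                return [cast(round(v, 10)) for v in vals]
            return [cast(v) for v in spec]
        return cls(stages=expand(stages, int),
                   learning_rates=expand(learning_rates, float))


@dataclass
class GridResult:
    """All evaluated configurations plus the winner of a search stage."""

    evaluated: list[tuple[GBMConfig, float, float]] = field(default_factory=list)
    best: GBMConfig | None = None
    stage: str = "coarse"

    def best_score(self) -> float:
        for cfg, cve, _ in self.evaluated:
            if cfg is self.best:
                return cve
        raise ValueError("no winner recorded")


def _sort_key(cfg: GBMConfig, cve: float):
    # minimise CVe; break ties toward the least complex model
    return (round(cve, 12), cfg.n_stages, cfg.learning_rate)


def _evaluate_grid(X, y, grid: GridSpec, plan: CVPlan, base: GBMConfig,
                   variance_keep: float | None,
                   evaluated: list) -> None:
    """Evaluate every grid point, sharing one fit per (fold, learning-rate).

    With deterministic fitting and no subsampling, the m-stage model is a
    prefix of the M-stage model, so all stage counts for one learning rate
    are read off the staged scores of a single max-stage fit per fold.
    """
    stage_list = sorted(set(int(s) for s in grid.stages))
    if not stage_list or not grid.learning_rates:
        raise ValueError("empty grid")
    max_stages = stage_list[-1]
    prep = _pca_fitter(variance_keep)
    for lr in grid.learning_rates:
        fold_err = {m: [] for m in stage_list}
        for q, fold in enumerate(plan.folds):
            mask = np.ones(len(y), dtype=bool)
            mask[fold] = False
            ytr = y[mask]
            if len(np.unique(ytr)) < 2:
                logger.warning("fold %d: single-class training split; skipped", q)
                continue
            Xtr, transform = prep(X[mask])
            Xte = transform(X[fold])
            cfg = replace(base, n_stages=max_stages, learning_rate=float(lr))
            model = gbm_fit(Xtr, ytr, cfg)
            cls = np.asarray(model.classes)
            order = np.argsort(cls)
            wanted = set(stage_list)
            for m, F in enumerate(model.staged_decision(Xte)):
                if m in wanted:
                    P = _softmax(F)
                    pred = cls[order[np.argmax(P[:, order], axis=1)]]
                    fold_err[m].append(float(np.mean(pred != y[fold])))
        for m in stage_list:
            if not fold_err[m]:
                raise ValueError("no usable folds")
            cve = float(np.mean(fold_err[m]))
            cfg = replace(base, n_stages=m, learning_rate=float(lr))
            evaluated.append((cfg, cve, 1.0 - cve))


def grid_search(X: np.ndarray, y: Sequence[int], plan: CVPlan,
                coarse: GridSpec | None = None,
                base: GBMConfig | None = None,
                variance_keep: float | None = None,
                fine_lr_step: float = 0.01,
                fine_stage_step: int = 10) -> GridResult:
    """Two-pass search: coarse grid, then refinement around its winner.

    The fine grid spans the interval between the winner's coarse
    neighbours in both axes (learning-rate step ``fine_lr_step``, stage
    step ``fine_stage_step``) and is evaluated under the same folds.  The
    returned winner minimises CVe over everything evaluated; equal scores
    resolve to the smaller (stages, learning_rate) pair.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    coarse = coarse or GridSpec.coarse_default()
    base = base or GBMConfig()
    result = GridResult(stage="coarse+fine")
    _evaluate_grid(X, y, coarse, plan, base, variance_keep, result.evaluated)
    best_cfg, best_cve, _ = min(result.evaluated,
                                key=lambda t: _sort_key(t[0], t[1]))

    def neighbours(values, winner):
        vals = sorted(set(values))
        i = vals.index(winner)
        lo = vals[i - 1] if i > 0 else winner
        hi = vals[i + 1] if i + 1 < len(vals) else winner
        return lo, hi

    s_lo, s_hi = neighbours(coarse.stages, best_cfg.n_stages)
    l_lo, l_hi = neighbours(coarse.learning_rates, best_cfg.learning_rate)
    fine_stages = [int(s) for s in
                   np.arange(s_lo, s_hi + 1e-9, fine_stage_step)] or [s_lo]
    fine_lrs = [float(round(v, 10)) for v in
                np.arange(l_lo, l_hi + fine_lr_step * 1e-6, fine_lr_step)]
    fine = GridSpec(stages=fine_stages, learning_rates=fine_lrs)
    fine.stages = sorted(set(fine.stages))
    fine.learning_rates = sorted(set(round(l, 10) for l in fine.learning_rates))
    _evaluate_grid(X, y, fine, plan, base, variance_keep, result.evaluated)
    # de-duplicate repeat evaluations (identical folds give identical scores)
    seen = {}
    for cfg, cve, acc in result.evaluated:
        seen.setdefault((cfg.n_stages, cfg.learning_rate), (cfg, cve, acc))
    result.evaluated = list(seen.values())
    best = min(result.evaluated, key=lambda t: _sort_key(t[0], t[1]))
    result.best = best[0]
    return result


def exhaustive_search(X, y, plan: CVPlan, grid: GridSpec,
                      base: GBMConfig | None = None,
                      variance_keep: float | None = None) -> GridResult:
    """Single-pass exhaustive evaluation of a grid (reference strategy)."""
    base = base or GBMConfig()
    result = GridResult(stage="exhaustive")
    _evaluate_grid(np.asarray(X, float), np.asarray(y), grid, plan, base,
                   variance_keep, result.evaluated)
    best = min(result.evaluated, key=lambda t: _sort_key(t[0], t[1]))
    result.best = best[0]
    return result
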