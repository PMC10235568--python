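"""Patient-specific chronological training.

The protocol is strictly quasi-prospective: the first three
chronological seizures supply everything fitted -- the preictal-period
grid search, per-feature standardization, class balancing, feature
selection and the classifier itself -- and the remaining seizures are
used only for testing.  No fitting operation ever sees the test span.

Two classifier families are provided: a logistic regression balanced by
inverse-frequency class weights, and a voting ensemble of 15 linear
SVMs whose members differ through stochastic interictal subsampling and
stochastic forest-of-trees feature selection (each member's randomness
is derived from the master seed, so the whole ensemble is reproducible).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import sklearn.ensemble
import sklearn.exceptions
import sklearn.linear_model
import sklearn.metrics
import sklearn.svm

from . import alarms as alarms_mod
from .features import (FeatureMatrix, LABEL_EXCLUDED, LABEL_INTERICTAL,
                       LABEL_PREICTAL, label_windows)

__all__ = [
    "TrainTestSplit", "Standardizer", "LinearModel", "SvmEnsemble",
    "LogisticTrainer", "SvmEnsembleTrainer", "GridSearchResult",
    "chronological_split", "lr_class_weights", "segment_subsample",
    "forest_feature_selection", "train_logistic", "train_svm_ensemble",
    "predict_windows", "grid_search_preictal", "PREICTAL_GRID_MIN",
]

#: Candidate preictal durations (minutes) of the grid search.
PREICTAL_GRID_MIN = (30.0, 40.0, 50.0, 60.0)


@dataclasses.dataclass
class TrainTestSplit:
    """Chronological split: training seizures strictly precede test ones."""

    train: FeatureMatrix
    test: FeatureMatrix
    train_onsets_s: np.ndarray
    test_onsets_s: np.ndarray
    split_time_s: float


def chronological_split(
    features: FeatureMatrix,
    onsets_s: np.ndarray,
    n_train: int = 3,
    ictal_s: float = 60.0,
) -> TrainTestSplit:
    """Split windows at the end of the ``n_train``-th seizure.

    Requires at least ``n_train + 1`` seizures (the >= 4 recorded
    seizures inclusion criterion with the default split).  Training
    windows end with the last training seizure's ictal segment; every
    test window starts after it.
    """
    onsets = np.sort(np.asarray(onsets_s, dtype=float))
    if len(onsets) < n_train + 1:
        raise ValueError(
            f"{len(onsets)} seizures < {n_train + 1}; patients need at "
            f"least {n_train + 1} recorded seizures ({n_train} for "
            "training, >= 1 for testing)"
        )
    split_t = onsets[n_train - 1] + ictal_s
    in_train = features.window_start_s < split_t
    return TrainTestSplit(
        train=features.subset_rows(in_train),
        test=features.subset_rows(~in_train),
        train_onsets_s=onsets[:n_train],
        test_onsets_s=onsets[n_train:],
        split_time_s=float(split_t),
    )


class Standardizer:
    """Per-feature z-scoring with train statistics only.

    Zero-variance (constant) features are dropped with a warning; the
    surviving column indices are exposed as ``kept_``.
    """

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("cannot standardize an empty training set")
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        self.kept_ = np.flatnonzero(self.sd_ > 0)
        n_dropped = X.shape[1] - len(self.kept_)
        if n_dropped:
            warnings.warn(
                f"dropping {n_dropped} constant feature(s) before "
                "standardization", stacklevel=2,
            )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X[:, self.kept_] - self.mean_[self.kept_]) / self.sd_[self.kept_]

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def select_names(self, names: Sequence[str]) -> list[str]:
        return [names[i] for i in self.kept_]


def lr_class_weights(y: np.ndarray) -> dict[int, float]:
    """Inverse-frequency class weights: w_c = n_total / (2 * n_c)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("class weighting needs both classes present")
    n = len(y)
    return {int(c): n / (2.0 * k) for c, k in zip(classes, counts)}


def segment_subsample(
    interictal_indices: np.ndarray,
    n_segments: int,
    per_segment: int,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Representative interictal subsample from equally spaced segments.

    The chronologically ordered interictal windows are cut into
    ``n_segments`` equal contiguous spans and ``per_segment`` windows
    are drawn uniformly without replacement from each.  Segments
    shorter than ``per_segment`` contribute all their windows (with a
    warning).
    """
    idx = np.asarray(interictal_indices)
    if len(idx) < n_segments:
        raise ValueError(
            f"{len(idx)} interictal windows cannot fill {n_segments} segments"
        )
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    segments = np.array_split(idx, n_segments)
    chosen = []
    for seg in segments:
        if len(seg) <= per_segment:
            if len(seg) < per_segment:
                warnings.warn(
                    f"segment of {len(seg)} windows shorter than "
                    f"per_segment={per_segment}; taking all", stacklevel=2,
                )
            chosen.append(seg)
        else:
            chosen.append(rng.choice(seg, size=per_segment, replace=False))
    return np.sort(np.concatenate(chosen))


def forest_feature_selection(
    X: np.ndarray,
    y: np.ndarray,
    n_keep: int,
    n_trees: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Top features by impurity importance of a randomized-tree forest.

    Ties are broken by feature index (stable sort on descending
    importance).  Returns sorted indices of the ``n_keep`` winners.
    """
    X = np.asarray(X, dtype=float)
    if n_keep > X.shape[1]:
        raise ValueError(f"n_keep={n_keep} exceeds {X.shape[1]} features")
    forest = sklearn.ensemble.ExtraTreesClassifier(
        n_estimators=n_trees, random_state=int(seed) % (2 ** 31), n_jobs=1,
    )
    forest.fit(X, y)
    order = np.argsort(-forest.feature_importances_, kind="stable")
    return np.sort(order[:n_keep])


@dataclasses.dataclass
class LinearModel:
    """A linear decision rule on standardized, selected features.

    ``weights`` and ``intercept`` act on the standardized values of the
    ``selected_idx`` columns (indices into the standardizer output).
    The decision rule is margin >= 0 -> preictal (a zero margin is
    classified preictal by convention).
    """

    weights: np.ndarray
    intercept: float
    standardizer: Standardizer
    selected_idx: np.ndarray
    feature_names: list[str]
    preictal_min: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.selected_idx):
            raise ValueError("one weight per selected feature required")

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        """Standardized values of the selected features."""
        return self.standardizer.transform(X_raw)[:, self.selected_idx]

    def margin_standardized(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.weights + self.intercept

    def decision_function(self, X_raw: np.ndarray) -> np.ndarray:
        return self.margin_standardized(self.transform(X_raw))

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        return (self.decision_function(X_raw) >= 0.0).astype(np.int8)

    @property
    def selected_sd(self) -> np.ndarray:
        """Train-set standard deviation of the selected raw features."""
        return self.standardizer.sd_[self.standardizer.kept_][self.selected_idx]


@dataclasses.dataclass
class SvmEnsemble:
    """Majority-voting ensemble of (by default 15) SVMs.

    Members share the train standardizer but differ in their interictal
    subsample and selected features; all per-member randomness descends
    from the master seed.
    """

    members: list  # (fitted sklearn SVC, selected_idx) pairs
    standardizer: Standardizer
    feature_names: list[str]
    member_seeds: list[int]
    preictal_min: float | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_outputs(self, X_raw: np.ndarray) -> np.ndarray:
        """Binary outputs per member, shape (n_members, n_windows)."""
        Z = self.standardizer.transform(X_raw)
        return np.stack([
            (svc.decision_function(Z[:, sel]) >= 0.0).astype(np.int8)
            for svc, sel in self.members
        ])

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        votes = self.member_outputs(X_raw).sum(axis=0)
        return (votes * 2 > self.n_members).astype(np.int8)

    def decision_function(self, X_raw: np.ndarray) -> np.ndarray:
        """Vote fraction minus 0.5 (a margin-like score for ranking)."""
        votes = self.member_outputs(X_raw).mean(axis=0)
        return votes - 0.5


def train_logistic(
    X: np.ndarray,
    y: np.ndarray,
    class_weight: dict | None = None,
    C: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> sklearn.linear_model.LogisticRegression:
    """Deterministic logistic-regression fit on standardized features.

    ``C`` is the inverse L2 regularization strength; ``C=np.inf`` gives
    the plain unpenalized maximum-likelihood fit.  Raises on
    non-convergence instead of warning.
    """
    lr = sklearn.linear_model.LogisticRegression(
        C=C, tol=tol, max_iter=max_iter,
        class_weight=class_weight, solver="lbfgs",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", sklearn.exceptions.ConvergenceWarning)
        try:
            lr.fit(np.asarray(X, dtype=float), np.asarray(y))
        except sklearn.exceptions.ConvergenceWarning as exc:
            raise RuntimeError(
                f"logistic regression did not converge (tol={tol}, "
                f"max_iter={max_iter}): {exc}"
            ) from exc
    return lr


def predict_windows(model, X_raw: np.ndarray) -> np.ndarray:
    """Binary per-window outputs of a fitted model.

    Logistic regression: probability >= 0.5 (margin >= 0 -> 1, the
    documented zero-margin tie rule).  Ensemble: majority vote of the
    member binary outputs (8 of 15 suffices; ties are impossible with
    an odd member count).
    """
    if np.asarray(X_raw).shape[1] != _expected_features(model):
        raise ValueError("feature count does not match the fitted model")
    return model.predict(np.asarray(X_raw, dtype=float)).astype(np.int8)


def _expected_features(model) -> int:
    if isinstance(model, (LinearModel, SvmEnsemble)):
        return len(model.standardizer.mean_)
    return model.n_features_in_


class LogisticTrainer:
    """Standardize -> (optional) forest feature selection -> weighted LR."""

    def __init__(self, C: float = 1.0, n_keep: int | None = 20,
                 n_trees: int = 100):
        self.C = C
        self.n_keep = n_keep
        self.n_trees = n_trees

    def fit(self, X_raw: np.ndarray, y: np.ndarray,
            feature_names: Sequence[str], seed: int = 0,
            preictal_min: float | None = None) -> LinearModel:
        std = Standardizer().fit(X_raw)
        Z = std.transform(X_raw)
        names = std.select_names(list(feature_names))
        if self.n_keep is not None and self.n_keep < Z.shape[1]:
            sel = forest_feature_selection(Z, y, self.n_keep, self.n_trees, seed)
        else:
            sel = np.arange(Z.shape[1])
        lr = train_logistic(Z[:, sel], y, class_weight=lr_class_weights(y),
                            C=self.C)
        return LinearModel(
            weights=lr.coef_[0], intercept=float(lr.intercept_[0]),
            standardizer=std, selected_idx=sel,
            feature_names=[names[i] for i in sel],
            preictal_min=preictal_min,
        )


class SvmEnsembleTrainer:
    """Voting ensemble: per-member interictal subsample + feature selection."""

    def __init__(self, n_models: int = 15, n_keep: int | None = 20,
                 n_trees: int = 100, C: float = 1.0, kernel: str = "linear",
                 n_segments: int = 10):
        self.n_models = n_models
        self.n_keep = n_keep
        self.n_trees = n_trees
        self.C = C
        self.kernel = kernel
        self.n_segments = n_segments

    def fit(self, X_raw: np.ndarray, y: np.ndarray,
            feature_names: Sequence[str], seed: int = 0,
            preictal_min: float | None = None) -> SvmEnsemble:
        y = np.asarray(y)
        std = Standardizer().fit(X_raw)
        Z = std.transform(X_raw)
        names = std.select_names(list(feature_names))
        pre_idx = np.flatnonzero(y == 1)
        int_idx = np.flatnonzero(y == 0)
        if len(pre_idx) == 0 or len(int_idx) == 0:
            raise ValueError("ensemble training needs both classes")
        per_segment = max(1, int(round(len(pre_idx) / self.n_segments)))
        seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in np.random.SeedSequence(seed).spawn(self.n_models)]
        members = []
        for m_seed in seeds:
            rng = np.random.default_rng(m_seed)
            sub = segment_subsample(int_idx, self.n_segments, per_segment, rng)
            rows = np.concatenate([pre_idx, sub])
            Zm, ym = Z[rows], y[rows]
            if self.n_keep is not None and self.n_keep < Z.shape[1]:
                sel = forest_feature_selection(Zm, ym, self.n_keep,
                                               self.n_trees, m_seed)
            else:
                sel = np.arange(Z.shape[1])
            svc = sklearn.svm.SVC(kernel=self.kernel, C=self.C,
                                  random_state=m_seed)
            svc.fit(Zm[:, sel], ym)
            members.append((svc, sel))
        return SvmEnsemble(
            members=members, standardizer=std, feature_names=names,
            member_seeds=seeds, preictal_min=preictal_min,
        )


def train_svm_ensemble(train: FeatureMatrix, n_models: int = 15,
                       seed: int = 0, **kwargs) -> SvmEnsemble:
    """Convenience wrapper over :class:`SvmEnsembleTrainer` for a labelled
    feature matrix (excluded windows are dropped)."""
    if train.labels is None:
        raise ValueError("training features must be labelled")
    keep = train.labels != LABEL_EXCLUDED
    fm = train.subset_rows(keep)
    trainer = SvmEnsembleTrainer(n_models=n_models, **kwargs)
    return trainer.fit(fm.values, fm.labels, fm.feature_names, seed=seed)


# ---------------------------------------------------------------------------
# preictal-period grid search
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GridSearchResult:
    """Selected preictal duration and per-candidate scores."""

    best_min: float
    scores: dict[float, float]
    per_fold: dict[float, list[float]]


def _fold_spans(span_start: float, onsets: np.ndarray, ictal_s: float,
                ) -> list[tuple[float, float]]:
    spans = []
    prev_end = span_start
    for onset in onsets:
        spans.append((prev_end, onset + ictal_s))
        prev_end = onset + ictal_s
    return spans


def grid_search_preictal(
    features: FeatureMatrix,
    train_onsets_s: np.ndarray,
    grid: Sequence[float] = PREICTAL_GRID_MIN,
    trainer=None,
    metric: str = "auc",
    sph_min: float = 10.0,
    threshold: float = alarms_mod.DEFAULT_THRESHOLD,
    ictal_s: float = 60.0,
    seed: int = 0,
) -> GridSearchResult:
    """Select the preictal duration by leave-one-seizure-out validation.

    For each candidate duration the training windows are relabelled and
    each of the (>= 3) training seizures is held out in turn: a model is
    fitted on the remaining seizures' windows and scored on the held-out
    seizure's span.

    The default score is the window-level ROC AUC of the held-out span
    under the candidate's labelling, standardized by its Mann-Whitney
    null standard error (candidates label different numbers of windows
    preictal, so raw AUCs fluctuate more for extreme durations; without
    the standardization the argmax would favour extreme candidates on
    score variance alone when no preictal signal exists).
    ``metric="alarm"`` instead runs the full Firing Power / alarm chain
    on the held-out span and scores ``predicted - normalized FPR``.
    The best candidate maximises the mean fold score; ties go to the
    shortest duration.
    """
    if len(grid) == 0:
        raise ValueError("empty preictal grid")
    if metric not in ("auc", "alarm"):
        raise ValueError("metric must be 'auc' or 'alarm'")
    onsets = np.sort(np.asarray(train_onsets_s, dtype=float))
    if len(onsets) < 3:
        raise ValueError("grid search needs at least 3 training seizures")
    if trainer is None:
        trainer = LogisticTrainer()
    span_start = float(features.window_start_s[0])
    fold_spans = _fold_spans(span_start, onsets, ictal_s)
    starts = features.window_start_s

    scores: dict[float, float] = {}
    per_fold: dict[float, list[float]] = {}
    fold_seeds = np.random.SeedSequence(seed).spawn(len(onsets))
    for cand in grid:
        labeled = features.relabel(onsets, cand * 60.0, ictal_s)
        fold_scores = []
        for k, (lo, hi) in enumerate(fold_spans):
            held = (starts >= lo) & (starts < hi)
            train_rows = ~held & (labeled.labels != LABEL_EXCLUDED)
            f_seed = int(fold_seeds[k].generate_state(1)[0] % (2 ** 31))
            model = trainer.fit(
                labeled.values[train_rows], labeled.labels[train_rows],
                labeled.feature_names, seed=f_seed,
            )
            if metric == "auc":
                eval_rows = held & (labeled.labels != LABEL_EXCLUDED)
                y = (labeled.labels[eval_rows] == LABEL_PREICTAL).astype(int)
                n1, n0 = int(y.sum()), int((1 - y).sum())
                if n1 == 0 or n0 == 0:
                    fold_scores.append(0.0)
                    continue
                s = model.decision_function(labeled.values[eval_rows])
                auc = sklearn.metrics.roc_auc_score(y, s)
                se = math.sqrt((n1 + n0 + 1) / (12.0 * n1 * n0))
                fold_scores.append((auc - 0.5) / se)
            else:
                held_idx = np.flatnonzero(held)
                preds = predict_windows(model, labeled.values[held_idx])
                tau = max(1, int(round(cand * 60.0 / features.window_s)))
                fps = alarms_mod.firing_power(preds, tau, threshold=threshold)
                ictal_mask = labeled.labels[held_idx] == LABEL_EXCLUDED
                evts, _ = alarms_mod.generate_alarms(
                    fps, refractory_windows=tau, ictal_mask=ictal_mask,
                    window_s=features.window_s,
                    window_start_s=starts[held_idx],
                )
                horizon = alarms_mod.HorizonSpec(sop_min=cand, sph_min=sph_min)
                classified, predicted = alarms_mod.classify_alarms(
                    evts, np.array([onsets[k]]), horizon,
                )
                n_false = sum(e.kind == "false_positive" for e in classified)
                max_alarms = max(1, math.ceil(len(held_idx) / tau))
                fold_scores.append(float(predicted[0]) - n_false / max_alarms)
        per_fold[float(cand)] = [float(s) for s in fold_scores]
        scores[float(cand)] = float(np.mean(fold_scores))

    best = None
    for cand in sorted(scores):
        if best is None or scores[cand] > scores[best] + 1e-12:
            best = cand
    return GridSearchResult(best_min=float(best), scores=scores,
                            per_fold=per_fold)
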