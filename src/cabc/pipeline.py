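"""Feature selection by recursive cABC analysis of permutation importances.

The protocol:

1. Set aside a stratified 20% holdout that is never touched during
   importance computation or boundary calculation.
2. On the training 80%, run repeated stratified k-fold cross-validation
   (default 5 splits x 20 repeats); in each fold, fit the classifier and
   compute permutation importance (default 50 shuffles per feature, score
   drop in balanced accuracy) on the fold's test part.
3. Average importances across folds (negatives clamped to zero) and run
   recursive cABC analysis on the mean importance vector.
4. For the full set and each recursion level, repeatedly retrain on 80%
   resamples of the training data restricted to that level's features and
   evaluate balanced accuracy on random 80% draws of the holdout,
   summarized as the median and the nonparametric 95% CI (2.5th/97.5th
   percentiles across the evaluation runs).
5. Report a permuted-target control (labels shuffled once, same pipeline)
   alongside; its CI should cover 0.5, the two-class chance level.

The classifier is a pluggable fit/predict contract; the default is a
random forest.  The classifier-performance stopping criterion is applied
to the evaluated levels: the recommended set is the deepest level whose CI
lower bound stays above the performance floor and whose median has not
dropped more than ``accuracy_drop`` below the full-feature median.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .core import ItemSet
from .errors import ConfigError, StratificationError
from .recursion import RecursionConfig, RecursionTrace, recursive_cabc

__all__ = [
    "Dataset",
    "PipelineConfig",
    "LevelResult",
    "SelectionReport",
    "AccuracyCI",
    "stratified_holdout",
    "mean_permutation_importance",
    "balanced_accuracy_ci",
    "select_features",
]


@dataclass(frozen=True)
class Dataset:
    """Tabular classification data: numeric features and class labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if X.shape[1] < 1:
            raise ValueError("need at least 1 feature")
        if len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names must match the number of columns")
        if pd.isna(y).any():
            raise ValueError("labels must not contain missing values")
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 classes")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_cases(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label: str) -> "Dataset":
        if label not in frame.columns:
            raise KeyError(f"label column {label!r} not in data")
        y = frame[label].to_numpy()
        feats = frame.drop(columns=[label])
        return cls(feats.to_numpy(dtype=float), y, tuple(feats.columns))

    def restrict(self, features: Sequence) -> "Dataset":
        idx = [self.feature_names.index(f) for f in features]
        return Dataset(self.X[:, idx], self.y,
                       tuple(self.feature_names[i] for i in idx))


def _default_classifier(seed: int):
    return RandomForestClassifier(n_estimators=100, random_state=seed)


@dataclass
class PipelineConfig:
    """Knobs of the selection protocol; defaults follow the study design."""

    holdout_fraction: float = 0.20
    cv_splits: int = 5
    cv_repeats: int = 20
    importance_permutations: int = 50
    recursion: RecursionConfig = field(default_factory=RecursionConfig)
    performance_floor: float = 0.5
    accuracy_drop: float = 0.10
    eval_draws: int = 100
    eval_fraction: float = 0.8
    include_permuted_control: bool = True
    classifier_factory: Callable[[int], object] = _default_classifier
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.holdout_fraction < 0.5:
            raise ConfigError("holdout_fraction must be in (0, 0.5)")
        for name in ("cv_splits", "cv_repeats", "importance_permutations",
                     "eval_draws"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")


def stratified_holdout(dataset: Dataset, fraction: float = 0.20,
                       seed: int = 0) -> tuple:
    """Split off a class-proportional validation sample.

    Returns ``(train, validation)``; proportions in both parts are within
    one case of exact stratification (rounding per scikit-learn's
    stratified splitter).  Deterministic given the seed.
    """
    _, counts = np.unique(dataset.y, return_counts=True)
    if counts.min() < 2:
        raise StratificationError(
            "every class needs at least 2 cases for a stratified split")
    idx = np.arange(dataset.n_cases)
    tr, va = train_test_split(idx, test_size=fraction, stratify=dataset.y,
                              random_state=seed)
    tr.sort(), va.sort()
    return (
        Dataset(dataset.X[tr], dataset.y[tr], dataset.feature_names),
        Dataset(dataset.X[va], dataset.y[va], dataset.feature_names),
    )


def _fold_mean_importances(train: Dataset, config: PipelineConfig) -> np.ndarray:
    cv = RepeatedStratifiedKFold(n_splits=config.cv_splits,
                                 n_repeats=config.cv_repeats,
                                 random_state=config.seed)
    sums = np.zeros(train.n_features)
    n_folds = 0
    for k, (tr, te) in enumerate(cv.split(train.X, train.y)):
        clf = config.classifier_factory(config.seed + 1000 + k)
        try:
            clf.fit(train.X[tr], train.y[tr])
            imp = permutation_importance(
                clf, train.X[te], train.y[te], scoring="balanced_accuracy",
                n_repeats=config.importance_permutations,
                random_state=config.seed + 2000 + k)
        except Exception as exc:  # noqa: BLE001 - annotate the fold and re-raise
            raise RuntimeError(f"classifier failed on fold {k}") from exc
        sums += imp.importances_mean
        n_folds += 1
    return np.clip(sums / n_folds, 0.0, None)


def mean_permutation_importance(train: Dataset, config: PipelineConfig) -> ItemSet:
    """Cross-validated permutation importance, averaged over folds.

    Over ``cv_splits x cv_repeats`` stratified folds, the classifier is
    fitted on the fold's training part and each feature is shuffled
    ``importance_permutations`` times on the fold's test part; the drop in
    balanced accuracy is the fold importance.  Fold importances are
    averaged per feature and clamped at zero (a negative mean permutation
    importance carries the same "unimportant" message as zero, and cABC
    requires non-negative input).
    """
    return ItemSet(train.feature_names, _fold_mean_importances(train, config))


class AccuracyCI(NamedTuple):
    median: float
    lower: float
    upper: float


def balanced_accuracy_ci(scores) -> AccuracyCI:
    """Median and nonparametric 95% CI (2.5th/97.5th percentiles) of scores."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one evaluation run")
    return AccuracyCI(float(np.median(s)),
                      float(np.percentile(s, 2.5)),
                      float(np.percentile(s, 97.5)))


def _draw_with_all_classes(y, size, rng):
    """Index draw without replacement, redrawn until every class appears."""
    classes = np.unique(y)
    for _ in range(1000):
        pick = rng.choice(y.shape[0], size=size, replace=False)
        if np.isin(classes, y[pick]).all():
            return pick
    raise RuntimeError("could not draw a subsample containing all classes")


@dataclass(frozen=True)
class LevelResult:
    """One row of the selection report."""

    name: str                 # "full", "A", "AA", ...
    features: tuple
    ks_p: Optional[float]     # uniformity p of this feature list's importances
    accuracy: AccuracyCI

    @property
    def n_features(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class SelectionReport:
    """Output of :func:`select_features`."""

    importances: Optional[ItemSet]   # None when all mean importances are zero
    trace: Optional[RecursionTrace]
    levels: tuple                       # LevelResult, "full" first
    recommended: str                    # name of the recommended level
    permuted_control: Optional["SelectionReport"]
    n_train: int
    n_validation: int
    seed: int

    @property
    def selected_sets(self) -> dict:
        """Per-level feature tuples (independent of any holdout evaluation)."""
        return {lvl.name: lvl.features for lvl in self.levels}

    def level(self, name: str) -> LevelResult:
        for lvl in self.levels:
            if lvl.name == name:
                return lvl
        raise KeyError(name)

    @property
    def final_features(self) -> tuple:
        return self.level(self.recommended).features

    def to_markdown(self) -> str:
        total = self.levels[0].n_features
        lines = ["| cABC level | KS p (items) | features (% of all) | "
                 "median balanced accuracy (95% CI) | feature names |",
                 "|---|---|---|---|---|"]

        def _fmt(lvl: LevelResult, tag: str) -> str:
            ks = "–" if lvl.ks_p is None else f"{lvl.ks_p:.3g}"
            acc = (f"{lvl.accuracy.median:.2f} "
                   f"({lvl.accuracy.lower:.2f}–{lvl.accuracy.upper:.2f})")
            names = ", ".join(map(str, lvl.features))
            if len(names) > 120:
                names = names[:117] + "..."
            return (f"| {tag} | {ks} | {lvl.n_features} "
                    f"({100 * lvl.n_features / total:.0f}%) | {acc} | {names} |")

        for i, lvl in enumerate(self.levels):
            tag = f"{i}: {lvl.name}" + (" *" if lvl.name == self.recommended else "")
            lines.append(_fmt(lvl, tag))
        if self.permuted_control is not None:
            ctrl = self.permuted_control.levels[-1]
            acc = ctrl.accuracy
            lines.append(f"| permuted target | – | {ctrl.n_features} | "
                         f"{acc.median:.2f} ({acc.lower:.2f}–{acc.upper:.2f}) | – |")
        return "\n".join(lines)


def _evaluate_level(features: Sequence, train: Dataset, val: Dataset,
                    config: PipelineConfig, seed: int,
                    rng: np.random.Generator) -> AccuracyCI:
    """Repeated-run balanced accuracy of one feature set on the holdout.

    Each evaluation run refits the classifier on a random 80% resample of
    the training data containing every class (the training share of a
    5-fold CV run) and scores one random 80% draw of the holdout, so the
    CI reflects both training and evaluation variability, as in repeated
    cross-validation.
    """
    sub_tr = train.restrict(features)
    sub_va = val.restrict(features)
    val_size = max(2, int(round(config.eval_fraction * sub_va.n_cases)))
    scores = np.empty(config.eval_draws)
    for i in range(config.eval_draws):
        tr_pick = _draw_with_all_classes(
            sub_tr.y, max(2, int(round(config.eval_fraction * sub_tr.n_cases))),
            rng)
        clf = config.classifier_factory(seed + i)
        clf.fit(sub_tr.X[tr_pick], sub_tr.y[tr_pick])
        va_pick = _draw_with_all_classes(sub_va.y, val_size, rng)
        scores[i] = balanced_accuracy_score(sub_va.y[va_pick],
                                            clf.predict(sub_va.X[va_pick]))
    return balanced_accuracy_ci(scores)


def select_features(dataset: Dataset,
                    config: Optional[PipelineConfig] = None) -> SelectionReport:
    """Run the full selection protocol on a dataset.

    The holdout labels enter only the per-level accuracy evaluation; the
    per-level feature sets are a pure function of the training data, so
    they are unchanged by any manipulation of the validation labels.
    """
    if config is None:
        config = PipelineConfig()
    if dataset.n_features < 3:
        raise ValueError("feature selection needs at least 3 features")
    train, val = stratified_holdout(dataset, config.holdout_fraction,
                                    seed=config.seed)
    report = _run(train, val, config)
    if config.include_permuted_control:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(999,)))
        y_perm = rng.permutation(dataset.y)
        null_data = Dataset(dataset.X, y_perm, dataset.feature_names)
        null_tr, null_va = stratified_holdout(null_data,
                                              config.holdout_fraction,
                                              seed=config.seed)
        null = _run(null_tr, null_va, config)
        report = replace(report, permuted_control=null)
    return report


def _run(train: Dataset, val: Dataset, config: PipelineConfig) -> SelectionReport:
    mean_imp = _fold_mean_importances(train, config)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))

    if not np.any(mean_imp > 0):
        importances = None
        trace = None
        level_sets = []
        full_p = None
    else:
        importances = ItemSet(train.feature_names, mean_imp)
        trace = recursive_cabc(importances, config.recursion)
        level_sets = trace.level_sets()
        full_p = (trace.levels[0].uniformity.p_value
                  if trace.levels and trace.levels[0].uniformity is not None
                  else (trace.final_uniformity.p_value
                        if trace.final_uniformity is not None else None))

    # per-level KS p-values: row k reports the uniformity of that row's own
    # item list (the next level's input, or the final candidate list)
    ks_by_row = [full_p]
    if trace is not None:
        for k in range(len(trace.levels)):
            if k + 1 < len(trace.levels):
                uni = trace.levels[k + 1].uniformity
            else:
                uni = trace.final_uniformity
            ks_by_row.append(uni.p_value if uni is not None else None)

    levels = []
    full_ci = _evaluate_level(train.feature_names, train, val, config,
                              config.seed + 5000, rng)
    levels.append(LevelResult("full", train.feature_names, ks_by_row[0], full_ci))
    for k, feats in enumerate(level_sets):
        ci = _evaluate_level(feats, train, val, config,
                             config.seed + 5001 + k, rng)
        levels.append(LevelResult("A" * (k + 1), tuple(feats),
                                  ks_by_row[k + 1], ci))

    # performance criterion: deepest level still above the floor and within
    # accuracy_drop of the full-feature median
    recommended = "full"
    for lvl in levels[1:]:
        ok = (lvl.accuracy.lower > config.performance_floor
              and lvl.accuracy.median >= full_ci.median - config.accuracy_drop)
        if ok:
            recommended = lvl.name
        else:
            break

    return SelectionReport(importances=importances, trace=trace,
                           levels=tuple(levels), recommended=recommended,
                           permuted_control=None,
                           n_train=train.n_cases, n_validation=val.n_cases,
                           seed=config.seed)
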