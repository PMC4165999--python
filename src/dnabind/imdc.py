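"""imDC: an imbalance-aware ensemble classifier.

The training data for sequence-function problems is typically dominated by
the negative class, and single classifiers trained on the raw data buy their
headline accuracy by ignoring the minority (positive) class.  imDC counters
this in three moves:

1. **Pool ranking** — a catalogue of 16 base-learner families is scored by
   stratified cross-validation on the full data and the best ``top_k``
   (default 5) are kept.  The ranking metric defaults to the minority-class
   F-measure, the quantity single classifiers fail on.
2. **Balanced rounds** — the majority class is undersampled into ``iterNum``
   class-balanced training sets.  The default ``cycle_partition`` sampler
   shuffles the majority once, partitions it into ceil(m/n) blocks of
   minority size n, and cycles the blocks across rounds, so with
   ``iterNum="auto"`` every majority sample is trained on exactly once.
3. **Weighted vote** — each kept learner is fitted on each round; its vote
   weight is its metric on the samples *outside* its round (an out-of-round
   holdout, so weights are not optimistically biased).  Prediction is the
   weighted average of hard 0/1 votes, thresholded at 0.5.

Everything is deterministic given (data, config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, Perceptron, RidgeClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import confusion, metrics

logger = logging.getLogger(__name__)

__all__ = [
    "LearnerSpec",
    "EnsembleConfig",
    "EnsembleModel",
    "default_pool",
    "rank_pool",
    "make_balanced_rounds",
    "train",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclasses.dataclass(frozen=True)
class LearnerSpec:
    """One base-learner family and how to instantiate it."""

    name: str
    factory: Callable[[int], object]  # seed -> unfitted estimator
    seed_consuming: bool = True


def _scaled(est) -> object:
    return make_pipeline(StandardScaler(), est)


def default_pool() -> list[LearnerSpec]:
    """The 16-entry base-learner catalogue.

    Covers the classic families: RBF and linear support-vector machines,
    naive Bayes, nearest neighbours, random forest, a single decision tree,
    bagged trees, boosted stumps, logistic and ridge linear models, linear
    and quadratic discriminants, a perceptron, a small feed-forward network,
    extremely randomised trees, and a decision-stump baseline.
    """
    return [
        LearnerSpec("svm_rbf", lambda s: _scaled(SVC(kernel="rbf", random_state=s))),
        LearnerSpec(
            "svm_linear", lambda s: _scaled(SVC(kernel="linear", random_state=s))
        ),
        LearnerSpec("naive_bayes", lambda s: GaussianNB(), seed_consuming=False),
        LearnerSpec(
            "knn",
            lambda s: _scaled(KNeighborsClassifier(n_neighbors=5)),
            seed_consuming=False,
        ),
        LearnerSpec(
            "random_forest",
            lambda s: RandomForestClassifier(n_estimators=100, random_state=s),
        ),
        LearnerSpec(
            "decision_tree", lambda s: DecisionTreeClassifier(random_state=s)
        ),
        LearnerSpec(
            "bagged_trees",
            lambda s: BaggingClassifier(
                DecisionTreeClassifier(random_state=s),
                n_estimators=25,
                random_state=s,
            ),
        ),
        LearnerSpec(
            "boosted_stumps",
            lambda s: AdaBoostClassifier(n_estimators=50, random_state=s),
        ),
        LearnerSpec(
            "logistic",
            lambda s: _scaled(LogisticRegression(max_iter=1000, random_state=s)),
        ),
        LearnerSpec(
            "ridge", lambda s: _scaled(RidgeClassifier()), seed_consuming=False
        ),
        LearnerSpec("lda", lambda s: LinearDiscriminantAnalysis(), seed_consuming=False),
        LearnerSpec(
            "qda",
            lambda s: QuadraticDiscriminantAnalysis(reg_param=0.1),
            seed_consuming=False,
        ),
        LearnerSpec(
            "perceptron", lambda s: _scaled(Perceptron(random_state=s))
        ),
        LearnerSpec(
            "mlp",
            lambda s: _scaled(
                MLPClassifier(
                    hidden_layer_sizes=(16,), max_iter=300, random_state=s
                )
            ),
        ),
        LearnerSpec(
            "extra_trees",
            lambda s: ExtraTreesClassifier(n_estimators=100, random_state=s),
        ),
        LearnerSpec(
            "stump", lambda s: DecisionTreeClassifier(max_depth=1, random_state=s)
        ),
    ]


@dataclasses.dataclass(frozen=True)
class EnsembleConfig:
    top_k: int = 5
    iter_num: int | str = "auto"  # "auto" resolves to ceil(m/n)
    sampling: str = "cycle_partition"  # or "random_undersample"
    weight_metric: str = "minority_F"  # minority_F | weighted_F | accuracy
    rank_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling not in ("cycle_partition", "random_undersample"):
            raise ValueError(f"unknown sampling scheme: {self.sampling!r}")
        if self.weight_metric not in ("minority_F", "weighted_F", "accuracy"):
            raise ValueError(f"unknown weight metric: {self.weight_metric!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.iter_num != "auto" and int(self.iter_num) < 1:
            raise ValueError("iterNum must be >= 1 or 'auto'")


@dataclasses.dataclass
class Member:
    learner_name: str
    round_index: int
    model: object
    weight: float


@dataclasses.dataclass
class EnsembleModel:
    config: EnsembleConfig
    selected: list[tuple[str, float]]  # (learner name, pool ranking score)
    members: list[Member]
    feature_names: tuple[str, ...]
    minority_label: int
    iter_num: int


def _metric_value(y_true, y_pred, which: str, minority_label: int) -> float:
    c = confusion(y_true, y_pred)
    c_min = c if minority_label == 1 else c.swapped()
    m_min = metrics(c_min)
    if which == "minority_F":
        return m_min.f_measure
    if which == "accuracy":
        return m_min.accuracy
    # weighted_F: support-weighted mean of the two per-class F-measures
    m_maj = metrics(c_min.swapped())
    n_min = c_min.tp + c_min.fn
    n_maj = c_min.tn + c_min.fp
    return (n_min * m_min.f_measure + n_maj * m_maj.f_measure) / (n_min + n_maj)


def _minority_label(y: np.ndarray) -> int:
    counts = np.bincount(y, minlength=2)
    return 1 if counts[1] <= counts[0] else 0


def rank_pool(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    pool: Sequence[LearnerSpec] | None = None,
    folds: int = 5,
    seed: int = 0,
    weight_metric: str = "minority_F",
) -> list[tuple[LearnerSpec, float]]:
    """Score every pool member by stratified CV and sort descending.

    A learner that fails to fit or predict scores 0 with a logged warning.
    Ties are resolved by learner name so the ordering is reproducible.
    """
    if pool is None:
        pool = default_pool()
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    minority = _minority_label(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(matrix, y))
    scored = []
    for spec in pool:
        pred = np.empty_like(y)
        try:
            for tr, te in splits:
                est = spec.factory(seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(matrix.iloc[tr].to_numpy(), y[tr])
                    pred[te] = est.predict(matrix.iloc[te].to_numpy())
            score = _metric_value(y, pred, weight_metric, minority)
        except Exception as exc:  # noqa: BLE001 - a broken learner must not kill the run
            logger.warning("learner %s failed during ranking: %s", spec.name, exc)
            score = 0.0
        scored.append((spec, float(score)))
    scored.sort(key=lambda t: (-t[1], t[0].name))
    return scored


def make_balanced_rounds(
    labels: Sequence[int],
    iter_num: int | str = "auto",
    sampling: str = "cycle_partition",
    seed: int = 0,
) -> list[np.ndarray]:
    """Index sets for class-balanced training rounds.

    Each round holds all n minority indices plus n majority indices.  With
    ``cycle_partition`` the majority is shuffled once, split into ceil(m/n)
    blocks that are cycled across rounds (the last, short block padded by
    wrapping around the shuffled order); ``random_undersample`` draws n
    majority indices afresh each round.  ``iter_num="auto"`` resolves to
    ceil(m/n).
    """
    y = np.asarray(labels).astype(int)
    minority = _minority_label(y)
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    n, m = len(min_idx), len(maj_idx)
    if n == 0:
        raise ValueError("no minority samples")
    n_blocks = max(1, math.ceil(m / n))
    if iter_num == "auto":
        iter_num = n_blocks
    iter_num = int(iter_num)
    rng = np.random.default_rng(seed)
    rounds = []
    if sampling == "cycle_partition":
        shuffled = rng.permutation(maj_idx)
        for r in range(iter_num):
            block = r % n_blocks
            start = block * n
            chunk = shuffled[start : start + n]
            if len(chunk) < n:  # pad the short tail block by wrapping around
                chunk = np.concatenate([chunk, shuffled[: n - len(chunk)]])
            rounds.append(np.sort(np.concatenate([min_idx, chunk])))
    elif sampling == "random_undersample":
        for _ in range(iter_num):
            chunk = rng.choice(maj_idx, size=min(n, m), replace=False)
            rounds.append(np.sort(np.concatenate([min_idx, chunk])))
    else:
        raise ValueError(f"unknown sampling scheme: {sampling!r}")
    return rounds


def train(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    config: EnsembleConfig | None = None,
    pool: Sequence[LearnerSpec] | None = None,
) -> EnsembleModel:
    """Fit the full ensemble: rank pool, keep top_k, train over balanced rounds.

    Every member's vote weight is the configured metric evaluated on the
    samples not in its training round; negative-impossible, but weights are
    floored at 0 for safety.  Raises if every weight is 0 (degenerate
    ensemble).
    """
    if config is None:
        config = EnsembleConfig()
    if pool is None:
        pool = default_pool()
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValueError("feature matrix must be finite")
    minority = _minority_label(y)
    ranked = rank_pool(
        matrix,
        y,
        pool,
        folds=config.rank_folds,
        seed=config.seed,
        weight_metric=config.weight_metric,
    )
    kept = ranked[: config.top_k]
    rounds = make_balanced_rounds(
        y, config.iter_num, config.sampling, seed=config.seed
    )
    X = matrix.to_numpy()
    all_idx = np.arange(len(y))
    members: list[Member] = []
    for r, round_idx in enumerate(rounds):
        holdout = np.setdiff1d(all_idx, round_idx)
        for j, (spec, _) in enumerate(kept):
            member_seed = (config.seed * 1000003 + r * 131 + j * 7) % (2**31 - 1)
            est = spec.factory(member_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X[round_idx], y[round_idx])
            if len(holdout) and len(np.unique(y[holdout])) == 2:
                pred = est.predict(X[holdout])
                weight = _metric_value(
                    y[holdout], pred, config.weight_metric, minority
                )
            else:  # no usable holdout (balanced input): fall back to round metric
                pred = est.predict(X[round_idx])
                weight = _metric_value(
                    y[round_idx], pred, config.weight_metric, minority
                )
            members.append(Member(spec.name, r, est, max(0.0, float(weight))))
    if not any(m.weight > 0 for m in members):
        raise ValueError("ensemble degenerate: all member weights are 0")
    return EnsembleModel(
        config=config,
        selected=[(s.name, sc) for s, sc in kept],
        members=members,
        feature_names=tuple(matrix.columns),
        minority_label=minority,
        iter_num=len(rounds),
    )


def predict(
    model: EnsembleModel, matrix: pd.DataFrame, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-vote prediction: (labels, scores in [0, 1]).

    The score is the weight-normalised fraction of members voting for the
    positive class; the label is positive when the score reaches the
    threshold.
    """
    got = tuple(matrix.columns)
    if got != model.feature_names:
        missing = set(model.feature_names) - set(got)
        extra = set(got) - set(model.feature_names)
        raise ValueError(
            f"feature mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    X = matrix.to_numpy()
    total_w = sum(m.weight for m in model.members)
    score = np.zeros(len(matrix))
    for m in model.members:
        if m.weight == 0:
            continue
        votes = m.model.predict(X)
        score += m.weight * (votes == 1)
    score /= total_w
    return (score >= threshold).astype(int), score


def save_model(model: EnsembleModel, path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> EnsembleModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version: {payload.get('format_version')!r}"
        )
    return payload["model"]
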