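"""Repeated-split classifier evaluation.

The evaluation protocol: per repeat, draw a stratified 70/30
train/validation split, fit the z-score normalizer on the training rows,
train a classifier (L2 logistic regression or a one-hidden-layer neural
network), score the validation rows, and record the Mann-Whitney AUC
and the sensitivity/specificity at the Youden-optimal operating point.
The procedure is repeated (default 100 times) and summarised by the
mean and SD of each metric.  Everything is reproducible from a single
master seed via per-repeat spawned seed sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .features import FeatureTable, Normalizer
from .registry import GROUPS, resolve_subset

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("logistic_regression", "neural_network")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family, feature subset and hyperparameters.

    Defaults: logistic regression uses an L2 ridge of strength C=1 on
    normalized features; the neural network is a single hidden layer of
    10 logistic units with alpha=1e-3, both capped at 1000 iterations.
    """

    kind: str = "neural_network"
    feature_subset: str = "combined"
    hidden_units: int = 10
    l2_logistic_C: float = 1.0
    nn_alpha: float = 1e-3
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        resolve_subset(self.feature_subset)
        if self.kind == "neural_network" and self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")

    @property
    def features(self) -> tuple[str, ...]:
        return resolve_subset(self.feature_subset)


@dataclass(frozen=True)
class SplitEvalResult:
    """Per-repeat validation metrics and their summary for one
    classifier spec and class pair."""

    spec: ClassifierSpec
    class_pair: tuple[str, str]
    per_repeat: pd.DataFrame  # columns: repeat, auc, sensitivity, specificity, converged
    master_seed: int

    @property
    def summary(self) -> dict[str, float]:
        out = {}
        for metric in ("auc", "sensitivity", "specificity"):
            out[f"mean_{metric}"] = float(self.per_repeat[metric].mean())
            out[f"sd_{metric}"] = float(self.per_repeat[metric].std(ddof=1)) if len(self.per_repeat) > 1 else 0.0
        out["n_repeats"] = int(len(self.per_repeat))
        out["n_nonconverged"] = int((~self.per_repeat["converged"]).sum())
        return out


def stratified_split(labels: Sequence, train_fraction: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-class proportional split of row positions.

    The per-class training count is ``round half-up(n_class * fraction)``.
    Raises if any class would be absent from either part.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    train_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    for cls in pd.unique(labels):
        pos = np.flatnonzero(labels == cls)
        n_train = int(np.floor(len(pos) * train_fraction + 0.5))
        if n_train < 1 or n_train >= len(pos):
            raise ValueError(
                f"class {cls!r} (n={len(pos)}) cannot appear in both parts at "
                f"fraction {train_fraction}"
            )
        perm = rng.permutation(pos)
        train_idx.append(perm[:n_train])
        val_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray,
                     seed: int = 0):
    """Fit the classifier on normalized training data.

    Returns ``(score_fn, converged)`` where ``score_fn`` maps feature
    rows to positive-class probabilities.  Non-convergence is flagged,
    not fatal.
    """
    if len(np.unique(y)) != 2:
        raise ValueError("training labels must contain both classes")
    if spec.kind == "logistic_regression":
        # L2 ridge is sklearn's default penalty
        model = LogisticRegression(C=spec.l2_logistic_C, solver="lbfgs",
                                   max_iter=spec.max_iter)
    else:
        model = MLPClassifier(hidden_layer_sizes=(spec.hidden_units,),
                              activation="logistic", solver="lbfgs",
                              alpha=spec.nn_alpha, max_iter=spec.max_iter,
                              random_state=seed)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X, y)
            logger.warning("%s did not converge within %d iterations",
                           spec.kind, spec.max_iter)

    positive = model.classes_[1]

    def score_fn(rows: np.ndarray) -> np.ndarray:
        proba = model.predict_proba(rows)
        return proba[:, list(model.classes_).index(positive)]

    return score_fn, converged


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Mann-Whitney AUC: the fraction of (positive, negative) pairs in
    which the positive scores higher, ties counted 1/2.  Equals the
    trapezoidal area under the empirical ROC curve."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def operating_point(scores: Sequence[float], labels: Sequence) -> tuple[float, float]:
    """(sensitivity, specificity) at the threshold maximizing Youden's
    J = sensitivity + specificity - 1; ties favour higher sensitivity."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # candidate rules: score >= t for each observed score, plus "predict none"
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    best = (-np.inf, -np.inf)  # (J, sensitivity)
    best_point = (0.0, 0.0)
    for t in thresholds:
        pred = scores >= t
        sens = float((pred & (labels == 1)).sum() / n_pos)
        spec = float((~pred & (labels == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        if (j, sens) > best:
            best = (j, sens)
            best_point = (sens, spec)
    return best_point


def _binary_labels(labels: Sequence, class_pair: tuple[str, str]) -> np.ndarray:
    """Encode the second class of the pair (the disease group) as 1."""
    labels = np.asarray(labels)
    return (labels == class_pair[1]).astype(int)


def repeated_split_eval(table: FeatureTable, spec: ClassifierSpec,
                        class_pair: tuple[str, str], repeats: int = 100,
                        train_fraction: float = 0.7,
                        master_seed: int = 0) -> SplitEvalResult:
    """Run the full repeated-split evaluation of one classifier spec on
    one class pair.  Fully reproducible from ``master_seed``."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    sub = table.subset_classes(class_pair)
    y_all = _binary_labels(sub.labels, class_pair)
    if y_all.sum() == 0 or y_all.sum() == len(y_all):
        raise ValueError(f"both classes of {class_pair} must be present")
    X_all = sub.features[list(spec.features)]

    children = np.random.SeedSequence(master_seed).spawn(repeats)
    rows = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        clf_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            train_idx, val_idx = stratified_split(y_all, train_fraction, rng)
            norm = Normalizer.fit(X_all.iloc[train_idx])
            X_train = norm.transform(X_all.iloc[train_idx]).to_numpy()
            X_val = norm.transform(X_all.iloc[val_idx]).to_numpy()
            score_fn, converged = train_classifier(spec, X_train, y_all[train_idx], seed=clf_seed)
            val_scores = score_fn(X_val)
            auc = roc_auc(val_scores, y_all[val_idx])
            sens, specificity = operating_point(val_scores, y_all[val_idx])
        except Exception as exc:
            raise RuntimeError(f"repeat {r} failed: {exc}") from exc
        rows.append((r, auc, sens, specificity, converged))
        logger.info("repeat %d: AUC=%.3f sens=%.3f spec=%.3f", r, auc, sens, specificity)

    per_repeat = pd.DataFrame(rows, columns=["repeat", "auc", "sensitivity",
                                             "specificity", "converged"])
    return SplitEvalResult(spec=spec, class_pair=tuple(class_pair),
                           per_repeat=per_repeat, master_seed=master_seed)


def group_ttests(table: FeatureTable, features: Sequence[str]) -> pd.DataFrame:
    """Per-feature group means +/- SD and equal-variance two-sample
    t-tests (normal vs subKC, normal vs KC); alpha = 0.05, no
    multiplicity correction."""
    for g in GROUPS:
        if g not in set(table.labels):
            raise ValueError(f"group {g!r} absent from table")
    by_group = {g: table.df[table.df["group"] == g] for g in GROUPS}
    rows = []
    for f in features:
        rec: dict[str, float | str] = {"feature": f}
        for g in GROUPS:
            vals = by_group[g][f]
            rec[f"mean_{g}"] = float(vals.mean())
            rec[f"sd_{g}"] = float(vals.std(ddof=1))
        for g in ("subKC", "KC"):
            t, p = stats.ttest_ind(by_group["normal"][f], by_group[g][f], equal_var=True)
            rec[f"t_normal_vs_{g}"] = float(t)
            rec[f"p_normal_vs_{g}"] = float(p)
            rec[f"significant_normal_vs_{g}"] = bool(p < 0.05)
        rows.append(rec)
    return pd.DataFrame(rows)
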