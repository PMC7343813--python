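"""Hierarchical PCA-LDA classification with cross-validated PC selection.

Spectra (difference, reconstructed, or baseline-corrected raw) are
mean-centered, projected onto a truncated principal-component basis to
separate structured variation from noise, and classified with linear
discriminant analysis under equal class priors (training sets are balanced
by construction).  Stage 1 separates growth habits (tree vs non-tree);
stage 2 fits independent genus models inside each habit group, each with
its own train/test split and tenfold cross-validation for the PC count.

Confusion matrices follow the convention rows = predicted class, columns =
real class, and per-class metrics are one-vs-rest: for class c,
TP = counts[c, c], FN = column c minus TP, FP = row c minus TP,
TN = the remainder; sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/total, precision = TP/(TP+FP), reported in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from ._utils import round_half_up

__all__ = [
    "SplitSpec",
    "split_train_test",
    "PcaModel",
    "fit_pca",
    "PcaLdaModel",
    "fit_pca_lda",
    "predict",
    "choose_n_pcs",
    "ConfusionMatrix",
    "confusion_matrix",
    "class_metrics",
    "ClassifyConfig",
    "StageResult",
    "HierarchicalResult",
    "hierarchical_classify",
    "compare_input_variants",
    "METRIC_NAMES",
]

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "precision")


# ---------------------------------------------------------------------------
# Train/test split


@dataclass
class SplitSpec:
    """Equal-per-class stratified split; the remainder is the test set."""

    per_class_train_n: int
    seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray


def split_train_test(labels: Sequence, per_class_train_n: Optional[int] = None,
                     seed: int = 0) -> SplitSpec:
    """Draw an equal-sized training set per class, without replacement.

    When ``per_class_train_n`` is None it defaults to floor(0.6 * size of
    the smallest class) -- the balanced-training recipe.  Deterministic
    under the seed; errors name any class that is too small.
    """
    labels_arr = np.asarray(labels, dtype=object)
    classes = sorted(set(labels_arr.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to split")
    sizes = {c: int(np.sum(labels_arr == c)) for c in classes}
    if per_class_train_n is None:
        per_class_train_n = int(np.floor(0.6 * min(sizes.values())))
        if per_class_train_n < 1:
            raise ValueError("smallest class too small for a 60% training draw")
    rng = np.random.default_rng(seed)
    train: List[int] = []
    for c in classes:
        idx = np.flatnonzero(labels_arr == c)
        if idx.size < per_class_train_n:
            raise ValueError(
                f"class {c!r} has {idx.size} spectra, fewer than per_class_train_n={per_class_train_n}")
        chosen = rng.permutation(idx)[:per_class_train_n]
        train.extend(int(i) for i in chosen)
    train_idx = np.asarray(sorted(train))
    mask = np.ones(labels_arr.size, dtype=bool)
    mask[train_idx] = False
    test_idx = np.flatnonzero(mask)
    return SplitSpec(per_class_train_n=per_class_train_n, seed=seed,
                     train_indices=train_idx, test_indices=test_idx)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    mean_: np.ndarray
    components_: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_ratio_: np.ndarray

    def transform(self, X: np.ndarray, n_components: Optional[int] = None) -> np.ndarray:
        comps = self.components_ if n_components is None else self.components_[:n_components]
        return (np.asarray(X, dtype=float) - self.mean_) @ comps.T


def fit_pca(train_matrix: np.ndarray, n_components: Optional[int] = None) -> PcaModel:
    """Mean-centered PCA by SVD with a deterministic sign convention: each
    component is flipped so its largest-magnitude loading is positive."""
    X = np.asarray(train_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 training spectra")
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PcaModel(mean_=pca.mean_, components_=comps,
                    explained_variance_ratio_=pca.explained_variance_ratio_.copy())


# ---------------------------------------------------------------------------
# LDA on PC scores


@dataclass
class PcaLdaModel:
    pca: PcaModel
    lda: LinearDiscriminantAnalysis
    class_labels: List[str]
    n_pcs: int
    ld_signs: np.ndarray  # orientation of the LD axes

    @property
    def n_ld_directions(self) -> int:
        return self.lda.scalings_.shape[1] if hasattr(self.lda, "scalings_") else len(self.class_labels) - 1


def _fit_lda(scores: np.ndarray, labels: Sequence) -> Tuple[LinearDiscriminantAnalysis, List[str], np.ndarray]:
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    priors = np.full(len(classes), 1.0 / len(classes))
    lda = LinearDiscriminantAnalysis(priors=priors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # collinearity warnings on tiny fixtures
        lda.fit(scores, np.asarray(labels, dtype=object))
    # orientation convention: the lexicographically-first class has a
    # non-positive mean score on every LD axis (score-plot reproducibility)
    first_mask = np.asarray(labels, dtype=object) == classes[0]
    ld = lda.transform(scores)
    n_dir = ld.shape[1]
    signs = np.ones(n_dir)
    mean_first = ld[first_mask].mean(axis=0)
    signs[mean_first > 0] = -1.0
    return lda, classes, signs


def fit_pca_lda(train_X: np.ndarray, train_labels: Sequence, n_pcs: int) -> PcaLdaModel:
    """Fit the PCA basis on the training matrix, truncate to ``n_pcs``
    scores and fit the LDA on those."""
    n_pcs = int(n_pcs)
    max_pcs = min(np.asarray(train_X).shape[0] - 1, np.asarray(train_X).shape[1])
    if not (1 <= n_pcs <= max_pcs):
        raise ValueError(f"n_pcs must be in [1, {max_pcs}], got {n_pcs}")
    pca = fit_pca(train_X, n_components=n_pcs)
    scores = pca.transform(train_X)
    lda, classes, signs = _fit_lda(scores, train_labels)
    return PcaLdaModel(pca=pca, lda=lda, class_labels=classes, n_pcs=n_pcs, ld_signs=signs)


def predict(model: PcaLdaModel, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Class labels and (orientation-fixed) LD scores for new spectra."""
    scores = model.pca.transform(X, n_components=model.n_pcs)
    labels = model.lda.predict(scores)
    ld = model.lda.transform(scores) * model.ld_signs
    return labels, ld


# ---------------------------------------------------------------------------
# PC-count selection by tenfold cross-validation


def choose_n_pcs(train_X: np.ndarray, train_labels: Sequence,
                 candidate_range: Sequence[int] = tuple(range(2, 16)),
                 folds: int = 10, seed: int = 0,
                 rule: str = "one_se") -> Tuple[int, pd.DataFrame]:
    """Stratified k-fold CV over candidate PC counts, PCA refit per fold
    (no leakage of held-out spectra into the basis).

    rule='one_se' returns the smallest candidate whose mean held-out
    accuracy is within one standard error of the best; rule='max' returns
    the accuracy-maximizing candidate (smallest on ties).
    """
    candidates = sorted(int(c) for c in candidate_range)
    if not candidates:
        raise ValueError("empty candidate_range")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if rule not in ("one_se", "max"):
        raise ValueError(f"unknown rule {rule!r}")
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_labels, dtype=object)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class ({counts.min()} spectra) cannot populate {folds} stratified folds")
    if len(candidates) == 1:
        return candidates[0], pd.DataFrame(
            {"n_pcs": candidates, "mean_accuracy": [np.nan], "se_accuracy": [np.nan]})

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = np.zeros((len(candidates), folds))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        n_max = min(max(candidates), tr.size - 1, X.shape[1])
        pca = fit_pca(X[tr], n_components=n_max)
        tr_scores_full = pca.transform(X[tr])
        te_scores_full = pca.transform(X[te])
        for ci, n in enumerate(candidates):
            if n > n_max:
                acc[ci, f] = np.nan
                continue
            lda, _, _ = _fit_lda(tr_scores_full[:, :n], y[tr])
            acc[ci, f] = float(np.mean(lda.predict(te_scores_full[:, :n]) == y[te]))
    mean_acc = np.nanmean(acc, axis=1)
    se_acc = np.nanstd(acc, axis=1, ddof=1) / np.sqrt(folds)
    table = pd.DataFrame({"n_pcs": candidates, "mean_accuracy": mean_acc, "se_accuracy": se_acc})
    best = int(np.nanargmax(mean_acc))
    if rule == "max":
        chosen = candidates[best]
    else:
        floor = mean_acc[best] - se_acc[best]
        chosen = next(c for c, m in zip(candidates, mean_acc) if m >= floor)
    return int(chosen), table


# ---------------------------------------------------------------------------
# Confusion matrix and one-vs-rest metrics


@dataclass
class ConfusionMatrix:
    """counts[predicted, real] with a fixed class order."""

    counts: np.ndarray
    class_labels: List[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.class_labels)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over class_labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        """Overall (micro) accuracy in percent."""
        return 100.0 * float(np.trace(self.counts)) / self.total

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"{c}, predicted" for c in self.class_labels],
            columns=[f"{c}, real" for c in self.class_labels],
        )


def confusion_matrix(true_labels: Sequence, predicted_labels: Sequence,
                     class_order: Sequence[str]) -> ConfusionMatrix:
    true_arr = np.asarray(true_labels, dtype=object)
    pred_arr = np.asarray(predicted_labels, dtype=object)
    if true_arr.size != pred_arr.size:
        raise ValueError("label vectors must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_arr, pred_arr):
        if t not in index:
            raise ValueError(f"true label {t!r} not in class_order")
        if p not in index:
            raise ValueError(f"predicted label {p!r} not in class_order")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts=counts, class_labels=list(class_order))


def class_metrics(cm: ConfusionMatrix, rounded: bool = False) -> pd.DataFrame:
    """One-vs-rest sensitivity/specificity/accuracy/precision per class, in
    percent.  ``rounded=True`` applies the report convention (half-up to one
    decimal); unrounded values are exact ratios.  Precision is NaN when the
    class was never predicted (TP+FP = 0)."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    for i, cls in enumerate(cm.class_labels):
        tp = counts[i, i]
        fn = counts[:, i].sum() - tp
        fp = counts[i, :].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            raise ValueError(f"real class {cls!r} has no test spectra")
        sens = 100.0 * tp / (tp + fn)
        spec = 100.0 * tn / (tn + fp) if tn + fp > 0 else np.nan
        acc = 100.0 * (tp + tn) / total
        prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else np.nan
        rows[cls] = {"sensitivity": sens, "specificity": spec,
                     "accuracy": acc, "precision": prec}
    df = pd.DataFrame(rows).T.loc[list(cm.class_labels), list(METRIC_NAMES)]
    if rounded:
        df = df.map(lambda v: np.nan if pd.isna(v) else round_half_up(v, 1))
    return df


# ---------------------------------------------------------------------------
# Hierarchical scheme


@dataclass
class ClassifyConfig:
    per_class_train_n: Optional[int] = None  # None -> floor(0.6 * smallest class)
    folds: int = 10
    seed: int = 0
    n_pcs: Optional[int] = None  # None -> choose by CV
    candidate_range: Tuple[int, ...] = tuple(range(2, 16))
    rule: str = "one_se"


@dataclass
class StageResult:
    name: str
    model: PcaLdaModel
    split: SplitSpec
    cm: ConfusionMatrix
    metrics: pd.DataFrame
    n_pcs: int
    cv_table: Optional[pd.DataFrame]

    @property
    def accuracy(self) -> float:
        return self.cm.accuracy()


def _run_stage(name: str, X: np.ndarray, target: np.ndarray, strata: np.ndarray,
               config: ClassifyConfig) -> StageResult:
    split = split_train_test(strata, config.per_class_train_n, seed=config.seed)
    Xtr, ytr = X[split.train_indices], target[split.train_indices]
    Xte, yte = X[split.test_indices], target[split.test_indices]
    cv_table = None
    n_pcs = config.n_pcs
    if n_pcs is None:
        max_pcs = min(Xtr.shape[0] - 1, Xtr.shape[1])
        candidates = [c for c in config.candidate_range if c <= max_pcs]
        n_pcs, cv_table = choose_n_pcs(Xtr, ytr, candidates, folds=config.folds,
                                       seed=config.seed, rule=config.rule)
    model = fit_pca_lda(Xtr, ytr, n_pcs)
    pred, _ = predict(model, Xte)
    cm = confusion_matrix(yte, pred, model.class_labels)
    return StageResult(name=name, model=model, split=split, cm=cm,
                       metrics=class_metrics(cm), n_pcs=n_pcs, cv_table=cv_table)


@dataclass
class HierarchicalResult:
    habit: StageResult
    tree_genus: StageResult
    nontree_genus: StageResult

    def stages(self) -> List[StageResult]:
        return [self.habit, self.tree_genus, self.nontree_genus]

    def averaged_metrics(self) -> pd.DataFrame:
        """Per-stage mean of the one-vs-rest metrics (the comparison table
        used to contrast input variants)."""
        rows = {s.name: s.metrics.mean(axis=0) for s in self.stages()}
        return pd.DataFrame(rows).T


def hierarchical_classify(X: np.ndarray, genus_labels: Sequence, habit_labels: Sequence,
                          config: Optional[ClassifyConfig] = None,
                          n_pcs_per_stage: Optional[Dict[str, Optional[int]]] = None
                          ) -> HierarchicalResult:
    """Two-stage scheme: habit over everything, then genus within habit.

    Stage 1 trains on an equal-per-genus draw (so both habits are balanced
    at the genus level) and classifies tree vs non-tree.  Stage 2 draws
    independent splits inside each habit group and classifies genera.  PC
    counts are cross-validated per stage unless pinned via ``config.n_pcs``
    or ``n_pcs_per_stage`` (the replication recipe pins 10/13/11).
    """
    config = ClassifyConfig() if config is None else config
    X = np.asarray(X, dtype=float)
    genus = np.asarray(genus_labels, dtype=object)
    habit = np.asarray(habit_labels, dtype=object)
    if not (X.shape[0] == genus.size == habit.size):
        raise ValueError("feature matrix and label vectors disagree in length")
    if any(g is None for g in genus) or any(h is None for h in habit):
        raise ValueError("hierarchical classification requires genus and habit labels")

    pins = {"habit": config.n_pcs, "tree_genus": config.n_pcs, "nontree_genus": config.n_pcs}
    if n_pcs_per_stage:
        pins.update(n_pcs_per_stage)

    def stage_config(n_pcs):
        return ClassifyConfig(per_class_train_n=config.per_class_train_n, folds=config.folds,
                              seed=config.seed, n_pcs=n_pcs,
                              candidate_range=config.candidate_range, rule=config.rule)

    habit_res = _run_stage("habit", X, habit, genus, stage_config(pins["habit"]))
    habit_names = sorted(set(habit.tolist()))
    if len(habit_names) != 2:
        raise ValueError(f"expected exactly 2 habit labels, got {habit_names}")
    groups = {}
    for stage_name, habit_value in (("tree_genus", "tree"), ("nontree_genus", "non_tree")):
        value = habit_value if habit_value in habit_names else (
            habit_names[1] if stage_name == "tree_genus" else habit_names[0])
        mask = habit == value
        groups[stage_name] = _run_stage(stage_name, X[mask], genus[mask], genus[mask],
                                        stage_config(pins[stage_name]))
    return HierarchicalResult(habit=habit_res, tree_genus=groups["tree_genus"],
                              nontree_genus=groups["nontree_genus"])


def compare_input_variants(variants: Dict[str, np.ndarray], genus_labels: Sequence,
                           habit_labels: Sequence,
                           config: Optional[ClassifyConfig] = None
                           ) -> Tuple[Dict[str, HierarchicalResult], pd.DataFrame]:
    """Run the full hierarchy on several input representations of the same
    particles (difference / reconstructed / raw) and tabulate the averaged
    metrics side by side."""
    results = {name: hierarchical_classify(Xv, genus_labels, habit_labels, config)
               for name, Xv in variants.items()}
    frames = []
    for name, res in results.items():
        df = res.averaged_metrics()
        df.insert(0, "input", name)
        frames.append(df.reset_index(names="stage"))
    return results, pd.concat(frames, ignore_index=True)
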