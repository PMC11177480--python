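"""Integrated case/control classification from multi-block cfDNA features.

Three feature blocks — promoter/TSS methylation betas, per-bin log2 copy
ratios, and inferred immune-cell proportions — are assembled per sample.
The high-dimensional blocks are centered, scaled, and reduced by PCA to the
minimal number of components reaching a cumulative explained-variance
target (95% by default), with all statistics fitted on training samples
only.  One cell type is dropped from the proportions block to limit
collinearity (proportions sum to one).  Classifiers are a random forest and
a radial-kernel SVM tuned by stratified 5-fold cross-validation maximizing
AUC; performance is reported as ROC/AUC on the held-out test set and
per-feature permutation importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .errors import ParameterError, ValidationError


def split_cohort(
    labels: pd.Series, train_fraction: float = 0.25, seed: int = 0, stratified: bool = True
):
    """Split sample labels into disjoint, exhaustive train/test index sets.

    The default ``train_fraction=0.25`` is a 1:3 train:test split.  With
    ``stratified`` the class proportions are preserved within rounding; an
    empty class on either side is an error.
    """
    labels = pd.Series(labels)
    if not 0 < train_fraction < 1:
        raise ParameterError("train_fraction must lie in (0, 1)")
    idx = np.arange(len(labels))
    strat = labels.to_numpy() if stratified else None
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=strat, shuffle=True
    )
    for side, name in ((train_idx, "train"), (test_idx, "test")):
        present = set(labels.iloc[side])
        if present != set(labels):
            raise ParameterError(f"{name} split lost a class: {set(labels) - present}")
    return np.sort(train_idx), np.sort(test_idx)


@dataclass
class StandardizeTransform:
    """Per-feature center/scale statistics fitted on training data only."""

    center: np.ndarray
    scale: np.ndarray  # 1.0 for zero-variance features


def fit_standardize(train_block: pd.DataFrame | np.ndarray) -> StandardizeTransform:
    """Fit centering/scaling (sample SD, ddof=1); zero-variance features get
    scale 1 so they map to exact zeros."""
    X = np.asarray(train_block, dtype=np.float64)
    if X.shape[0] < 2:
        raise ParameterError("standardization needs >= 2 training samples")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    return StandardizeTransform(center=center, scale=scale)


def apply_standardize(transform: StandardizeTransform, block: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = np.asarray(block, dtype=np.float64)
    return (X - transform.center) / transform.scale


@dataclass
class PCATransform:
    """PCA loadings retaining the minimal prefix of components reaching the
    explained-variance target; sign fixed so each component's
    largest-magnitude loading is positive."""

    components: np.ndarray  # n_components x n_features
    n_components: int
    explained_variance_ratio: np.ndarray


def pca_reduce(train_block: np.ndarray, variance_target: float = 0.95) -> tuple[PCATransform, np.ndarray]:
    """Fit PCA on standardized training data and reduce it.

    Components are ordered by explained variance; the retained count is the
    smallest ``m`` with cumulative explained-variance ratio >= the target,
    capped at the matrix rank.  Returns the transform and the reduced
    training matrix.
    """
    if not 0 < variance_target <= 1:
        raise ParameterError("variance_target must lie in (0, 1]")
    X = np.asarray(train_block, dtype=np.float64)
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValidationError("training block has zero variance")
    evr = var / total
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    m = int(np.searchsorted(np.cumsum(evr), variance_target - 1e-12) + 1)
    m = min(m, rank)
    components = vt[:m]
    # sign convention: largest-|loading| entry of each component positive
    for i in range(m):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    transform = PCATransform(components=components, n_components=m, explained_variance_ratio=evr[:m])
    return transform, apply_pca(transform, X)


def apply_pca(transform: PCATransform, block: np.ndarray) -> np.ndarray:
    return np.asarray(block, dtype=np.float64) @ transform.components.T


def assemble_features(
    blocks: dict[str, pd.DataFrame],
    include: tuple[str, ...] = ("meth", "cnv", "props"),
    drop_cell_type: str | None = None,
) -> pd.DataFrame:
    """Concatenate the selected preprocessed blocks column-wise.

    All blocks must share the same sample index in the same order.
    ``drop_cell_type`` removes one column from the ``props`` block to limit
    collinearity (compositions sum to one).
    """
    chosen = []
    index = None
    for name in include:
        if name not in blocks:
            raise ParameterError(f"unknown block {name!r}")
        block = blocks[name]
        if index is None:
            index = block.index
        elif not block.index.equals(index):
            raise ValidationError(f"block {name!r} has inconsistent samples")
        if name == "props" and drop_cell_type is not None:
            if drop_cell_type not in block.columns:
                raise ParameterError(f"cell type {drop_cell_type!r} not in proportions block")
            block = block.drop(columns=[drop_cell_type])
        chosen.append(block.add_prefix(f"{name}:"))
    return pd.concat(chosen, axis=1)


_DEFAULT_GRIDS = {
    "random_forest": {"max_features": ["sqrt", 0.5]},
    "svm_radial": {"C": [0.1, 1.0, 10.0]},
}


def train_classifier(
    features: pd.DataFrame | np.ndarray,
    labels: pd.Series | np.ndarray,
    model: str = "random_forest",
    cv_folds: int = 5,
    seed: int = 0,
    param_grid: dict | None = None,
):
    """Train a classifier with stratified CV hyperparameter selection.

    ``model`` is ``random_forest`` or ``svm_radial`` (radial-basis kernel).
    Hyperparameters are chosen by ``cv_folds``-fold stratified CV maximizing
    AUC, then the model is refitted on all training data.  Returns
    ``(fitted_estimator, cv_results)`` where ``cv_results`` holds the best
    CV AUC, chosen parameters, and fold assignment seed.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("labels contain a single class")
    if counts.min() < cv_folds:
        raise ParameterError(f"each class needs >= cv_folds={cv_folds} samples")
    if model == "random_forest":
        base = RandomForestClassifier(n_estimators=300, random_state=seed)
    elif model == "svm_radial":
        base = SVC(kernel="rbf", gamma="scale", random_state=seed)
    else:
        raise ParameterError(f"unknown model {model!r}")
    grid = param_grid if param_grid is not None else _DEFAULT_GRIDS[model]
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid, scoring="roc_auc", cv=cv, refit=True, n_jobs=1)
    search.fit(X, y)
    cv_results = {
        "cv_auc": float(search.best_score_),
        "best_params": search.best_params_,
        "seed": seed,
        "model": model,
    }
    return search.best_estimator_, cv_results


def predict_scores(model, features) -> np.ndarray:
    """Continuous case scores: positive-class probability when available,
    otherwise the decision function."""
    X = np.asarray(features, dtype=np.float64)
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, -1]
    return model.decision_function(X)


def auc_mann_whitney(y_true, scores) -> float:
    """AUC as the normalized Mann-Whitney U statistic with midrank ties."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("AUC needs exactly two classes in the test set")
    pos = y == classes[-1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate_roc(model, test_features, test_labels) -> tuple[pd.DataFrame, float]:
    """ROC points at every distinct score threshold plus the AUC.

    The positive class is the lexicographically larger label.  Returns
    ``(roc_frame, auc)`` with columns ``threshold, fpr, tpr``.
    """
    y = np.asarray(test_labels)
    scores = predict_scores(model, test_features)
    auc = auc_mann_whitney(y, scores)
    classes = np.unique(y)
    pos = y == classes[-1]
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    for t in thresholds:
        called = scores >= t
        tpr = called[pos].mean() if pos.any() else np.nan
        fpr = called[~pos].mean() if (~pos).any() else np.nan
        rows.append((t, fpr, tpr))
    return pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"]), auc


def feature_importance(
    model, features: pd.DataFrame, labels, n_repeats: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Permutation importance: mean AUC drop when a feature column is shuffled.

    Model-agnostic, so random-forest and SVM importances are comparable.
    Features are returned in descending importance, ties broken by column
    order.
    """
    X = features.to_numpy(np.float64) if isinstance(features, pd.DataFrame) else np.asarray(features)
    names = list(features.columns) if isinstance(features, pd.DataFrame) else [
        f"f{i}" for i in range(X.shape[1])
    ]
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    baseline = auc_mann_whitney(y, predict_scores(model, X))
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        vals = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            vals.append(baseline - auc_mann_whitney(y, predict_scores(model, Xp)))
        drops[j] = float(np.mean(vals))
    order = np.argsort(-drops, kind="stable")
    return pd.DataFrame(
        {"feature": [names[j] for j in order], "importance": drops[order]}
    ).reset_index(drop=True)


@dataclass
class PreparedFeatures:
    """Train/test matrices after leakage-free preprocessing of each block."""

    train: pd.DataFrame
    test: pd.DataFrame
    transforms: dict = field(default_factory=dict)


def prepare_feature_blocks(
    blocks: dict[str, pd.DataFrame],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    include: tuple[str, ...] = ("meth", "cnv", "props"),
    variance_target: float = 0.95,
    pca_blocks: tuple[str, ...] = ("meth", "cnv"),
    drop_cell_type: str | None = None,
) -> PreparedFeatures:
    """Standardize and PCA-reduce blocks using training statistics only.

    ``pca_blocks`` lists the high-dimensional blocks that are reduced; the
    proportions block is standardized but kept in its original columns.
    """
    train_parts, test_parts, transforms = {}, {}, {}
    for name in include:
        block = blocks[name]
        if name == "props" and drop_cell_type is not None:
            block = block.drop(columns=[drop_cell_type])
        tr, te = block.iloc[train_idx], block.iloc[test_idx]
        std = fit_standardize(tr)
        tr_s, te_s = apply_standardize(std, tr), apply_standardize(std, te)
        if name in pca_blocks:
            pca, tr_r = pca_reduce(tr_s, variance_target)
            te_r = apply_pca(pca, te_s)
            cols = [f"{name}_pc{i+1}" for i in range(pca.n_components)]
            transforms[name] = (std, pca)
        else:
            tr_r, te_r = tr_s, te_s
            cols = list(block.columns)
            transforms[name] = (std, None)
        train_parts[name] = pd.DataFrame(tr_r, index=block.index[train_idx], columns=cols)
        test_parts[name] = pd.DataFrame(te_r, index=block.index[test_idx], columns=cols)
    train = pd.concat([train_parts[n].add_prefix(f"{n}:") for n in include], axis=1)
    test = pd.concat([test_parts[n].add_prefix(f"{n}:") for n in include], axis=1)
    return PreparedFeatures(train=train, test=test, transforms=transforms)
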