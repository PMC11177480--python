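"""Tissue-of-origin and immune-cell deconvolution of cfDNA methylomes.

A reference matrix gives the methylation level of each marker site (or
marker region) in each candidate cell type.  Because shallow cfDNA data
rarely cover every marker site, sites are aggregated into *mega sites*:
hierarchical clustering of the reference profiles (Euclidean distance,
complete linkage by default), cut into ``k`` groups, singleton groups
dropped, and each retained group's reads pooled.  Remaining missing values
are imputed by k-nearest-neighbour regression over features.  Mixture
proportions are then estimated by least squares constrained to the
probability simplex:

    min_w || R w - y ||^2   s.t.  w >= 0,  sum(w) = 1.

The same code path serves the tissue-of-origin mode (marker regions) and
the immune mode (mega sites built from reference CpGs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import pdist
from sklearn.impute import KNNImputer

from .errors import ParameterError, ValidationError
from .methylome import summarize_regions

# weight of the sum-to-one row in the augmented least-squares system
_SIMPLEX_WEIGHT = 100.0


def marker_region_levels(calls: pd.DataFrame, markers: pd.DataFrame) -> pd.Series:
    """Pooled methylation proportion per marker region.

    ``markers`` is a region frame (chrom, start0, end0, name, ...).  All
    covered CpGs inside a region contribute reads; a region with no covered
    site is NaN.  Index is the marker name.
    """
    summary = summarize_regions(calls, markers)
    return pd.Series(summary["level"].to_numpy(), index=summary["name"].to_numpy(), name="level")


@dataclass
class MegaSiteSet:
    """Groups of reference sites aggregated to overcome coverage sparsity.

    ``groups`` maps a mega-site label to the member site identifiers (index
    labels of the reference matrix); every retained group has >= 2 members.
    ``reference`` holds the aggregated reference level (unweighted mean of
    member sites) per mega site and cell type.
    """

    groups: dict[str, list]
    reference: pd.DataFrame  # mega sites x cell types

    @property
    def sizes(self) -> pd.Series:
        return pd.Series({g: len(m) for g, m in self.groups.items()}, name="n_sites")


def build_mega_sites(
    reference_matrix: pd.DataFrame,
    k: int = 32,
    metric: str = "euclidean",
    method: str = "complete",
) -> MegaSiteSet:
    """Cluster reference sites into ``k`` dendrogram groups and drop singletons.

    Sites (rows of ``reference_matrix``, one column per cell type) are
    clustered on their cell-type profiles; the dendrogram is cut into ``k``
    groups, groups of size 1 are removed, and each retained group's
    reference value per cell type is the unweighted mean of its member
    sites.
    """
    if reference_matrix.isna().any().any():
        raise ValidationError("reference matrix must not contain missing values")
    n_sites = len(reference_matrix)
    if k > n_sites:
        raise ParameterError(f"k={k} exceeds the number of sites ({n_sites})")
    if k < 1:
        raise ParameterError("k must be >= 1")
    z = linkage(pdist(reference_matrix.to_numpy(np.float64), metric=metric), method=method)
    assignment = fcluster(z, t=k, criterion="maxclust")
    groups: dict[str, list] = {}
    rows = {}
    for gid in np.unique(assignment):
        members = reference_matrix.index[assignment == gid].tolist()
        if len(members) < 2:
            continue
        label = f"mega_{gid}"
        groups[label] = members
        rows[label] = reference_matrix.loc[members].mean(axis=0)
    if not groups:
        warnings.warn("all clusters are singletons; mega-site set is empty", stacklevel=2)
        reference = pd.DataFrame(columns=reference_matrix.columns)
    else:
        reference = pd.DataFrame(rows).T
        reference.columns = reference_matrix.columns
    return MegaSiteSet(groups=groups, reference=reference)


def aggregate_sample_to_mega_sites(calls: pd.DataFrame, mega_sites: MegaSiteSet) -> pd.Series:
    """Pooled methylated-read proportion per mega site for one sample.

    Member sites are identified by ``(chrom, pos0)`` labels of the reference
    matrix the mega sites were built from; a mega site with no covered
    member is NaN.
    """
    indexed = calls.set_index(["chrom", "pos0"])[["n_meth", "n_unmeth"]]
    indexed = indexed.groupby(level=[0, 1]).sum()  # pool strands if both present
    values = {}
    for label, members in mega_sites.groups.items():
        present = [m for m in members if m in indexed.index]
        if not present:
            values[label] = np.nan
            continue
        sub = indexed.loc[present]
        total = int(sub["n_meth"].sum() + sub["n_unmeth"].sum())
        values[label] = float(sub["n_meth"].sum() / total) if total else np.nan
    return pd.Series(values, name="level")


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """k-NN imputation of a features x samples matrix.

    Each missing entry is replaced by the mean of the sample's values at the
    ``k`` nearest features (Euclidean distance over jointly observed
    samples); a feature observed nowhere falls back to the per-sample mean.
    A matrix with no missing entries is returned unchanged.
    """
    if matrix.isna().all().all():
        raise ValidationError("matrix is entirely missing")
    if not matrix.isna().any().any():
        return matrix.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform", keep_empty_features=True)
    # rows are features: a missing entry is filled from the k nearest feature
    # rows' values in the same sample column
    values = imputer.fit_transform(matrix.to_numpy(np.float64))
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


@dataclass
class MixtureEstimate:
    """Simplex-constrained mixture proportions for one sample."""

    proportions: pd.Series
    residual: float
    n_features_used: int


def deconvolve(
    sample_vector: pd.Series | np.ndarray,
    reference_matrix: pd.DataFrame,
    drop_missing: bool = True,
) -> MixtureEstimate:
    """Estimate cell-type proportions by simplex-constrained least squares.

    Solves ``min_w ||R w - y||^2`` subject to ``w >= 0`` and ``sum(w) = 1``
    via non-negative least squares on a system augmented with a heavily
    weighted sum-to-one row, followed by renormalization.  Features missing
    in ``y`` are dropped before solving when ``drop_missing``.
    """
    R = reference_matrix.to_numpy(np.float64)
    y = np.asarray(sample_vector, dtype=np.float64).ravel()
    if y.shape[0] != R.shape[0]:
        raise ValidationError("sample vector and reference matrix features differ")
    keep = ~np.isnan(y)
    if drop_missing:
        R, y = R[keep], y[keep]
    elif not keep.all():
        raise ValidationError("missing values present and drop_missing=False")
    n_used, n_types = R.shape
    if n_used < 2:
        raise ValidationError(f"only {n_used} usable features; need >= 2")
    if np.linalg.matrix_rank(R) < n_types:
        warnings.warn("reference matrix is rank deficient; proportions may be unstable", stacklevel=2)
    A = np.vstack([R, np.full((1, n_types), _SIMPLEX_WEIGHT)])
    b = np.concatenate([y, [_SIMPLEX_WEIGHT]])
    w, _ = nnls(A, b)
    s = w.sum()
    w = w / s if s > 0 else np.full(n_types, 1.0 / n_types)
    residual = float(np.linalg.norm(R @ w - y))
    return MixtureEstimate(
        proportions=pd.Series(w, index=reference_matrix.columns, name="proportion"),
        residual=residual,
        n_features_used=int(n_used),
    )


def deconvolve_cohort(
    sample_matrix: pd.DataFrame, reference_matrix: pd.DataFrame, knn_k: int | None = 10
) -> pd.DataFrame:
    """Deconvolve every sample (column) of a features x samples matrix.

    Missing values are imputed with :func:`knn_impute` first when ``knn_k``
    is given (features missing in every sample stay missing and are
    dropped per sample).  Returns samples x cell types proportions.
    """
    matrix = sample_matrix.loc[reference_matrix.index]
    if knn_k is not None and matrix.isna().any().any():
        observed_somewhere = ~matrix.isna().all(axis=1)
        matrix = matrix.copy()
        matrix.loc[observed_somewhere] = knn_impute(matrix.loc[observed_somewhere], k=knn_k)
    rows = {}
    for sample in matrix.columns:
        est = deconvolve(matrix[sample], reference_matrix)
        rows[sample] = est.proportions
    return pd.DataFrame(rows).T


def group_compare(
    values_group1, values_group2, test: str = "wilcoxon"
) -> float:
    """Two-sided comparison of a cell type's proportions between two groups.

    ``test="wilcoxon"`` runs the Wilcoxon rank-sum (Mann-Whitney) test,
    exact for group sizes <= 25 without ties, normal approximation with tie
    correction otherwise; ``test="ttest"`` runs Welch's t-test.  Returns 1.0
    when every value is identical across both groups.
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("each group needs >= 2 samples")
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0
    if test == "wilcoxon":
        pooled = np.concatenate([x, y])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (max(len(x), len(y)) <= 25 and not has_ties) else "asymptotic"
        return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method)[1])
    if test == "ttest":
        return float(stats.ttest_ind(x, y, equal_var=False)[1])
    raise ParameterError(f"unknown test {test!r}")
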