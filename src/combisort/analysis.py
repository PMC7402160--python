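"""Element-level combinatorial analytics over fitted expression values.

Given per-element prevalences and per-pair expression fits, this module
reproduces the downstream views of the combinatorial experiment: stacked
bin-fraction profiles with rank ordering, enhancer x promoter mean-expression
matrices, hierarchical clustering of those matrices, and PCA of elements in
the space spanned by their partners (centering only, on log expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import distance

from .estimation import BinRepresentatives, Prevalence, weighted_mean_expression
from .simulate import BIN_LABELS


@dataclass
class StackedFractions:
    """Per-element bin-share profiles, ranked by mean expression."""

    fractions: pd.DataFrame  # element x 4 bins; rows sum to 1
    weighted_mean: pd.Series
    rank: pd.Series  # 1 = highest expression; permutation of 1..n


def stacked_fractions(
    prevalence: Prevalence,
    reps: BinRepresentatives | None = None,
) -> StackedFractions:
    """Normalize each element's prevalence across bins and rank by the
    weighted-average expression (descending; ties broken lexicographically).

    Elements with zero total prevalence are excluded with a warning — they
    were never observed and have no profile.
    """
    x = prevalence.x
    totals = x.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} zero-prevalence element(s): "
            f"{list(x.index[zero])[:5]}",
            stacklevel=2,
        )
        x = x.loc[~zero]
        totals = totals.loc[~zero]
    fractions = x.div(totals, axis=0)
    reps = reps or BinRepresentatives.from_gates(prevalence.gates)
    wmean = pd.Series(
        {key: weighted_mean_expression(row.values, reps) for key, row in x.iterrows()},
        name="weighted_mean",
    )
    order = sorted(wmean.index, key=lambda k: (-wmean[k], str(k)))
    rank = pd.Series({k: i + 1 for i, k in enumerate(order)}, name="rank")
    return StackedFractions(fractions=fractions, weighted_mean=wmean, rank=rank)


@dataclass
class PairMatrix:
    """row-class x col-class mean-expression matrix with explicit missingness.

    ``values`` rows/columns are gene labels; cells never observed are NaN,
    never silently zero. ``native_mask`` marks cells whose row and column come
    from the same gene (the element pairing found in the genome).
    """

    values: pd.DataFrame
    row_class: str
    col_class: str
    native_mask: pd.DataFrame | None = None

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())


def pairwise_matrix(
    pair_values: pd.Series | Mapping[tuple[str, str], float],
    row_class: str = "enhancer",
    col_class: str = "promoter",
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> PairMatrix:
    """Pivot per-pair expression values into a row-gene x col-gene matrix.

    ``pair_values`` maps (row element, col element) to a fitted mu or
    weighted mean, already marginalized over the other classes. Labels may be
    part ids or gene names; a trailing ``_<class>`` suffix is stripped so rows
    and columns read as genes. Pairs absent from the input become NaN cells.
    """
    if not isinstance(pair_values, pd.Series):
        pair_values = pd.Series(dict(pair_values))
    if pair_values.empty:
        raise ValueError("no pair values supplied")

    def strip(label: str, cls: str) -> str:
        suffix = f"_{cls}"
        return label[: -len(suffix)] if label.endswith(suffix) else label

    idx = pd.MultiIndex.from_tuples(
        [(strip(str(r), row_class), strip(str(c), col_class)) for r, c in pair_values.index]
    )
    series = pd.Series(pair_values.values, index=idx)
    matrix = series.unstack()
    if row_labels is not None:
        matrix = matrix.reindex(index=[strip(str(r), row_class) for r in row_labels])
    if col_labels is not None:
        matrix = matrix.reindex(columns=[strip(str(c), col_class) for c in col_labels])
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    native = pd.DataFrame(
        np.equal.outer(matrix.index.to_numpy(), matrix.columns.to_numpy()),
        index=matrix.index,
        columns=matrix.columns,
    )
    return PairMatrix(values=matrix, row_class=row_class, col_class=col_class, native_mask=native)


@dataclass
class ClusterResult:
    """Deterministic dendrogram orders for a pair matrix."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def row_clusters(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.row_linkage, t=k, criterion="maxclust")
        return dict(zip(self.row_labels, (int(c) for c in flat)))


def _prepare_for_clustering(
    matrix: pd.DataFrame, log: bool, max_missing: float
) -> pd.DataFrame:
    m = matrix.copy()
    # lexicographic input order makes the linkage permutation-invariant
    m = m.sort_index(axis=0).sort_index(axis=1)
    row_ok = m.isna().mean(axis=1) <= max_missing
    m = m.loc[row_ok]
    col_ok = m.isna().mean(axis=0) <= max_missing
    m = m.loc[:, col_ok]
    if log:
        if (m <= 0).any().any():
            raise ValueError("log clustering requires positive expression values")
        m = np.log10(m)
    # residual missing cells take the column mean: neutral for distances
    return m.fillna(m.mean(axis=0))


def cluster_matrix(
    pm: PairMatrix,
    linkage: str = "average",
    metric: str = "euclidean",
    log: bool = True,
    max_missing: float = 0.5,
) -> ClusterResult:
    """Hierarchically cluster rows and columns of a pair matrix.

    Rows/columns with more than ``max_missing`` missing cells are dropped,
    remaining gaps are imputed with the column mean, and clustering runs on
    log10 expression (average linkage, Euclidean distance by default). Input
    is sorted lexicographically first so leaf order is reproducible and
    independent of row permutation.
    """
    m = _prepare_for_clustering(pm.values, log=log, max_missing=max_missing)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    row_link = hierarchy.linkage(distance.pdist(m.values, metric=metric), method=linkage)
    col_link = hierarchy.linkage(distance.pdist(m.values.T, metric=metric), method=linkage)
    row_order = [m.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [m.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        row_labels=list(m.index),
        col_labels=list(m.columns),
    )


@dataclass
class PcaResult:
    """Scores and explained-variance fractions from a centered SVD."""

    scores: pd.DataFrame  # samples x components
    explained_fraction: np.ndarray  # decreasing, sums to 1 over full rank
    components: pd.DataFrame  # components x features
    total_variance: float


def pca_elements(
    pm: PairMatrix,
    samples_axis: Literal["rows", "cols"] = "rows",
    log: bool = True,
    impute: bool = False,
) -> PcaResult:
    """PCA of elements (samples) in the expression space of their partners
    (features): feature-mean centering, no variance scaling, exact SVD.

    With ``impute=False`` any sample or feature containing missing cells is
    dropped rather than filled — absent pairs carry no expression to impute.
    ``samples_axis='cols'`` runs the dual analysis on the transpose.
    """
    matrix = pm.values if samples_axis == "rows" else pm.values.T
    m = matrix.copy()
    if impute:
        if log:
            m = np.log10(m.where(m > 0))
        m = m.fillna(m.mean(axis=0))
    else:
        m = m.dropna(axis=0, how="any")
        m = m.dropna(axis=1, how="any")
        if log:
            if (m.values <= 0).any():
                raise ValueError("log PCA requires positive expression values")
            m = np.log10(m)
    if m.shape[0] < 3:
        raise ValueError("need at least 3 complete samples for PCA")
    X = m.values - m.values.mean(axis=0, keepdims=True)
    if not np.any(X):
        raise ValueError("matrix has zero variance after centering")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| component positive, for reproducibility
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = S**2
    total = float(var.sum())
    comp_names = [f"PC{k + 1}" for k in range(len(S))]
    scores = pd.DataFrame(U * S, index=m.index, columns=comp_names)
    components = pd.DataFrame(Vt, index=comp_names, columns=m.columns)
    return PcaResult(
        scores=scores,
        explained_fraction=var / total,
        components=components,
        total_variance=total,
    )
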