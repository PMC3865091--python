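"""Signed weighted coexpression networks and module detection.

The chain is the standard signed-network construction: Pearson correlation
mapped to a signed similarity S = (1 + r) / 2, soft thresholding a = S^beta
with beta chosen as the lowest power whose degree distribution fits a
power law with signed R^2 > 0.8, the topological overlap matrix (TOM)

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

average-linkage clustering of the dissimilarity 1 - TOM, dynamic tree cut,
and module eigengenes (first principal component of each module's
standardized expression) correlated against sample traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import InputError, ParameterError
from .matrix import ExpressionMatrix
from .treecut import ModulePartition, cut_tree_dynamic

__all__ = [
    "signed_similarity",
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "select_soft_power",
    "SoftPowerReport",
    "topological_overlap",
    "tom_dissimilarity",
    "average_linkage",
    "dynamic_tree_cut",
    "module_eigengene",
    "eigengene_matrix",
    "EigengeneMatrix",
    "correlation_with_p",
    "module_trait_table",
    "feature_significance",
    "coexpression_modules",
]


def signed_similarity(m: ExpressionMatrix) -> pd.DataFrame:
    """Signed similarity S_ij = (1 + cor(x_i, x_j)) / 2 in [0, 1].

    Anti-correlated features map near 0, uncorrelated near 0.5, correlated
    near 1. Zero-variance features are excluded with a warning.
    """
    if m.n_samples < 4:
        raise InputError("similarity needs at least 4 samples")
    X = m.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(X, axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(m.values.index[~keep])
        warnings.warn(f"excluding {len(dropped)} zero-variance features: {dropped[:5]}")
        X = X[keep]
    idx = m.values.index[keep]
    if X.shape[0] == 1:
        return pd.DataFrame([[1.0]], index=idx, columns=idx)
    if np.isnan(X).any():
        # pairwise-complete Pearson when missing values survive filtering
        r = pd.DataFrame(X.T).corr().to_numpy()
    else:
        r = np.corrcoef(X)
    S = np.clip((1.0 + r) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=idx, columns=idx)


def adjacency(S: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Soft-thresholded adjacency a_ij = S_ij^beta with zero diagonal."""
    if beta < 1:
        raise ParameterError("beta must be >= 1")
    A = np.power(S.to_numpy(dtype=float), beta)
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=S.index, columns=S.columns)


def connectivity(A: pd.DataFrame) -> pd.Series:
    """Weighted degree k_i = sum_j a_ij (diagonal excluded)."""
    M = A.to_numpy(dtype=float).copy()
    np.fill_diagonal(M, 0.0)
    return pd.Series(M.sum(axis=1), index=A.index, name="k")


def scale_free_fit(A: pd.DataFrame, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of the degree distribution.

    Connectivities are binned into ``n_bins`` equal-count (quantile) bins and
    the empirical frequency per unit connectivity -- bin frequency divided by
    bin width, i.e. an equal-count histogram density -- is regressed on log10
    mean connectivity. The regression R^2 is returned signed by the negated
    slope sign, so positive values indicate the decreasing degree
    distributions expected of (approximately) scale-free networks. Degenerate
    inputs (constant k, fewer than 3 usable bins) return 0 with a warning.
    """
    k = connectivity(A).to_numpy()
    return _scale_free_fit_from_k(k, n_bins)


def _scale_free_fit_from_k(k: np.ndarray, n_bins: int = 10) -> float:
    k = np.asarray(k, dtype=float)
    if len(k) < 30:
        raise InputError("scale-free fit needs at least 30 features")
    if np.allclose(k, k[0]):
        warnings.warn("all connectivities equal; scale-free fit undefined")
        return 0.0
    edges = np.quantile(k, np.linspace(0.0, 1.0, n_bins + 1))
    mean_k, density = [], []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        mask = (k >= lo) & ((k < hi) if b < n_bins - 1 else (k <= hi))
        width = hi - lo
        if mask.sum() == 0 or width <= 0:
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        mean_k.append(mk)
        density.append(mask.sum() / len(k) / width)
    if len(mean_k) < 3:
        warnings.warn("too few usable bins; scale-free fit undefined")
        return 0.0
    x = np.log10(mean_k)
    y = np.log10(density)
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(r**2 * (-np.sign(slope)))


@dataclass(frozen=True)
class SoftPowerReport:
    """Per-candidate scale-free fit and the selected soft power."""

    table: pd.DataFrame  # columns beta, signed_r2, mean_k
    selected_beta: int
    achieved_r2: float
    criterion_met: bool  # False = fallback to argmax, flagged

    @property
    def flagged(self) -> bool:
        return not self.criterion_met


def select_soft_power(
    S: pd.DataFrame,
    candidates=range(1, 21),
    r2_threshold: float = 0.8,
) -> SoftPowerReport:
    """Choose the lowest soft power reaching signed R^2 > threshold.

    When no candidate qualifies, the power with the highest signed R^2 is
    selected and the report is flagged.
    """
    candidates = list(candidates)
    if not candidates:
        raise ParameterError("candidate list must be nonempty")
    rows = []
    for beta in candidates:
        A = adjacency(S, beta)
        k = connectivity(A)
        rows.append(
            {"beta": beta, "signed_r2": scale_free_fit(A), "mean_k": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    passing = table[table["signed_r2"] > r2_threshold]
    if len(passing):
        best = passing.iloc[0]
        met = True
    else:
        best = table.loc[table["signed_r2"].idxmax()]
        met = False
    return SoftPowerReport(
        table=table,
        selected_beta=int(best["beta"]),
        achieved_r2=float(best["signed_r2"]),
        criterion_met=met,
    )


def topological_overlap(A: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix for a symmetric adjacency in [0, 1].

    Measures relative interconnectedness: direct adjacency plus shared
    neighbours, normalized by the smaller connectivity. Diagonal is 1 by
    convention.
    """
    M = A.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise InputError("adjacency must be square and symmetric")
    if M.min() < 0 or M.max() > 1:
        raise InputError("adjacency entries must lie in [0, 1]")
    M = M.copy()
    np.fill_diagonal(M, 0.0)
    k = M.sum(axis=1)
    shared = M @ M
    denom = np.minimum.outer(k, k) + 1.0 - M
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (shared + M) / denom
    T = np.nan_to_num(T, nan=0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    return pd.DataFrame(T, index=A.index, columns=A.columns)


def tom_dissimilarity(T: pd.DataFrame) -> pd.DataFrame:
    """Dissimilarity d = 1 - TOM with zero diagonal."""
    D = 1.0 - T.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=T.index, columns=T.columns)


def average_linkage(D: pd.DataFrame) -> np.ndarray:
    """UPGMA merge tree of a dissimilarity matrix (scipy linkage array)."""
    M = D.to_numpy(dtype=float)
    condensed = squareform(np.maximum(M, M.T), checks=False)
    return linkage(condensed, method="average")


def dynamic_tree_cut(
    linkage_matrix: np.ndarray,
    feature_ids,
    cut_height: float = 0.995,
    deep_split: int = 2,
    min_module_size: int = 5,
) -> ModulePartition:
    """Module detection by dynamic branch cutting (see :mod:`comodnet.treecut`)."""
    return cut_tree_dynamic(
        linkage_matrix,
        feature_ids,
        cut_height=cut_height,
        deep_split=deep_split,
        min_module_size=min_module_size,
    )


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def module_eigengene(
    m: ExpressionMatrix, partition: ModulePartition, module_id: int
) -> tuple[pd.Series, float]:
    """Module eigengene: first right singular vector of the member submatrix.

    Features are standardized across samples first; the eigengene has unit
    norm over samples and is oriented so its correlation with the module's
    mean standardized profile is nonnegative. Returns (eigengene, proportion
    of variance explained). A single-member module returns that feature's
    standardized profile (unit-normalized).
    """
    members = partition.members(module_id)
    if not members:
        raise InputError(f"module {module_id} has no members")
    X = _standardize_rows(m.values.loc[members].to_numpy(dtype=float))
    if len(members) == 1:
        v = X[0] / np.linalg.norm(X[0])
        return pd.Series(v, index=m.sample_ids, name=f"ME{module_id}"), 1.0
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    v = Vt[0]
    mean_profile = X.mean(axis=0)
    if np.dot(v, mean_profile) < 0:
        v = -v
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(v, index=m.sample_ids, name=f"ME{module_id}"), var_explained


@dataclass
class EigengeneMatrix:
    """Module x sample eigengene profiles with per-module variance explained."""

    values: pd.DataFrame  # modules x samples, rows "ME<k>"
    var_explained: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def eigengene_matrix(m: ExpressionMatrix, partition: ModulePartition) -> EigengeneMatrix:
    rows, ve = {}, {}
    for k in partition.module_ids:
        eg, v = module_eigengene(m, partition, k)
        rows[eg.name] = eg
        ve[eg.name] = v
    values = pd.DataFrame(rows).T
    if values.empty:
        values = pd.DataFrame(columns=m.sample_ids)
    return EigengeneMatrix(values=values, var_explained=pd.Series(ve, dtype=float))


def correlation_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided p from t = r sqrt((n-2)/(1-r^2)), n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError("x and y must have the same length")
    n = len(x)
    if n < 4:
        raise InputError("correlation test needs n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise InputError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0:
        return r, float(np.finfo(float).tiny)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(max(p, np.finfo(float).tiny))


def module_trait_table(eigengenes: EigengeneMatrix, traits: pd.DataFrame) -> pd.DataFrame:
    """Correlate every module eigengene with every trait column.

    ``traits`` is a sample x trait frame aligned on sample IDs; ordinal
    traits (e.g. the EoC code) are used as plain numeric vectors.
    """
    if list(traits.index) != eigengenes.sample_ids:
        traits = traits.reindex(eigengenes.sample_ids)
        if traits.isna().any().any():
            raise InputError("trait samples do not align with eigengene samples")
    rows = []
    for module in eigengenes.values.index:
        for trait in traits.columns:
            r, p = correlation_with_p(eigengenes.values.loc[module], traits[trait])
            rows.append({"module": module, "trait": trait, "r": r, "p": p})
    return pd.DataFrame(rows)


def feature_significance(m: ExpressionMatrix, trait: pd.Series) -> pd.DataFrame:
    """Per-feature trait correlation (GS) table ranked by |GS| descending.

    Constant features are excluded with a warning; rank is dense on |GS|.
    """
    trait = trait.reindex(m.sample_ids)
    if trait.isna().any():
        raise InputError("trait samples do not align with expression samples")
    rows, dropped = [], []
    for fid in m.values.index:
        x = m.values.loc[fid]
        if x.std() == 0:
            dropped.append(fid)
            continue
        r, p = correlation_with_p(x, trait)
        rows.append({"feature_id": fid, "GS": r, "p": p})
    if dropped:
        warnings.warn(f"excluding {len(dropped)} constant features: {dropped[:5]}")
    tab = pd.DataFrame(rows)
    tab = tab.sort_values("GS", key=np.abs, ascending=False, kind="stable").reset_index(drop=True)
    tab["rank"] = np.abs(tab["GS"]).rank(method="dense", ascending=False).astype(int)
    return tab


def coexpression_modules(
    m: ExpressionMatrix,
    beta: int | None = None,
    cut_height: float = 0.995,
    deep_split: int = 2,
    min_module_size: int = 5,
    dissimilarity: str = "tom",
    power_candidates=range(1, 21),
) -> tuple[ModulePartition, SoftPowerReport]:
    """Full module-detection chain from a preprocessed log2 matrix.

    With ``beta=None`` the soft power is selected automatically.
    ``dissimilarity`` chooses between the default ``"tom"`` (1 - TOM) and
    ``"adjacency"`` (1 - a) clustering input.
    """
    S = signed_similarity(m)
    if beta is None:
        report = select_soft_power(S, candidates=power_candidates)
    else:
        A0 = adjacency(S, beta)
        report = SoftPowerReport(
            table=pd.DataFrame(
                [{"beta": beta, "signed_r2": scale_free_fit(A0), "mean_k": float(connectivity(A0).mean())}]
            ),
            selected_beta=beta,
            achieved_r2=scale_free_fit(A0),
            criterion_met=True,
        )
    A = adjacency(S, report.selected_beta)
    if dissimilarity == "tom":
        D = tom_dissimilarity(topological_overlap(A))
    elif dissimilarity == "adjacency":
        D = 1.0 - A
        np.fill_diagonal(D.values, 0.0)
    else:
        raise ParameterError("dissimilarity must be 'tom' or 'adjacency'")
    Z = average_linkage(D)
    partition = dynamic_tree_cut(
        Z, S.index, cut_height=cut_height, deep_split=deep_split, min_module_size=min_module_size
    )
    return partition, report
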