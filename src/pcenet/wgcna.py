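"""Weighted co-expression network construction and module-trait analysis.

The chain is the classic WGCNA recipe applied to protein expression:
Pearson similarity -> soft-threshold adjacency a_ij = |s_ij|^beta ->
topological overlap matrix (TOM) -> average-linkage clustering of 1 - TOM
-> tree cut into modules -> per-module eigenprotein (first principal
component) -> module membership (kME) and point-biserial module-trait
correlation with Benjamini-Hochberg control.

Everything here is deterministic given the input: there is no internal
randomness, and protein order is canonicalized at ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

__all__ = [
    "SimilarityMatrix",
    "AdjacencyMatrix",
    "TOMatrix",
    "Dendrogram",
    "ModulePartition",
    "EigenproteinSet",
    "correlation_matrix",
    "pick_soft_power",
    "adjacency",
    "tom_similarity",
    "cluster_dendrogram",
    "dynamic_tree_cut",
    "eigenproteins",
    "module_membership",
    "module_trait_association",
    "bh_adjust",
]

#: Tree-cut height as a fraction of the maximum merge height, per
#: deep-split sensitivity level (4 = most sensitive, finest modules).
DEEP_SPLIT_CUT_FRACTION = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.99}


@dataclass
class SimilarityMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    protein_ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        S = self.S
        if S.shape[0] != S.shape[1] or S.shape[0] != len(self.protein_ids):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(S, S.T, atol=1e-12):
            raise ValueError("similarity matrix not symmetric")
        if np.nanmax(np.abs(S)) > 1 + 1e-12:
            raise ValueError("similarity values outside [-1, 1]")


@dataclass
class AdjacencyMatrix:
    protein_ids: list[str]
    A: np.ndarray
    beta: int


@dataclass
class TOMatrix:
    protein_ids: list[str]
    T: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.T


@dataclass
class Dendrogram:
    """Average-linkage merge tree in scipy linkage-matrix form."""

    protein_ids: list[str]
    Z: np.ndarray


@dataclass
class ModulePartition:
    """Protein -> integer module label; label 0 means unassigned ("grey")."""

    labels: pd.Series  # index: protein IDs, values: int labels

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m != 0)

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels != 0].value_counts().sort_index()
        return counts


@dataclass
class EigenproteinSet:
    """Per-module first-principal-component sample profile.

    ``profiles`` holds one unit-norm sample-length score vector per module
    (columns), oriented to correlate non-negatively with the module's mean
    standardized profile; ``variance_explained`` is the top component's
    share of within-module variance.
    """

    profiles: pd.DataFrame  # samples x modules
    variance_explained: pd.Series  # per module


def correlation_matrix(X) -> SimilarityMatrix:
    """Pairwise Pearson correlation across samples for every protein pair.

    Zero-variance proteins carry no correlation signal and are dropped with
    a warning before computing the matrix.
    """
    data = X.data
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples for pairwise correlation")
    sd = data.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(data.index[~keep])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance proteins: {dropped[:5]}...",
            stacklevel=2,
        )
        data = data.loc[keep]
    S = np.corrcoef(data.to_numpy(dtype=float))
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(data.index), S)


def pick_soft_power(
    S: SimilarityMatrix,
    candidates=tuple(range(1, 31)),
    target_r2: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by approximate scale-free topology.

    For each candidate beta, connectivity k_i = sum_{j != i} |s_ij|^beta is
    binned (10 equal-occupancy bins of log10 k) and the log-density of k is
    regressed on log10 k; the model fit R^2 measures how well the degree
    distribution follows a power law. Returns the smallest beta reaching
    ``target_r2``, else the best-fitting candidate with a warning.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate powers supplied")
    absS = np.abs(S.S).astype(float)
    np.fill_diagonal(absS, 0.0)
    records = []
    for beta in candidates:
        k = (absS**beta).sum(axis=1)
        r2, slope = _scale_free_fit(k)
        records.append({"beta": beta, "r_squared": r2, "slope": slope,
                        "mean_k": float(k.mean())})
    fits = pd.DataFrame(records)
    if fits["r_squared"].isna().all():
        warnings.warn("degenerate connectivity spread; returning smallest power",
                      stacklevel=2)
        return min(candidates), fits
    ok = fits[fits["r_squared"] >= target_r2]
    if len(ok):
        return int(ok["beta"].iloc[0]), fits
    best = int(fits.loc[fits["r_squared"].idxmax(), "beta"])
    warnings.warn(
        f"no candidate power reached R^2 >= {target_r2}; best is beta={best}",
        stacklevel=2,
    )
    return best, fits


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10-density vs log10-connectivity regression."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.ptp(np.log10(k)) < 1e-12:
        return float("nan"), float("nan")
    logk = np.log10(k)
    edges = np.quantile(logk, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return float("nan"), float("nan")
    idx = np.clip(np.searchsorted(edges, logk, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        width = edges[b + 1] - edges[b]
        if width <= 0:
            continue
        density = mask.mean() / width
        xs.append(logk[mask].mean())
        ys.append(np.log10(density))
    if len(xs) < 3:
        return float("nan"), float("nan")
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot <= 0:
        return float("nan"), float(slope)
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return float(r2), float(slope)


def adjacency(S: SimilarityMatrix, beta: int, signed: bool = False) -> AdjacencyMatrix:
    """Soft-threshold adjacency a_ij = |s_ij|^beta (or ((1+s)/2)^beta signed)."""
    if beta < 1:
        raise ValueError("soft power must be >= 1")
    if signed:
        A = ((1.0 + S.S) / 2.0) ** beta
    else:
        A = np.abs(S.S) ** beta
    np.fill_diagonal(A, 1.0)
    return AdjacencyMatrix(S.protein_ids, A, int(beta))


def tom_similarity(A: AdjacencyMatrix) -> TOMatrix:
    """Topological overlap: T_ij = (L_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    L_ij sums shared-neighbor adjacency products over u != i, j and
    k_i is the connectivity excluding the diagonal; T_ii = 1.
    """
    a = A.A.astype(float).copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a  # (i,j) entry already excludes u == i and u == j (zero diag)
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (L + a) / denom
    T = np.nan_to_num(T, nan=0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    return TOMatrix(A.protein_ids, T)


def cluster_dendrogram(D: np.ndarray, protein_ids: list[str]) -> Dendrogram:
    """Average-linkage agglomerative tree on a dissimilarity matrix."""
    D = np.asarray(D, dtype=float)
    if np.isnan(D).any():
        raise ValueError("NaN in dissimilarity matrix")
    if D.shape[0] != len(protein_ids):
        raise ValueError("dissimilarity shape does not match protein IDs")
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="average")
    return Dendrogram(list(protein_ids), Z)


def dynamic_tree_cut(
    dend: Dendrogram, min_module_size: int = 15, deep_split: int = 4
) -> ModulePartition:
    """Cut the dendrogram into modules of at least ``min_module_size``.

    Branches merging below a deep-split-dependent fraction of the maximum
    merge height become candidate modules; undersized candidates are
    dissolved to the unassigned label 0. Surviving modules are relabeled
    1..M by decreasing size (ties by smallest member ID).
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if deep_split not in DEEP_SPLIT_CUT_FRACTION:
        raise ValueError(f"deep_split must be one of {sorted(DEEP_SPLIT_CUT_FRACTION)}")
    if len(dend.protein_ids) == 0:
        raise ValueError("empty dendrogram")
    cut = DEEP_SPLIT_CUT_FRACTION[deep_split] * float(dend.Z[:, 2].max())
    raw = fcluster(dend.Z, t=cut, criterion="distance")
    labels = pd.Series(raw, index=dend.protein_ids)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    labels[~labels.isin(keep)] = 0
    # relabel by decreasing size; tie-break on the smallest protein ID inside
    order = sorted(
        (m for m in labels.unique() if m != 0),
        key=lambda m: (-int((labels == m).sum()), min(labels.index[labels == m])),
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    remap[0] = 0
    return ModulePartition(labels.map(remap))


def _standardize_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    if (sd <= 0).any():
        raise ValueError("zero-variance protein encountered in a module")
    return (M - mu) / sd


def eigenproteins(X, partition: ModulePartition) -> EigenproteinSet:
    """First-principal-component summary profile of each module.

    Each protein profile is standardized across samples; the eigenprotein
    is the unit-norm first right singular vector of the standardized module
    submatrix, oriented so that it correlates non-negatively with the
    module's mean standardized profile. ``variance_explained`` is the top
    singular value squared over the total.
    """
    profiles = {}
    var_exp = {}
    for m in partition.module_ids:
        members = partition.members(m)
        if len(members) < 2:
            raise ValueError(f"module {m} has fewer than 2 proteins")
        M = _standardize_rows(X.data.loc[members].to_numpy(dtype=float))
        _, s, Vt = np.linalg.svd(M, full_matrices=False)
        v = Vt[0]
        mean_profile = M.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        profiles[m] = v
        var_exp[m] = float(s[0] ** 2 / (s**2).sum())
    E = pd.DataFrame(profiles, index=X.sample_ids)
    E.columns.name = "module"
    return EigenproteinSet(E, pd.Series(var_exp, name="variance_explained"))


def module_membership(X, E: EigenproteinSet) -> pd.DataFrame:
    """kME grid: Pearson correlation of each protein with each eigenprotein."""
    M = X.data.to_numpy(dtype=float)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = np.nan
    Zp = (M - M.mean(axis=1, keepdims=True)) / sd
    Ev = E.profiles.to_numpy(dtype=float)
    Ez = (Ev - Ev.mean(axis=0, keepdims=True)) / Ev.std(axis=0, ddof=1, keepdims=True)
    n = M.shape[1]
    kme = (Zp @ Ez) / (n - 1)
    out = pd.DataFrame(
        np.clip(kme, -1.0, 1.0), index=X.protein_ids, columns=E.profiles.columns
    )
    return out


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the asymptotic t distribution."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return r, float(np.finfo(float).tiny)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return r, min(p, 1.0)


def module_trait_association(
    E: EigenproteinSet,
    traits,
    r_min: float = 0.5,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Point-biserial correlation of each eigenprotein with each binary trait.

    p-values come from the t transform with n - 2 degrees of freedom; the
    Benjamini-Hochberg adjustment is applied jointly over all module x trait
    tests; a pair is significant iff |r| > r_min and q < q_max.
    """
    tdf = traits.traits
    n = len(tdf)
    if n < 4:
        raise ValueError("need at least 4 samples for module-trait association")
    rows = []
    for m in E.profiles.columns:
        e = E.profiles[m].to_numpy(dtype=float)
        for trait in tdf.columns:
            y = tdf[trait].to_numpy(dtype=float)
            if np.unique(y).size < 2:
                raise ValueError(f"trait {trait!r} is constant")
            r, p = _pearson_with_p(e, y)
            rows.append({"module": m, "trait": trait, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["r"].abs() > r_min) & (out["q"] < q_max)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
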