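"""Weighted co-expression module analysis (eigengenes, module-trait maps, hubs).

A parameterized reimplementation of the standard weighted co-expression
workflow used in the study: per-gene covariate removal, soft-thresholded
unsigned adjacency ``|r|^β`` (β = 10), topological overlap, average-linkage
clustering of ``1 − TOM`` with a minimum module size of 44 genes and
eigengene-based merging at cut height 0.25, module eigengenes (first
principal component of the standardized module submatrix), module-trait and
module-phenotype Pearson correlations, gene significance (GS) / module
membership (MM) tables, and top-5 hub selection under GS > 0.2, MM > 0.8.

Matrices are genes × samples throughout; gene and sample ids ride along on
pandas indexes.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ModuleResult",
    "remove_covariates",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_trait_correlation",
    "gene_significance",
    "module_membership",
    "select_hubs",
    "eigengene_phenotype_correlation",
    "run_workflow",
]

UNASSIGNED = "unassigned"


@dataclass
class ModuleResult:
    """Outputs of module detection and downstream correlation analyses."""

    labels: pd.Series  # gene -> module name ("M1", ..., or "unassigned")
    eigengenes: pd.DataFrame  # samples × modules, unit-norm columns
    merge_history: list[tuple[str, str]] = field(default_factory=list)
    module_trait: pd.DataFrame | None = None  # MultiIndex (module, trait) -> r, p, significant
    gs: pd.DataFrame | None = None  # genes × traits
    mm: pd.DataFrame | None = None  # genes × modules
    hubs: dict[str, list[str]] = field(default_factory=dict)
    hub_edges: pd.DataFrame | None = None

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)


def _design_matrix(annotations: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    parts = []
    for col in columns:
        s = annotations[col]
        if s.dtype.kind in "biufc":
            parts.append(s.astype(float).to_frame(col))
        else:
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=annotations.index)


def remove_covariates(
    expr: pd.DataFrame,
    annotations: pd.DataFrame,
    unwanted: list[str],
    retained: list[str] | None = None,
) -> pd.DataFrame:
    """Regress out unwanted covariates gene-by-gene, preserving retained ones.

    Fits, per gene, a linear model with intercept plus the retained and
    unwanted covariates jointly, then subtracts only the fitted contribution
    of the unwanted covariates.  Categorical covariates are dummy-coded.
    Raises on a collinear design, naming the aliased columns.
    """
    retained = retained or []
    if not unwanted:
        return expr.copy()
    ann = annotations.loc[expr.columns]
    D_unw = _design_matrix(ann, unwanted)
    D_ret = _design_matrix(ann, retained)
    D = np.column_stack([np.ones(len(ann)), D_ret.to_numpy(), D_unw.to_numpy()])
    names = ["intercept"] + list(D_ret.columns) + list(D_unw.columns)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify aliased columns via rank-revealing QR pivoting
        from scipy.linalg import qr

        _, r, piv = qr(D, pivoting=True)
        keep = piv[: rank]
        aliased = sorted(set(names) - {names[i] for i in keep})
        raise ValueError(f"collinear design; aliased covariates: {aliased}")
    Y = expr.to_numpy(float).T  # samples × genes
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    n_unw = D_unw.shape[1]
    fitted_unwanted = D[:, -n_unw:] @ beta[-n_unw:, :]
    cleaned = (Y - fitted_unwanted).T
    return pd.DataFrame(cleaned, index=expr.index, columns=expr.columns)


def adjacency(expr: pd.DataFrame, beta: float = 10.0) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency ``a_ij = |pearson(x_i, x_j)|^β``.

    Diagonal entries are 1.  Raises (listing offenders) if any gene has zero
    variance across samples.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if expr.shape[1] < 3:
        raise ValueError("adjacency needs at least 3 samples")
    X = expr.to_numpy(float)
    sd = X.std(axis=1)
    bad = list(expr.index[sd == 0])
    if bad:
        raise ValueError(f"zero-variance genes: {bad[:10]}{'...' if len(bad) > 10 else ''}")
    r = np.corrcoef(X)
    a = np.abs(np.clip(r, -1, 1)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix of an adjacency with entries in [0, 1].

    ``TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`` with the
    sum over u ∉ {i, j} and ``k_i = Σ_{u≠i} a_iu``; the diagonal is 1.
    """
    A = adj.to_numpy(float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if A.min() < 0 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    shared = A0 @ A0  # Σ_u a_iu a_uj over u != i, j (diagonal removed) minus nothing extra
    # subtract terms where u == i or u == j: with zeroed diagonal those are absent
    k = A0.sum(axis=1)
    num = shared + A0
    den = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def module_eigengene(expr: pd.DataFrame, module_genes: list[str]) -> pd.Series:
    """First principal component of the standardized module submatrix.

    The eigengene is a unit-norm sample-score vector, sign-aligned so that
    its correlation with the module's mean standardized expression profile
    is positive.
    """
    if len(module_genes) < 2:
        raise ValueError("a module eigengene needs at least 2 genes")
    sub = expr.loc[module_genes].to_numpy(float)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(v, mean_profile) < 0:
        v = -v
    return pd.Series(v, index=expr.columns)


# Default static cut on the 1−TOM dendrogram.  Genuine modules complete well
# below this height while unclustered background pairs sit at dissimilarity
# ≈ 1 and only coalesce in the last merges, so a fixed high cut separates
# them deterministically (the customary static-cut default of the standard
# co-expression tooling).
DEFAULT_CUT_HEIGHT = 0.995


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame,
    min_size: int = 44,
    merge_cut: float = 0.25,
    cut_height: float | None = None,
) -> ModuleResult:
    """Average-linkage clustering of 1 − TOM into co-expression modules.

    Flat clusters are taken at ``cut_height`` (default
    :data:`DEFAULT_CUT_HEIGHT`); clusters smaller than
    ``min_size`` become "unassigned".  Modules whose eigengene dissimilarity
    ``1 − r`` falls below ``merge_cut`` are merged iteratively.  Warns (and
    labels everything unassigned) when no cluster reaches ``min_size``.
    """
    genes = list(tom.index)
    diss = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    if cut_height is None:
        cut_height = DEFAULT_CUT_HEIGHT
    flat = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(flat).value_counts()
    keep = sizes.index[sizes >= min_size]
    labels = pd.Series(
        [f"C{c}" if c in set(keep) else UNASSIGNED for c in flat], index=genes
    )
    if len(keep) == 0:
        _warnings.warn("no cluster reached min_size; all genes unassigned")
        return ModuleResult(labels=labels, eigengenes=pd.DataFrame(index=expr.columns))

    merge_history: list[tuple[str, str]] = []
    while True:
        modules = sorted(set(labels) - {UNASSIGNED})
        eig = pd.DataFrame(
            {m: module_eigengene(expr, list(labels.index[labels == m])) for m in modules}
        )
        if len(modules) < 2:
            break
        corr = eig.corr().to_numpy()
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if 1.0 - corr[i, j] >= merge_cut:
            break
        a, b = modules[i], modules[j]
        labels[labels == b] = a
        merge_history.append((b, a))

    # stable final naming: M1, M2, ... by decreasing module size
    modules = sorted(set(labels) - {UNASSIGNED})
    order = sorted(modules, key=lambda m: (-(labels == m).sum(), m))
    rename = {old: f"M{i+1}" for i, old in enumerate(order)}
    labels = labels.map(lambda s: rename.get(s, UNASSIGNED))
    eig = pd.DataFrame(
        {
            new: module_eigengene(expr, list(labels.index[labels == new]))
            for new in sorted(rename.values(), key=lambda s: int(s[1:]))
        }
    )
    return ModuleResult(labels=labels, eigengenes=eig, merge_history=merge_history)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r and two-sided p for every (module eigengene, trait) pair.

    p-values use the t transform with n − 2 degrees of freedom; a constant
    trait yields missing values.  ``significant`` flags p < alpha.
    """
    if len(eigengenes) < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for mod in eigengenes.columns:
        e = eigengenes[mod].to_numpy(float)
        for tr in traits.columns:
            t = traits.loc[eigengenes.index, tr].to_numpy(float)
            r, p = _pearson_with_p(e, t)
            rows.append({"module": mod, "trait": tr, "r": r, "p": p,
                         "significant": bool(p < alpha) if np.isfinite(p) else False})
    return pd.DataFrame(rows).set_index(["module", "trait"])


def gene_significance(expr: pd.DataFrame, trait: pd.Series) -> pd.Series:
    """GS_g = |pearson(x_g, trait)| per gene."""
    t = trait.loc[expr.columns].to_numpy(float)
    X = expr.to_numpy(float)
    tz = t - t.mean()
    Xz = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xz**2).sum(axis=1) * (tz**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xz @ tz) / denom
    return pd.Series(np.abs(r), index=expr.index, name="GS")


def module_membership(expr: pd.DataFrame, eigengene: pd.Series) -> pd.Series:
    """MM_g = |pearson(x_g, eigengene)| per gene."""
    return gene_significance(expr, eigengene).rename("MM")


def select_hubs(
    gs: pd.Series,
    mm: pd.Series,
    adj: pd.DataFrame,
    module_genes: list[str],
    gs_min: float = 0.2,
    mm_min: float = 0.8,
    top_n: int = 5,
    edge_threshold: float = 0.02,
) -> tuple[list[str], pd.DataFrame]:
    """Top hub genes of a module and their intra-module edge list.

    Genes qualify with GS > gs_min and MM > mm_min; ranking is by MM
    descending, ties broken by intramodular connectivity (sum of adjacency
    to module genes) then gene id.  Warns when fewer than ``top_n`` qualify.
    The edge list contains all adjacency entries from the hubs to module
    genes at or above ``edge_threshold``.
    """
    cand = [g for g in module_genes if gs[g] > gs_min and mm[g] > mm_min]
    if len(cand) < top_n:
        _warnings.warn(f"only {len(cand)} genes pass the GS/MM hub thresholds")
    conn = adj.loc[module_genes, module_genes].sum(axis=1) - 1.0  # drop self-loop
    ranked = sorted(cand, key=lambda g: (-mm[g], -conn[g], g))
    hubs = ranked[:top_n]
    edges = []
    for h in hubs:
        for g in module_genes:
            if g == h:
                continue
            w = float(adj.at[h, g])
            if w >= edge_threshold:
                edges.append({"source": h, "target": g, "weight": w})
    return hubs, pd.DataFrame(edges, columns=["source", "target", "weight"])


def hub_network(hub_edges: pd.DataFrame) -> nx.Graph:
    """Hub edge list as an undirected weighted graph (for export/rendering)."""
    g = nx.Graph()
    for row in hub_edges.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=row.weight)
    return g


def eigengene_phenotype_correlation(
    eigengene: pd.Series,
    phenotype: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-group Pearson correlation of an eigengene with a phenotype.

    Samples with missing phenotype are dropped; groups with fewer than 3
    remaining samples yield missing values with a warning.
    """
    rows = []
    for grp in pd.unique(groups.dropna()):
        idx = groups.index[groups == grp]
        e = eigengene.loc[idx]
        ph = phenotype.loc[idx]
        ok = ph.notna() & e.notna()
        if ok.sum() < 3:
            _warnings.warn(f"group {grp!r} has fewer than 3 samples with phenotype data")
            rows.append({"group": grp, "n": int(ok.sum()), "r": np.nan, "p": np.nan})
            continue
        r, p = _pearson_with_p(e[ok].to_numpy(float), ph[ok].to_numpy(float))
        rows.append({"group": grp, "n": int(ok.sum()), "r": r, "p": p})
    return pd.DataFrame(rows).set_index("group")


def run_workflow(
    expr: pd.DataFrame,
    annotations: pd.DataFrame,
    trait_columns: list[str] | None = None,
    unwanted: list[str] | None = None,
    beta: float = 10.0,
    min_size: int = 44,
    merge_cut: float = 0.25,
    cut_height: float | None = None,
    gs_min: float = 0.2,
    mm_min: float = 0.8,
    top_n: int = 5,
) -> ModuleResult:
    """End-to-end module workflow on a genes × samples matrix.

    Removes unwanted covariates (default: batch) while preserving the
    traits, builds the |r|^β network and TOM, detects and merges modules,
    and fills in module-trait correlations, GS/MM tables and hub lists.
    GS for hub selection uses each module's most-correlated trait.
    """
    trait_columns = trait_columns or [c for c in ("APOE_code", "Trem2_code", "APP_code", "sex_code") if c in annotations.columns]
    unwanted = ["batch"] if unwanted is None else unwanted
    unwanted = [c for c in unwanted if c in annotations.columns]
    cleaned = remove_covariates(expr, annotations, unwanted, trait_columns) if unwanted else expr
    adj = adjacency(cleaned, beta=beta)
    tom = tom_similarity(adj)
    result = detect_modules(tom, cleaned, min_size=min_size, merge_cut=merge_cut, cut_height=cut_height)
    traits = annotations.loc[cleaned.columns, trait_columns].astype(float)
    if result.modules:
        result.module_trait = module_trait_correlation(result.eigengenes, traits)
        result.gs = pd.DataFrame({tr: gene_significance(cleaned, traits[tr]) for tr in traits})
        result.mm = pd.DataFrame(
            {m: module_membership(cleaned, result.eigengenes[m]) for m in result.modules}
        )
        edges_all = []
        for m in result.modules:
            genes_m = list(result.labels.index[result.labels == m])
            best_trait = result.module_trait.loc[m]["r"].abs().idxmax()
            hubs, edges = select_hubs(
                result.gs[best_trait], result.mm[m], adj, genes_m,
                gs_min=gs_min, mm_min=mm_min, top_n=top_n,
            )
            result.hubs[m] = hubs
            edges["module"] = m
            edges_all.append(edges)
        result.hub_edges = pd.concat(edges_all, ignore_index=True) if edges_all else None
    return result
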