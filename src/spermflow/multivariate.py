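"""Multivariate layer: dependence, clustering and dimension reduction.

This module houses the statistics used to describe the joint behaviour of
the per-sample chromatin variables: Pearson correlation matrices with
Benjamini-Hochberg false-discovery-rate masking, Hoeffding's D as a general
(direction-free) dependence measure driving variable clustering, and a
standardized PCA whose loadings are variable-component correlations and
whose contributions are each variable's percentage share of a component,
followed by hierarchical clustering of observations on the leading
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import pearsonr, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hoeffding_d",
    "CorrelationMatrix",
    "correlation_matrix",
    "VariableClusterTree",
    "cluster_variables",
    "PCAResult",
    "principal_components",
    "component_contribution",
    "cluster_observations_on_pcs",
]


# ---------------------------------------------------------------------------
# Hoeffding's D

def hoeffding_d(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D statistic of general bivariate dependence.

    Computed from midranks ``R``, ``S`` and bivariate ranks ``Q`` (the point
    itself plus points strictly smaller on both axes, with half credit for
    ties on one axis and quarter credit for ties on both)::

        D1 = sum (Q-1)(Q-2)
        D2 = sum (R-1)(R-2)(S-1)(S-2)
        D3 = sum (R-2)(S-2)(Q-1)
        D  = 30 * [(n-2)(n-3) D1 + D2 - 2(n-2) D3]
                 / [n(n-1)(n-2)(n-3)(n-4)]

    With this normalisation D lies in [-0.5, 1]; perfect (monotone or not)
    functional dependence on continuous data gives 1, independence gives a
    value fluctuating around 0.  Direction does not matter.

    Raises on n < 5; returns NaN for a constant input (dependence is
    undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 5:
        raise ValueError("Hoeffding's D needs at least 5 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")

    r = rankdata(x)  # midranks
    s = rankdata(y)
    # pairwise "strictly smaller with tie half-credit" scores
    cx = (x[:, None] > x[None, :]).astype(float)
    cx += 0.5 * (x[:, None] == x[None, :])
    cy = (y[:, None] > y[None, :]).astype(float)
    cy += 0.5 * (y[:, None] == y[None, :])
    # row sums include the self-pair (0.5 * 0.5); Q counts the point itself
    q = 1.0 + ((cx * cy).sum(axis=1) - 0.25)

    d1 = float(np.sum((q - 1.0) * (q - 2.0)))
    d2 = float(np.sum((r - 1.0) * (r - 2.0) * (s - 1.0) * (s - 2.0)))
    d3 = float(np.sum((r - 2.0) * (s - 2.0) * (q - 1.0)))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom


# ---------------------------------------------------------------------------
# FDR-masked Pearson correlations

@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with BH-adjusted significance mask."""

    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    flags: list[str] = field(default_factory=list)

    def masked_r(self) -> pd.DataFrame:
        """r with non-significant cells blanked (NaN), diagonal kept."""
        out = self.r.where(self.significant)
        np.fill_diagonal(out.values, 1.0)
        return out


def correlation_matrix(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> CorrelationMatrix:
    """Pearson correlations over all variable pairs with BH-FDR masking.

    P-values are adjusted (Benjamini-Hochberg) over the upper triangle only;
    a pair is significant when its adjusted p is at or below ``alpha``.
    Constant variables are flagged and their cells left NaN / untested.
    """
    variables = list(variables) if variables is not None else list(table.columns)
    p = len(variables)
    x = table.loc[:, variables].to_numpy(dtype=float)
    flags: list[str] = []
    constant = [
        v for j, v in enumerate(variables)
        if np.nanstd(x[:, j]) == 0
    ]
    flags.extend(f"constant_variable:{v}" for v in constant)

    r = np.full((p, p), np.nan)
    p_raw = np.full((p, p), np.nan)
    np.fill_diagonal(r, 1.0)
    pairs = []
    for i in range(p):
        for j in range(i + 1, p):
            if variables[i] in constant or variables[j] in constant:
                continue
            xi, xj = x[:, i], x[:, j]
            ok = ~(np.isnan(xi) | np.isnan(xj))
            if ok.sum() < 3:
                flags.append(f"too_few_pairs:{variables[i]}~{variables[j]}")
                continue
            res = pearsonr(xi[ok], xj[ok])
            r[i, j] = r[j, i] = res.statistic
            p_raw[i, j] = p_raw[j, i] = res.pvalue
            pairs.append((i, j))

    p_adj = np.full((p, p), np.nan)
    sig = np.zeros((p, p), dtype=bool)
    if pairs:
        raw = np.array([p_raw[i, j] for i, j in pairs])
        reject, adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
        for (i, j), a, rej in zip(pairs, adj, reject):
            p_adj[i, j] = p_adj[j, i] = a
            sig[i, j] = sig[j, i] = rej

    idx = pd.Index(variables)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p_raw=pd.DataFrame(p_raw, index=idx, columns=idx),
        p_adjusted=pd.DataFrame(p_adj, index=idx, columns=idx),
        significant=pd.DataFrame(sig, index=idx, columns=idx),
        alpha=alpha,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# variable clustering on Hoeffding's D

@dataclass
class VariableClusterTree:
    """Agglomerative tree over variables built on scaled Hoeffding-D
    similarity (distance = 1 - D)."""

    variables: list[str]
    similarity: pd.DataFrame
    linkage_matrix: np.ndarray
    order: list[str]
    flags: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.variables)


def cluster_variables(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    method: str = "average",
) -> VariableClusterTree:
    """Cluster variables by general dependence.

    Pairwise scaled Hoeffding D is the similarity (self-similarity 1, the
    scale maximum); the tree is built by ``method`` linkage on ``1 - D``.
    An undefined pairwise D (constant variable) propagates as NaN similarity
    and maximal distance, with a flag.
    """
    variables = list(variables) if variables is not None else list(table.columns)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables to cluster")
    p = len(variables)
    x = table.loc[:, variables].to_numpy(dtype=float)
    sim = np.full((p, p), 1.0)
    flags: list[str] = []
    for i in range(p):
        for j in range(i + 1, p):
            d = hoeffding_d(x[:, i], x[:, j])
            if np.isnan(d):
                flags.append(f"undefined_dependence:{variables[i]}~{variables[j]}")
            sim[i, j] = sim[j, i] = d

    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    # undefined similarities are treated as maximally distant
    dist = np.where(np.isnan(dist), 1.5, dist)
    dist = np.clip(dist, 0.0, None)
    condensed = dist[np.triu_indices(p, k=1)]
    lk = linkage(condensed, method=method)
    order = [variables[i] for i in leaves_list(lk)]
    idx = pd.Index(variables)
    return VariableClusterTree(
        variables=variables,
        similarity=pd.DataFrame(sim, index=idx, columns=idx),
        linkage_matrix=lk,
        order=order,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# standardized PCA with loadings and contributions

@dataclass
class PCAResult:
    """Eigen-decomposition of the correlation matrix.

    ``loadings`` are variable-component correlations (in [-1, 1]);
    ``contributions`` are ``100 * loading^2 / eigenvalue`` and sum to 100
    per component; ``scores`` are the observations projected on the
    (unit-norm) eigenvectors.  Each component is oriented so its
    largest-|loading| variable loads positively.
    """

    eigenvalues: np.ndarray
    explained: np.ndarray
    loadings: pd.DataFrame
    contributions: pd.DataFrame
    scores: pd.DataFrame
    means: np.ndarray
    sds: np.ndarray


def component_contribution(loading: float, eigenvalue: float) -> float:
    """A variable's percentage contribution to one component:
    ``100 * loading^2 / eigenvalue``."""
    if eigenvalue <= 0:
        raise ValueError("eigenvalue must be positive")
    return 100.0 * loading * loading / eigenvalue


def principal_components(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    standardize: bool = True,
) -> PCAResult:
    """PCA of the (standardized) variable block.

    Standardizing makes this the eigen-decomposition of the correlation
    matrix, so eigenvalues sum to the number of variables and loadings are
    correlations.  Requires more complete observations than variables.
    """
    variables = list(variables) if variables is not None else list(table.columns)
    x = table.loc[:, variables].to_numpy(dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n, p = x.shape
    if n < p + 1:
        raise ValueError(
            f"PCA needs at least {p + 1} complete observations for {p} "
            f"variables, got {n}"
        )
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if standardize:
        if np.any(sds == 0):
            bad = [variables[j] for j in np.where(sds == 0)[0]]
            raise ValueError(f"constant variable(s) in PCA input: {bad}")
        z = (x - means) / sds
        cov = np.corrcoef(z, rowvar=False)
    else:
        z = x - means
        cov = np.cov(z, rowvar=False)

    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    loadings = eigvecs * np.sqrt(eigvals)
    # orient: largest-|loading| variable positive on each component
    for j in range(p):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            eigvecs[:, j] *= -1

    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(
            eigvals[None, :] > 0,
            100.0 * loadings**2 / np.where(eigvals[None, :] > 0, eigvals, 1.0),
            0.0,
        )
    scores = z @ eigvecs
    comp_names = [f"PC{j + 1}" for j in range(p)]
    idx = pd.Index(variables)
    return PCAResult(
        eigenvalues=eigvals,
        explained=eigvals / eigvals.sum(),
        loadings=pd.DataFrame(loadings, index=idx, columns=comp_names),
        contributions=pd.DataFrame(contrib, index=idx, columns=comp_names),
        scores=pd.DataFrame(scores, columns=comp_names),
        means=means,
        sds=sds,
    )


def cluster_observations_on_pcs(
    pca: PCAResult, n_pcs: int = 2, k: int = 2
) -> np.ndarray:
    """Ward hierarchical clustering of observation scores on the first
    ``n_pcs`` components, cut at ``k`` clusters (labels 0..k-1)."""
    scores = pca.scores.iloc[:, :n_pcs].to_numpy()
    n = len(scores)
    if k > n:
        raise ValueError(f"k={k} exceeds number of observations ({n})")
    if k == n:
        return np.arange(n)
    lk = linkage(scores, method="ward")
    return fcluster(lk, t=k, criterion="maxclust") - 1
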