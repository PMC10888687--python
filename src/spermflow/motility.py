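"""CASA kinematics: derived ratios, motility classes, subpopulations.

The subpopulation extraction is the two-stage ("double clustering") scheme
common in CASA studies: a deliberately over-fitted k-means pass condenses the
per-cell cloud into a few dozen centroids, then Ward agglomeration of those
centroids, cut at the silhouette-optimal level, yields the biological
subpopulations (typically Slow / Fast / Hyperactivated in the boar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import median_abs_deviation
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .config import ClusteringConfig
from .tables import KINEMATIC_COLUMNS, KinematicTable

__all__ = [
    "KinematicRecord",
    "SubpopulationModel",
    "derive_kinematics",
    "kinematics_frame",
    "classify_motility",
    "cluster_subpopulations",
    "summarize_subpopulations",
]


@dataclass(frozen=True)
class KinematicRecord:
    """One cell's kinematics.  Velocities in um/s, ratios in %, ALH in um,
    BCF in Hz, DNC in um^2/s, DNCm in um (NaN when VSL = 0)."""

    vcl: float
    vsl: float
    vap: float
    lin: float
    str: float
    wob: float
    alh: float
    bcf: float
    dnc: float
    dncm: float


def derive_kinematics(
    vcl: float, vsl: float, vap: float, alh: float, bcf: float
) -> KinematicRecord:
    """Derive the ratio variables from the measured velocities.

    LIN = 100*VSL/VCL, STR = 100*VSL/VAP, WOB = 100*VAP/VCL,
    DNC = VCL*ALH and DNCm = DNC/VSL ("mean dance"; undefined for an
    immotile-straight cell with VSL = 0, returned as NaN).
    """
    if vcl <= 0 or vap <= 0:
        raise ValueError("vcl and vap must be positive")
    if not (vsl <= vap + 1e-9 and vap <= vcl + 1e-9):
        raise ValueError("velocities must satisfy VSL <= VAP <= VCL")
    dnc = vcl * alh
    dncm = dnc / vsl if vsl > 0 else float("nan")
    return KinematicRecord(
        vcl=vcl,
        vsl=vsl,
        vap=vap,
        lin=100.0 * vsl / vcl,
        str=100.0 * vsl / vap,
        wob=100.0 * vap / vcl,
        alh=alh,
        bcf=bcf,
        dnc=dnc,
        dncm=dncm,
    )


def kinematics_frame(
    vcl: np.ndarray,
    vsl: np.ndarray,
    vap: np.ndarray,
    alh: np.ndarray,
    bcf: np.ndarray,
) -> pd.DataFrame:
    """Vectorised :func:`derive_kinematics` returning a kinematic frame."""
    vcl, vsl, vap = (np.asarray(a, dtype=float) for a in (vcl, vsl, vap))
    alh, bcf = np.asarray(alh, dtype=float), np.asarray(bcf, dtype=float)
    if np.any(vcl <= 0) or np.any(vap <= 0):
        raise ValueError("vcl and vap must be positive")
    dnc = vcl * alh
    with np.errstate(divide="ignore", invalid="ignore"):
        dncm = np.where(vsl > 0, dnc / np.where(vsl > 0, vsl, 1.0), np.nan)
    return pd.DataFrame(
        {
            "vcl": vcl,
            "vsl": vsl,
            "vap": vap,
            "lin": 100.0 * vsl / vcl,
            "str": 100.0 * vsl / vap,
            "wob": 100.0 * vap / vcl,
            "alh": alh,
            "bcf": bcf,
            "dnc": dnc,
            "dncm": dncm,
        },
        columns=list(KINEMATIC_COLUMNS),
    )


def classify_motility(
    vcl: np.ndarray | float,
    str_pct: np.ndarray | float,
    motile_vcl_cut: float = 10.0,
) -> np.ndarray | str:
    """Classify cells as immotile / nonprogressive / progressive.

    Progressive requires VCL > 25 um/s and STR > 45%; motile requires
    VCL >= ``motile_vcl_cut`` (the progressive criterion is fixed; the motile
    cut is an analysis choice).
    """
    scalar = np.isscalar(vcl)
    vcl = np.atleast_1d(np.asarray(vcl, dtype=float))
    str_pct = np.atleast_1d(np.asarray(str_pct, dtype=float))
    out = np.full(vcl.shape, "nonprogressive", dtype=object)
    out[vcl < motile_vcl_cut] = "immotile"
    out[(vcl > 25.0) & (str_pct > 45.0)] = "progressive"
    return out[0] if scalar else out.astype(str)


@dataclass
class SubpopulationModel:
    """Fitted two-stage subpopulation model (in standardized feature space)."""

    features: tuple[str, ...]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    stage1_centroids: np.ndarray
    linkage_matrix: np.ndarray
    final_k: int
    final_centroids: np.ndarray
    labels: np.ndarray
    silhouettes: dict[int, float] = field(default_factory=dict)

    def standardize(self, df: pd.DataFrame) -> np.ndarray:
        x = df.loc[:, list(self.features)].to_numpy(dtype=float)
        return (x - self.feature_means) / self.feature_sds


def _standardize(df: pd.DataFrame, features: tuple[str, ...]):
    x = df.loc[:, list(features)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("kinematic features contain missing values")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1) if len(x) > 1 else np.zeros(x.shape[1])
    for j, s in enumerate(sds):
        if s == 0:
            raise ValueError(f"zero-variance kinematic column: {features[j]}")
    return (x - means) / sds, means, sds


def cluster_subpopulations(
    cells: pd.DataFrame,
    config: ClusteringConfig | None = None,
    seed: int = 0,
) -> SubpopulationModel:
    """Two-stage subpopulation clustering of pooled motile cells.

    Stage 1 compresses the standardized kinematic cloud with k-means
    (``config.stage1_k`` groups); stage 2 applies Ward linkage to the stage-1
    centroids and cuts the tree at the k in ``[k_min, k_max]`` maximising the
    cell-level silhouette.  K-means is fitted on lexicographically sorted rows
    so the result is invariant to the order of the input.
    """
    config = config or ClusteringConfig()
    z, means, sds = _standardize(cells, config.features)
    n = len(z)
    if n < config.stage1_k:
        raise ValueError(
            f"need at least stage1_k={config.stage1_k} cells, got {n}"
        )
    order = np.lexsort(z.T[::-1])  # sort by first feature, then the rest
    km = KMeans(
        n_clusters=config.stage1_k,
        n_init=10,
        random_state=seed,
    ).fit(z[order])
    centroids = km.cluster_centers_
    stage1_labels = km.predict(z)

    lk = linkage(centroids, method="ward")
    # silhouette is evaluated on (a subsample of) the sorted rows so the
    # model selection is invariant to input row order
    z_sorted = z[order]
    sorted_stage1 = km.labels_
    if n > 10000:
        pick = np.random.default_rng(seed).choice(n, 10000, replace=False)
        pick.sort()
    else:
        pick = np.arange(n)
    best_k, best_s, best_labels = None, -np.inf, None
    silhouettes: dict[int, float] = {}
    k_hi = min(config.k_max, len(centroids))
    for k in range(config.k_min, k_hi + 1):
        merged = fcluster(lk, t=k, criterion="maxclust") - 1
        cell_labels = merged[stage1_labels]
        eval_labels = merged[sorted_stage1][pick]
        if len(np.unique(eval_labels)) < 2:
            continue
        s = float(silhouette_score(z_sorted[pick], eval_labels))
        silhouettes[k] = s
        if s > best_s:
            best_k, best_s, best_labels = k, s, cell_labels
    if best_labels is None:  # degenerate: single attainable cluster
        best_k, best_labels = 1, np.zeros(n, dtype=int)

    # relabel clusters by ascending mean VCL (or first feature) for stability
    final_centroids = np.vstack(
        [z[best_labels == c].mean(axis=0) for c in range(best_k)]
    )
    order_c = np.argsort(final_centroids[:, 0], kind="stable")
    remap = np.empty(best_k, dtype=int)
    remap[order_c] = np.arange(best_k)
    best_labels = remap[best_labels]
    final_centroids = final_centroids[order_c]

    return SubpopulationModel(
        features=config.features,
        feature_means=means,
        feature_sds=sds,
        stage1_centroids=centroids,
        linkage_matrix=lk,
        final_k=best_k,
        final_centroids=final_centroids,
        labels=best_labels,
        silhouettes=silhouettes,
    )


def summarize_subpopulations(
    model: SubpopulationModel,
    cells: pd.DataFrame,
    sample_ids: np.ndarray | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Median +/- MAD per cluster, and per-sample cluster percentages.

    Returns ``(summary, percentages)``; ``percentages`` is None when
    ``sample_ids`` is not given.  The summary has one row per cluster with
    ``<var>_median`` and ``<var>_mad`` for all ten kinematic variables plus
    the cluster's overall share (``pct``, summing to 100 over clusters).
    """
    labels = model.labels
    if len(labels) != len(cells):
        raise ValueError("model labels do not match cells")
    rows = []
    for c in range(model.final_k):
        sub = cells.loc[labels == c, list(KINEMATIC_COLUMNS)]
        row: dict[str, float] = {"cluster": c}
        for col in KINEMATIC_COLUMNS:
            vals = sub[col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            row[f"{col}_median"] = float(np.median(vals)) if len(vals) else np.nan
            row[f"{col}_mad"] = (
                float(median_abs_deviation(vals, scale=1.0)) if len(vals) else np.nan
            )
        row["pct"] = 100.0 * np.sum(labels == c) / len(labels)
        rows.append(row)
    summary = pd.DataFrame(rows)

    percentages = None
    if sample_ids is not None:
        sid = pd.Series(np.asarray(sample_ids), name="sample_id")
        ct = pd.crosstab(sid, pd.Series(labels, name="cluster"))
        ct = ct.reindex(columns=range(model.final_k), fill_value=0)
        percentages = ct.div(ct.sum(axis=1), axis=0) * 100.0
        percentages.columns = [f"subpop_{c}" for c in percentages.columns]
    return summary, percentages
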