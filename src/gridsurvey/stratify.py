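"""Contextual stratification of the sampling frame.

Gridded covariates (socio-economic, infrastructural, environmental, physical,
climatic) are extracted at the settled cells, categorical variables are
expanded to full one-hot indicators, and the resulting attribute matrix is
reduced by correlation-matrix PCA.  The retained principal-component scores
are clustered with k-means to form contextual strata — partitions of the
frame into more homogeneous geographic contexts (urban/peri-urban/rural and
the like).  The cluster count k is chosen by the analyst; an elbow scan over
the within-cluster sum of squares (WSS) is provided as advisory diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA as _SKPCA

from .grid import SettledCellFrame

__all__ = [
    "CovariateRaster",
    "CovariateStack",
    "PCAResult",
    "KMeansScan",
    "Stratification",
    "extract_covariates",
    "fit_pca",
    "kmeans_scan",
    "suggest_k",
    "assign_strata",
]


@dataclass
class CovariateRaster:
    """A gridded covariate: 2-D array on the frame grid plus metadata."""

    name: str
    array: np.ndarray
    kind: str = "continuous"  # or "categorical"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        self.array = np.asarray(self.array, dtype=float)


@dataclass
class CovariateStack:
    """Cell-by-attribute matrix aligned to a SettledCellFrame.

    ``columns`` records, per column: source variable name, kind
    (continuous / indicator), and the original category for indicators.
    """

    cell_ids: np.ndarray
    matrix: np.ndarray
    columns: pd.DataFrame  # name, source, kind, category

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def extract_covariates(
    frame: SettledCellFrame, rasters: list[CovariateRaster]
) -> CovariateStack:
    """Extract covariate values at settled cells; one-hot categoricals.

    Continuous variables are copied as single columns with missing values
    imputed by the column mean.  Each categorical variable is expanded to one
    indicator column per observed level (full one-hot, no dropped level);
    missing category values are imputed by the modal level.
    """
    frame.require_nonempty("covariate extraction")
    rows = frame.cells["row"].to_numpy()
    cols = frame.cells["col"].to_numpy()
    blocks: list[np.ndarray] = []
    meta: list[dict] = []
    for rast in rasters:
        if rast.array.shape != frame.grid.shape:
            raise ValueError(
                f"covariate {rast.name!r} shape {rast.array.shape} does not "
                f"match grid {frame.grid.shape}"
            )
        values = rast.array[rows, cols]
        if rast.kind == "continuous":
            n_missing = int(np.isnan(values).sum())
            if n_missing:
                if n_missing == len(values):
                    raise ValueError(f"covariate {rast.name!r} is all-missing")
                fill = np.nanmean(values)
                warnings.warn(
                    f"imputed {n_missing} missing value(s) in {rast.name!r} "
                    f"with column mean {fill:.6g}",
                    stacklevel=2,
                )
                values = np.where(np.isnan(values), fill, values)
            blocks.append(values[:, None])
            meta.append(
                {"name": rast.name, "source": rast.name, "kind": "continuous",
                 "category": None}
            )
        else:
            finite = values[~np.isnan(values)]
            if finite.size == 0:
                raise ValueError(f"categorical covariate {rast.name!r} is all-missing")
            if np.isnan(values).any():
                levels_, counts = np.unique(finite, return_counts=True)
                mode = levels_[np.argmax(counts)]
                warnings.warn(
                    f"imputed {int(np.isnan(values).sum())} missing value(s) in "
                    f"{rast.name!r} with modal level {mode:g}",
                    stacklevel=2,
                )
                values = np.where(np.isnan(values), mode, values)
            levels = np.unique(values)
            if len(levels) == 1:
                warnings.warn(
                    f"categorical covariate {rast.name!r} has a single level; "
                    "its indicator column is constant",
                    stacklevel=2,
                )
            for lev in levels:
                blocks.append((values == lev).astype(float)[:, None])
                meta.append(
                    {"name": f"{rast.name}={lev:g}", "source": rast.name,
                     "kind": "indicator", "category": lev}
                )
    if not blocks:
        raise ValueError("no covariates supplied")
    return CovariateStack(
        cell_ids=frame.cell_ids,
        matrix=np.hstack(blocks),
        columns=pd.DataFrame(meta),
    )


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the covariate stack."""

    scores: np.ndarray  # m x q retained scores
    loadings: np.ndarray  # p_kept x q
    explained_variance: np.ndarray  # eigenvalues of the correlation matrix
    explained_variance_ratio: np.ndarray  # all components
    q: int
    kept_columns: list[str]
    dropped_columns: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray

    @property
    def cumulative_variance(self) -> float:
        return float(self.explained_variance_ratio[: self.q].sum())


def fit_pca(stack: CovariateStack, variance_threshold: float = 0.9) -> PCAResult:
    """Standardize columns and decompose; retain components to the threshold.

    Columns are centred and scaled to unit variance (correlation PCA) —
    covariates mix units, so covariance PCA would let the largest-unit
    variable dominate.  Zero-variance columns are dropped with a warning.
    ``q`` is the smallest component count whose cumulative explained variance
    reaches ``variance_threshold``.  Loading signs are fixed so each
    component's largest-magnitude loading is positive, making scores
    reproducible across library versions.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    X = np.asarray(stack.matrix, dtype=float)
    names = list(stack.columns["name"])
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    keep = sds > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropped constant column(s) before PCA: {dropped}", stacklevel=2
        )
    if not keep.any():
        raise ValueError("all covariate columns are constant")
    Z = (X[:, keep] - means[keep]) / sds[keep]
    pca = _SKPCA(n_components=min(Z.shape), svd_solver="full")
    scores_full = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()  # p_kept x n_comp
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip
    scores_full = scores_full * flip
    ratio = pca.explained_variance_ratio_
    q = int(np.searchsorted(np.cumsum(ratio), variance_threshold - 1e-12) + 1)
    q = min(q, len(ratio))
    return PCAResult(
        scores=scores_full[:, :q],
        loadings=loadings[:, :q],
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=ratio,
        q=q,
        kept_columns=[n for n, k in zip(names, keep) if k],
        dropped_columns=dropped,
        column_means=means,
        column_sds=sds,
    )


@dataclass
class KMeansScan:
    """WSS and explained-variance share across candidate cluster counts."""

    k_values: np.ndarray
    wss: np.ndarray
    explained_share: np.ndarray  # 1 - WSS_k / WSS_1
    seed: int
    n_starts: int


def _best_kmeans(
    scores: np.ndarray, k: int, seed: int, n_starts: int,
    warm_centroids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts k-means; optional hierarchical warm start.

    The warm start refines the previous best (k-1)-solution's centroids plus
    the point farthest from them, which guarantees WSS(k) <= WSS(k-1) and
    makes the elbow scan exactly non-increasing.
    """
    m = scores.shape[0]
    if k > m:
        raise ValueError(f"k={k} exceeds number of points m={m}")
    if k == m:
        return np.arange(m), scores.copy(), 0.0
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(scores)
    best = (labels, km.cluster_centers_, float(km.inertia_))
    if warm_centroids is not None and warm_centroids.shape[0] == k - 1:
        d2 = ((scores[:, None, :] - warm_centroids[None]) ** 2).sum(-1).min(1)
        init = np.vstack([warm_centroids, scores[np.argmax(d2)]])
        km2 = KMeans(n_clusters=k, n_init=1, init=init, random_state=seed,
                     algorithm="lloyd")
        labels2 = km2.fit_predict(scores)
        if km2.inertia_ < best[2]:
            best = (labels2, km2.cluster_centers_, float(km2.inertia_))
    return best


def kmeans_scan(
    scores: np.ndarray,
    k_range=range(1, 11),
    seed: int = 0,
    n_starts: int = 25,
) -> KMeansScan:
    """Scan k over ``k_range``; report per-k WSS and explained-variance share.

    WSS(1) is the total sum of squares about the global centroid, so the
    explained share ``1 - WSS_k / WSS_1`` starts at 0 and reaches 1 at k = m.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    m = scores.shape[0]
    k_values = np.asarray(sorted(set(int(k) for k in k_range)))
    if k_values.min() < 1 or k_values.max() > m:
        raise ValueError(f"k_range must lie within [1, m={m}]")
    wss = []
    prev_centroids = None
    for k in k_values:
        if k == 1:
            centroid = scores.mean(axis=0, keepdims=True)
            w = float(((scores - centroid) ** 2).sum())
            prev_centroids = centroid
        else:
            warm = prev_centroids if (prev_centroids is not None
                                      and prev_centroids.shape[0] == k - 1) else None
            _, prev_centroids, w = _best_kmeans(scores, k, seed, n_starts, warm)
        wss.append(w)
    wss = np.asarray(wss)
    total_ss = float(((scores - scores.mean(axis=0)) ** 2).sum())
    share = 1.0 - wss / total_ss if total_ss > 0 else np.zeros_like(wss)
    return KMeansScan(
        k_values=k_values, wss=wss, explained_share=np.clip(share, 0.0, 1.0),
        seed=seed, n_starts=n_starts,
    )


def suggest_k(scan: KMeansScan, tol: float = 1e-6) -> list[int]:
    """Rank candidate k values by elbow strength (advisory only).

    Normalizes the WSS curve to the unit square and ranks interior k by
    perpendicular distance below the chord joining the curve endpoints
    (kneedle-style).  A curve with no bend above ``tol`` yields an empty
    list; the final stratum count is an analyst decision informed by the
    spatial pattern of the clusters, not an automatic choice.
    """
    k = scan.k_values.astype(float)
    w = scan.wss.astype(float)
    if len(k) < 3:
        raise ValueError("elbow scan needs at least 3 values of k")
    kn = (k - k[0]) / (k[-1] - k[0])
    wrange = w[0] - w[-1]
    if wrange <= 0:
        return []
    wn = (w - w[-1]) / wrange
    # signed distance below the chord from (0,1) to (1,0): line kn + wn = 1
    dist = (1.0 - kn - wn) / np.sqrt(2.0)
    interior = slice(1, len(k) - 1)
    cand = [
        (float(d), int(kk))
        for d, kk in zip(dist[interior], scan.k_values[interior])
        if d > tol
    ]
    cand.sort(key=lambda t: (-t[0], t[1]))
    return [kk for _, kk in cand]


@dataclass
class Stratification:
    """Cell-to-stratum assignment plus the diagnostics that produced it."""

    k: int
    labels: np.ndarray  # per-cell stratum id in 0..k-1
    pca: PCAResult | None = None
    scan: KMeansScan | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in 0..k-1")

    @property
    def strata(self) -> np.ndarray:
        return np.arange(self.k)

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def assign_strata(
    scores: np.ndarray,
    k: int,
    seed: int = 0,
    n_starts: int = 25,
    populations: np.ndarray | None = None,
) -> Stratification:
    """Cluster PC scores into k contextual strata.

    Deterministic under a fixed seed.  Labels are relabelled by descending
    mean population of member cells (stratum 0 = most populous context — the
    "high urban status" stratum) so downstream reports are stable; if no
    populations are given, descending cluster size is used instead.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    m = scores.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        raise ValueError(f"k={k} exceeds number of cells m={m}")
    if k == 1:
        raw = np.zeros(m, dtype=int)
    else:
        raw, _, _ = _best_kmeans(scores, k, seed, n_starts)
        if len(np.unique(raw)) < k:
            for retry in range(1, 6):  # rare with k-means++, bounded retries
                raw, _, _ = _best_kmeans(scores, k, seed + 1000 * retry, n_starts)
                if len(np.unique(raw)) == k:
                    break
            else:
                raise RuntimeError(f"k-means produced an empty cluster for k={k}")
    if populations is not None:
        populations = np.asarray(populations, dtype=float)
        key = np.array([populations[raw == c].mean() for c in range(k)])
    else:
        key = np.bincount(raw, minlength=k).astype(float)
    order = np.argsort(-key, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return Stratification(k=k, labels=relabel[raw], seed=seed)
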