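"""Wheat storage quality grading from pesticide-residue trajectories.

Each storage day is summarised by a two-component quality index
Q_i = (d_i, dbar_i): the observed residue concentration and the mean of
the forecast concentrations over the next n days.  Per pesticide, the
Q points are clustered with K-means++ (D^2-weighted probabilistic
seeding followed by Lloyd iterations); the cluster count is selected by
the silhouette coefficient with the Davies-Bouldin index reported as
corroboration.  Clusters are ranked into quality levels by ascending
center concentration — lower residues mean better-preserved wheat, so
Level 1 is best.

Clustering runs in the raw mg/kg space by default (centers are then
directly interpretable as concentrations); set ``standardize=True`` to
z-score the two components first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QualityIndexTable",
    "ClusterModel",
    "ClusterEvaluation",
    "build_quality_index",
    "kmeanspp_seed",
    "kmeans_fit",
    "silhouette",
    "davies_bouldin",
    "select_k",
    "assign_quality_levels",
    "QualityKMeans",
]

logger = logging.getLogger(__name__)


def build_quality_index(observed: np.ndarray, forecasts: dict[int, np.ndarray] | np.ndarray,
                        n: int) -> pd.DataFrame:
    """Per-day quality index rows (d_i, dbar_i).

    Parameters
    ----------
    observed : 1-D array of daily concentrations, day i at index i.
    forecasts : mapping day -> array of next-day predictions
        (forecasts[i][j-1] predicts day i+j), or a 2-D array with row i
        holding the horizon forecast issued at day i.
    n : number of future days averaged into dbar_i (>= 1).

    Returns a frame with columns ``day, d, dbar``; days without a full
    n-day forecast window are dropped (count logged).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    observed = np.asarray(observed, dtype=np.float64)
    if isinstance(forecasts, np.ndarray):
        forecasts = {i: forecasts[i] for i in range(forecasts.shape[0])}
    horizons = [len(np.atleast_1d(v)) for v in forecasts.values()]
    if horizons and max(horizons) < n:
        raise ValueError(f"n={n} exceeds longest available forecast horizon {max(horizons)}")
    rows, dropped = [], 0
    for day in range(len(observed)):
        fc = forecasts.get(day)
        if fc is None or len(np.atleast_1d(fc)) < n:
            dropped += 1
            continue
        rows.append((day, observed[day], float(np.mean(np.atleast_1d(fc)[:n]))))
    if dropped:
        logger.info("quality index: dropped %d day(s) lacking a full %d-day forecast",
                    dropped, n)
    return pd.DataFrame(rows, columns=["day", "d", "dbar"])


# ---------------------------------------------------------------------------
# K-means++ seeding and Lloyd iterations


def kmeanspp_seed(points: np.ndarray, k: int, seed: int | np.random.Generator,
                  first_index: int | None = None) -> np.ndarray:
    """D^2-weighted initial centers.

    The first center is uniform-random over the points; each subsequent
    center is drawn with probability proportional to the squared
    distance from each point to its nearest already-chosen center, so
    far-out points are favoured.  Deterministic given the seed.

    ``first_index`` pins the first center to a given point (useful for
    studying the conditional D^2 law).
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    n_distinct = len(np.unique(points, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if first_index is None:
        first_index = int(rng.integers(len(points)))
    centers = [points[first_index]]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    while len(centers) < k:
        prob = d2 / d2.sum()
        idx = int(rng.choice(len(points), p=prob))
        centers.append(points[idx])
        d2 = np.minimum(d2, np.sum((points - centers[-1]) ** 2, axis=1))
    return np.asarray(centers)


@dataclass
class ClusterModel:
    """A fitted k-means solution in the 2-D quality-index space."""

    k: int
    centers: np.ndarray
    assignments: np.ndarray
    sizes: np.ndarray
    inertia: float  # within-cluster sum of squares
    n_iter: int
    seed: int | None = None
    wcss_trace: list[float] = field(default_factory=list)


def _assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _wcss(points: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(((points - centers[labels]) ** 2).sum())


def kmeans_fit(points: np.ndarray, initial_centers: np.ndarray,
               tolerance: float = 1e-8, max_iter: int = 300) -> ClusterModel:
    """Lloyd iterations from given initial centers.

    Assign each point to its nearest center (Euclidean), recompute
    centers as assigned-point means, and repeat until the largest center
    shift falls below ``tolerance`` or ``max_iter`` is hit.  The
    within-cluster sum of squares is non-increasing across iterations
    (recorded in ``wcss_trace``).  An emptied cluster is re-seeded with
    the point farthest from its former center.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    centers = np.array(initial_centers, dtype=np.float64, copy=True)
    if centers.ndim == 1:
        centers = centers[:, None]
    if len(np.unique(centers, axis=0)) != len(centers):
        raise ValueError("initial centers must be distinct")
    k = len(centers)
    trace: list[float] = []
    labels = _assign(points, centers)
    for it in range(1, max_iter + 1):
        trace.append(_wcss(points, centers, labels))
        new_centers = centers.copy()
        for j in range(k):
            mask = labels == j
            if mask.any():
                new_centers[j] = points[mask].mean(axis=0)
            else:
                far = int(np.argmax(np.sum((points - centers[j]) ** 2, axis=1)))
                logger.info("kmeans: cluster %d emptied; re-seeded with point %d", j, far)
                new_centers[j] = points[far]
        shift = np.max(np.linalg.norm(new_centers - centers, axis=1))
        centers = new_centers
        labels = _assign(points, centers)
        if shift < tolerance:
            break
    inertia = _wcss(points, centers, labels)
    trace.append(inertia)
    sizes = np.bincount(labels, minlength=k)
    return ClusterModel(k=k, centers=centers, assignments=labels, sizes=sizes,
                        inertia=inertia, n_iter=it, wcss_trace=trace)


# ---------------------------------------------------------------------------
# Internal clustering quality indices


def silhouette(points: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette coefficient.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean
    intra-cluster distance (0 for a singleton cluster) and b(i) the
    smallest mean distance from i to the points of any other cluster.
    In [-1, 1]; larger means tighter, better-separated clusters.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    scores = np.empty(len(points))
    for i in range(len(points)):
        own = labels == labels[i]
        n_own = own.sum()
        a = dist[i, own].sum() / (n_own - 1) if n_own > 1 else 0.0
        b = min(dist[i, labels == c].mean() for c in uniq if c != labels[i])
        scores[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(scores.mean())


def davies_bouldin(points: np.ndarray, assignments: np.ndarray,
                   centers: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-case
    (s_i + s_j) / d_ij ratio, where s_i is the mean distance of cluster
    i's points to its center and d_ij the center separation.  >= 0,
    lower is better."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    labels = np.asarray(assignments)
    centers = np.asarray(centers, dtype=np.float64)
    if centers.ndim == 1:
        centers = centers[:, None]
    k = len(centers)
    if k < 2:
        raise ValueError("Davies-Bouldin requires >= 2 clusters")
    spread = np.array([
        np.linalg.norm(points[labels == j] - centers[j], axis=1).mean()
        if (labels == j).any() else 0.0
        for j in range(k)
    ])
    total = 0.0
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            d_ij = np.linalg.norm(centers[i] - centers[j])
            if d_ij == 0:
                raise ValueError(f"coincident centers {i} and {j}: ratio undefined")
            worst = max(worst, (spread[i] + spread[j]) / d_ij)
        total += worst
    return float(total / k)


@dataclass(frozen=True)
class ClusterEvaluation:
    """SC and DBI per candidate k, plus the selections each implies."""

    table: pd.DataFrame  # columns: k, silhouette, davies_bouldin, wcss
    chosen_k: int        # argmax silhouette
    dbi_k: int           # argmin Davies-Bouldin

    @property
    def criteria_agree(self) -> bool:
        return self.chosen_k == self.dbi_k


def _best_of_seeds(points: np.ndarray, k: int, seeds: list[int]) -> ClusterModel:
    best = None
    for s in seeds:
        init = kmeanspp_seed(points, k, s)
        try:
            model = kmeans_fit(points, init)
        except ValueError:  # duplicate sampled centers
            continue
        if best is None or model.inertia < best.inertia:
            best = model
            best.seed = s
    if best is None:
        raise ValueError(f"no valid k-means fit for k={k}")
    return best


def select_k(points: np.ndarray, k_range=range(2, 8),
             seeds: list[int] | int = 10,
             base_seed: int = 0) -> tuple[ClusterEvaluation, dict[int, ClusterModel]]:
    """Fit each candidate k (best WCSS over restarts) and tabulate SC/DBI.

    The chosen k maximises the silhouette coefficient; the DBI argmin is
    reported alongside, and any disagreement between the two criteria is
    surfaced in the evaluation rather than silently resolved.
    """
    points = np.asarray(points, dtype=np.float64)
    if isinstance(seeds, int):
        seeds = [base_seed + 1000 * i for i in range(seeds)]
    rows, models = [], {}
    for k in k_range:
        model = _best_of_seeds(points, k, seeds)
        sc = silhouette(points, model.assignments)
        dbi = davies_bouldin(points, model.assignments, model.centers)
        models[k] = model
        rows.append({"k": k, "silhouette": sc, "davies_bouldin": dbi,
                     "wcss": model.inertia})
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["silhouette"].idxmax(), "k"])
    dbi_k = int(table.loc[table["davies_bouldin"].idxmin(), "k"])
    if chosen != dbi_k:
        logger.warning("cluster-count criteria disagree: SC picks k=%d, DBI picks k=%d",
                       chosen, dbi_k)
    return ClusterEvaluation(table=table, chosen_k=chosen, dbi_k=dbi_k), models


def assign_quality_levels(model: ClusterModel) -> np.ndarray:
    """Quality level per cluster, 1 = best.

    Clusters are ranked by ascending first center coordinate (observed
    concentration), ties broken by the second coordinate: lower residue
    means better wheat.  Returns ``levels[j]`` = level of cluster j.
    """
    centers = np.atleast_2d(model.centers)
    second = centers[:, 1] if centers.shape[1] > 1 else np.zeros(len(centers))
    order = np.lexsort((second, centers[:, 0]))
    levels = np.empty(len(centers), dtype=int)
    levels[order] = np.arange(1, len(centers) + 1)
    return levels


class QualityKMeans:
    """Estimator-style wrapper: K-means++ clustering of quality-index
    points with quality-level labelling.

    Parameters
    ----------
    n_clusters : number of clusters k.
    n_restarts : K-means++ restarts; the lowest-WCSS fit is kept.
    tolerance, max_iter : Lloyd stopping rule.
    standardize : z-score the columns before clustering (centers are
        reported back in the original units).
    random_state : seed for the restart sequence.
    """

    def __init__(self, n_clusters: int = 3, n_restarts: int = 10,
                 tolerance: float = 1e-8, max_iter: int = 300,
                 standardize: bool = False, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.tolerance = tolerance
        self.max_iter = max_iter
        self.standardize = standardize
        self.random_state = random_state

    # minimal get/set_params so the class composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("n_clusters", "n_restarts", "tolerance", "max_iter",
                 "standardize", "random_state")}

    def set_params(self, **params) -> "QualityKMeans":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "QualityKMeans":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if self.standardize:
            self._mean = X.mean(axis=0)
            self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
            Xw = (X - self._mean) / self._sd
        else:
            self._mean, self._sd = np.zeros(X.shape[1]), np.ones(X.shape[1])
            Xw = X
        seeds = [self.random_state + 1000 * i for i in range(self.n_restarts)]
        model = None
        for s in seeds:
            init = kmeanspp_seed(Xw, self.n_clusters, s)
            try:
                cand = kmeans_fit(Xw, init, self.tolerance, self.max_iter)
            except ValueError:
                continue
            if model is None or cand.inertia < model.inertia:
                model = cand
                model.seed = s
        if model is None:
            raise ValueError("k-means failed for every restart seed")
        model.centers = model.centers * self._sd + self._mean
        self.model_ = model
        self.cluster_centers_ = model.centers
        self.labels_ = model.assignments
        self.inertia_ = model.inertia
        self.quality_levels_ = assign_quality_levels(model)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        return _assign((X - self._mean) / self._sd,
                       (self.cluster_centers_ - self._mean) / self._sd)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
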