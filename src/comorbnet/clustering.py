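"""Age-incidence clustering with composite validity scoring.

Diseases are represented by 91-dimensional vectors of earliest-onset counts
(ages 0..90), scaled to unit Euclidean length so that shape, not caseload,
drives similarity.  Several clustering methods are run over a range of
cluster counts k; each solution is scored with a battery of internal validity
indices, all sign-aligned so larger is better.  Indices that vary
monotonically with k for every method are discarded (they would always point
to an end of the search range), the survivors are z-standardized over the
whole (method, k) grid and averaged into one composite per k, and the
locally optimal k is selected.  Final labels always come from Ward-linkage
hierarchical clustering at the chosen k, which yields compact clusters of
similar size and is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .ingest import N_AGE_BINS, OnsetHistogramSet

logger = logging.getLogger(__name__)

__all__ = [
    "ValidityGrid",
    "ClusterSelection",
    "build_vectors",
    "cluster_solutions",
    "score_grid",
    "remove_monotonic",
    "select_k",
    "cluster_profiles",
    "choose_clusters",
    "DEFAULT_METHODS",
    "DEFAULT_MEASURES",
]

DEFAULT_METHODS = ("ward", "kmeans", "average")
DEFAULT_MEASURES = ("silhouette", "calinski_harabasz", "dunn", "davies_bouldin", "connectivity", "gap")


def build_vectors(histograms: OnsetHistogramSet) -> pd.DataFrame:
    """Unit-normalized incidence vectors, one row per disease, 91 age columns."""
    rows = {}
    for disease in sorted(histograms.histograms):
        h = histograms.histograms[disease].astype(float)
        norm = np.linalg.norm(h)
        if norm == 0:
            raise ValueError(f"disease {disease!r} has an all-zero onset histogram")
        rows[disease] = h / norm
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=range(N_AGE_BINS))
    frame.index.name = "disease"
    return frame


def cluster_solutions(
    vectors: pd.DataFrame,
    methods: Sequence[str] = DEFAULT_METHODS,
    k_range: Iterable[int] = range(2, 11),
    seed: int = 0,
) -> dict[tuple[str, int], np.ndarray]:
    """Labelings for every (method, k); Euclidean distance on unit vectors.

    Hierarchical methods (``ward``, ``average``, ``complete``) cut one
    deterministic dendrogram per method; ``kmeans`` uses multiple seeded
    restarts.  Every labeling is guaranteed to have exactly k nonempty
    clusters (a k-means run that collapses clusters is rerun with more
    restarts, and raises if it still collapses).
    """
    ks = sorted(set(k_range))
    x = vectors.to_numpy(dtype=float)
    if not methods:
        raise ValueError("no clustering methods given")
    if ks and ks[-1] > len(vectors):
        raise ValueError(f"k={ks[-1]} exceeds the {len(vectors)} diseases available")

    out: dict[tuple[str, int], np.ndarray] = {}
    trees = {m: linkage(x, method=m) for m in methods if m in ("ward", "average", "complete", "single")}
    for method in methods:
        for k in ks:
            if method in trees:
                labels = fcluster(trees[method], t=k, criterion="maxclust") - 1
            elif method == "kmeans":
                labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
                if len(np.unique(labels)) != k:
                    labels = KMeans(n_clusters=k, n_init=50, random_state=seed + 1).fit_predict(x)
            else:
                raise ValueError(f"unknown clustering method: {method!r}")
            if len(np.unique(labels)) != k:
                raise ValueError(f"{method} produced {len(np.unique(labels))} clusters instead of {k}")
            out[(method, k)] = labels
    return out


# ---------------------------------------------------------------------------
# Validity measures.  Each returns a score where larger = better clustering
# (indices that natively decrease with quality are negated), or raises on a
# degenerate labeling; score_grid records failures as NaN.


def _dunn(x: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-cluster distance over maximum within-cluster diameter."""
    dist = squareform(pdist(x))
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("Dunn index needs at least two clusters")
    diam = 0.0
    for c in ids:
        members = labels == c
        if members.sum() > 1:
            diam = max(diam, dist[np.ix_(members, members)].max())
    if diam == 0:
        raise ValueError("all clusters are singletons or duplicate points")
    sep = min(
        dist[np.ix_(labels == a, labels == b)].min()
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    )
    return sep / diam


def _connectivity(x: np.ndarray, labels: np.ndarray, n_neighbors: int = 10) -> float:
    """Negated Handl connectivity: penalty 1/j when a point's j-th nearest
    neighbour lands in another cluster.  Lower penalty (closer to 0) is better,
    hence the sign flip."""
    n = len(x)
    L = min(n_neighbors, n - 1)
    dist = squareform(pdist(x))
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")[:, :L]
    weights = 1.0 / np.arange(1, L + 1)
    penalty = float(np.sum((labels[order] != labels[:, None]) * weights))
    return -penalty


def _gap(x: np.ndarray, labels: np.ndarray, rng: np.random.Generator, n_ref: int = 10) -> float:
    """Gap statistic: log dispersion of uniform reference data (clustered with
    k-means at the same k) minus log dispersion of the given labeling."""
    k = len(np.unique(labels))
    log_w = np.log(_pooled_dispersion(x, labels))
    lo, hi = x.min(axis=0), x.max(axis=0)
    ref = np.empty(n_ref)
    for b in range(n_ref):
        sample = rng.uniform(lo, hi, size=x.shape)
        ref_labels = KMeans(n_clusters=k, n_init=3, random_state=int(rng.integers(2**31))).fit_predict(sample)
        ref[b] = np.log(_pooled_dispersion(sample, ref_labels))
    return float(ref.mean() - log_w)


def _pooled_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        members = x[labels == c]
        total += float(((members - members.mean(axis=0)) ** 2).sum())
    if total <= 0:
        raise ValueError("zero within-cluster dispersion")
    return total


def _measure_registry(seed: int) -> dict[str, Callable[[np.ndarray, np.ndarray], float]]:
    rng = np.random.default_rng(seed)
    return {
        "silhouette": lambda x, l: float(silhouette_score(x, l)),
        "calinski_harabasz": lambda x, l: float(calinski_harabasz_score(x, l)),
        "davies_bouldin": lambda x, l: -float(davies_bouldin_score(x, l)),
        "dunn": _dunn,
        "connectivity": _connectivity,
        "gap": lambda x, l: _gap(x, l, rng),
    }


@dataclass
class ValidityGrid:
    """Validity scores indexed by (method, k) rows and measure columns.

    All scores are sign-aligned (larger = better); NaN marks a measure that
    failed on that labeling rather than a silently dropped cell.
    """

    scores: pd.DataFrame
    k_range: tuple[int, ...]
    methods: tuple[str, ...]
    measures: tuple[str, ...]

    def write(self, path) -> None:
        self.scores.to_csv(path)


def score_grid(
    labelings: dict[tuple[str, int], np.ndarray],
    vectors: pd.DataFrame,
    measures: Sequence[str] = DEFAULT_MEASURES,
    seed: int = 0,
) -> ValidityGrid:
    """Score every labeling with every validity measure."""
    registry = _measure_registry(seed)
    unknown = [m for m in measures if m not in registry]
    if unknown:
        raise ValueError(f"unknown measures: {unknown}; available: {sorted(registry)}")
    x = vectors.to_numpy(dtype=float)
    index = pd.MultiIndex.from_tuples(sorted(labelings), names=["method", "k"])
    scores = pd.DataFrame(index=index, columns=list(measures), dtype=float)
    for method, k in index:
        labels = labelings[(method, k)]
        for m in measures:
            try:
                scores.loc[(method, k), m] = registry[m](x, labels)
            except ValueError as exc:
                logger.warning("measure %s failed for (%s, k=%d): %s", m, method, k, exc)
                scores.loc[(method, k), m] = np.nan
    methods = tuple(sorted({m for m, _ in labelings}))
    ks = tuple(sorted({k for _, k in labelings}))
    return ValidityGrid(scores=scores, k_range=ks, methods=methods, measures=tuple(measures))


def _strictly_monotone(values: np.ndarray) -> bool:
    if np.isnan(values).any() or len(values) < 2:
        return False
    diffs = np.diff(values)
    return bool((diffs > 0).all() or (diffs < 0).all())


def remove_monotonic(grid: ValidityGrid) -> tuple[ValidityGrid, list[str]]:
    """Drop measures that are strictly monotone in k for every method.

    Such a measure is extremized at an end of the k search range regardless of
    the data, so it cannot mark an interior optimum.  Strict (not non-strict)
    monotonicity is required: a plateau still carries peak information.
    """
    removed = []
    for measure in grid.measures:
        per_method = [
            grid.scores.loc[method][measure].to_numpy(dtype=float) for method in grid.methods
        ]
        if all(_strictly_monotone(v) for v in per_method):
            removed.append(measure)
    kept = [m for m in grid.measures if m not in removed]
    if not kept:
        raise ValueError(
            "every validity measure is monotone in k; widen the k range or choose other measures"
        )
    return (
        ValidityGrid(grid.scores[kept].copy(), grid.k_range, grid.methods, tuple(kept)),
        removed,
    )


@dataclass
class ClusterSelection:
    chosen_k: int
    composite_by_k: dict[int, float]
    removed_measures: list[str]
    final_labels: dict[str, int]
    cluster_names: dict[int, str] | None = None


def select_k(
    grid: ValidityGrid,
    labelings: dict[tuple[str, int], np.ndarray],
    vectors: pd.DataFrame,
    removed_measures: list[str] | None = None,
    final_method: str = "ward",
) -> ClusterSelection:
    """Pick the locally optimal k from the composite validity score.

    Each retained measure is z-standardized (zero mean, unit variance) across
    all (method, k) cells jointly, then the standardized scores are averaged
    over methods and measures at each k.  The chosen k is the local maximum of
    this composite — strictly above both neighbours, or above the single
    neighbour at a boundary; among several local maxima the highest wins, and
    ties break toward smaller k (larger clusters mean more testable pairs, so
    fewer, bigger clusters are preferred only when the score says so).  Final
    labels come from the deterministic ``final_method`` dendrogram at the
    chosen k.
    """
    z = grid.scores.copy()
    for m in grid.measures:
        col = z[m]
        mu, sd = col.mean(), col.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"measure {m!r} is constant over the grid; cannot standardize")
        z[m] = (col - mu) / sd
    composite = z.groupby(level="k").mean().mean(axis=1)
    ks = list(composite.index)
    values = composite.to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        raise ValueError("composite score is flat across k; no optimum exists")

    maxima = []
    for i, k in enumerate(ks):
        left_ok = i == 0 or values[i] > values[i - 1]
        right_ok = i == len(ks) - 1 or values[i] > values[i + 1]
        if left_ok and right_ok:
            maxima.append((k, values[i]))
    if maxima:
        best = max(v for _, v in maxima)
        chosen_k = min(k for k, v in maxima if v == best)
    else:
        # plateaued composite with no strict peak: fall back to the global max
        best = values.max()
        chosen_k = min(k for k, v in zip(ks, values) if v == best)

    key = (final_method, chosen_k)
    if key not in labelings:
        raise ValueError(f"no {final_method} labeling available at k={chosen_k}")
    final = {str(d): int(c) for d, c in zip(vectors.index, labelings[key])}
    return ClusterSelection(
        chosen_k=chosen_k,
        composite_by_k={int(k): float(v) for k, v in zip(ks, values)},
        removed_measures=list(removed_measures or []),
        final_labels=final,
    )


def cluster_profiles(labels: dict[str, int], histograms: OnsetHistogramSet) -> pd.DataFrame:
    """Per-cluster mean of member unit incidence vectors (one row per cluster)."""
    vectors = build_vectors(histograms)
    frame = vectors.assign(_cluster=[labels[d] for d in vectors.index])
    return frame.groupby("_cluster").mean().rename_axis("cluster")


def choose_clusters(
    histograms: OnsetHistogramSet,
    methods: Sequence[str] = DEFAULT_METHODS,
    k_range: Iterable[int] = range(2, 11),
    measures: Sequence[str] = DEFAULT_MEASURES,
    seed: int = 0,
) -> ClusterSelection:
    """Full pipeline: vectors -> solutions -> scores -> pruning -> selection."""
    vectors = build_vectors(histograms)
    labelings = cluster_solutions(vectors, methods, k_range, seed)
    grid = score_grid(labelings, vectors, measures, seed)
    pruned, removed = remove_monotonic(grid)
    return select_k(pruned, labelings, vectors, removed_measures=removed)
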