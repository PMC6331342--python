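"""Resampled k-means consensus clustering and OXPHOS subgroup labeling.

Tumor samples are stratified on their ETC protein panel by consensus
clustering: many k-means runs on random 80% subsamples, tallying for every
sample pair how often it co-clusters among the iterations where it was
co-sampled.  The consensus matrix (entries in [0, 1]; 1 = the pair always
clustered together) feeds optimal-k selection (minimum proportion of
ambiguous clustering, with CDF delta-area diagnostics), final assignment by
hierarchical clustering on 1 - consensus, and the low-/high-OXPHOS labeling
of the two-group solution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .prep import ProteinMatrix, mean_panel_score

logger = logging.getLogger(__name__)

LOW_OXPHOS = "low-OXPHOS"
HIGH_OXPHOS = "high-OXPHOS"


@dataclass
class ConsensusResult:
    """Per-k consensus matrices with selection diagnostics."""

    samples: list[str]
    consensus: dict[int, np.ndarray]
    cosample_counts: dict[int, np.ndarray]
    assignments: dict[int, np.ndarray]
    chosen_k: int | None = None
    cdf_area: dict[int, float] = field(default_factory=dict)
    delta_area: dict[int, float] = field(default_factory=dict)
    pac: dict[int, float] = field(default_factory=dict)
    low_confidence: bool = False


def _panel_values(m: ProteinMatrix, panel: list[str] | None) -> np.ndarray:
    """Panel-restricted value array with per-protein median imputation."""
    values = m.values if panel is None else m.values[[p for p in panel if p in m.values.columns]]
    if values.shape[1] == 0:
        raise ValueError("no panel protein present in matrix")
    if values.isna().all(axis=1).any():
        raise ValueError("a sample is missing every panel protein")
    filled = values.fillna(values.median(axis=0, skipna=True))
    return filled.to_numpy(dtype=float)


def consensus_matrix(
    x: np.ndarray,
    k: int,
    iterations: int = 1000,
    resample_fraction: float = 0.8,
    n_init: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Co-clustering frequencies over resampled k-means runs.

    Each iteration draws ``floor(resample_fraction * n)`` samples without
    replacement and clusters them with k-means (Euclidean, ``n_init``
    random restarts, best inertia kept).  consensus(i, j) = co-cluster
    count / co-sample count, with the diagonal forced to 1; pairs never
    co-sampled get 0 with a warning.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if not (0 < resample_fraction <= 1):
        raise ValueError("resample_fraction must be in (0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    n = x.shape[0]
    sub_n = int(np.floor(resample_fraction * n))
    if k >= sub_n:
        raise ValueError(f"k={k} must be below the subsample size {sub_n}")

    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(iterations):
        idx = rng.choice(n, size=sub_n, replace=False)
        km = KMeans(
            n_clusters=k,
            n_init=n_init,
            random_state=int(rng.integers(2**31 - 1)),
        )
        labels = km.fit_predict(x[idx])
        co_sample[np.ix_(idx, idx)] += 1
        same = labels[:, None] == labels[None, :]
        co_cluster[np.ix_(idx, idx)] += same
    never = co_sample == 0
    if never[np.triu_indices(n, k=1)].any():
        warnings.warn(
            "some sample pairs were never co-sampled; their consensus is set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(never, 0.0, co_cluster / np.maximum(co_sample, 1))
    np.fill_diagonal(consensus, 1.0)
    return consensus, co_sample


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus values."""
    vals = np.sort(consensus[np.triu_indices(consensus.shape[0], k=1)])
    # right-continuous step CDF integrated over [0, 1]
    grid = np.unique(np.concatenate([[0.0], vals, [1.0]]))
    cdf = np.searchsorted(vals, grid, side="right") / len(vals)
    return float(np.sum(cdf[:-1] * np.diff(grid)))


def pac_score(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: off-diagonal mass in (lower, upper)."""
    vals = consensus[np.triu_indices(consensus.shape[0], k=1)]
    return float(np.mean((vals > lower) & (vals < upper)))


def assign_clusters(consensus: np.ndarray, k: int) -> np.ndarray:
    """Cut average-linkage hierarchy on 1 - consensus into k groups.

    Labels are renumbered by descending group size (label 0 = largest).
    """
    n = consensus.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    dist = 1.0 - consensus
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(tree, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = {old: new for new, old in enumerate(sizes.index)}
    return np.array([order[r] for r in raw])


def select_k(
    consensus_by_k: dict[int, np.ndarray],
    delta_threshold: float = 0.1,
    pac_window: tuple[float, float] = (0.1, 0.9),
    method: str = "pac",
) -> tuple[int, dict[int, float], dict[int, float], dict[int, float], bool]:
    """Optimal k from consensus stability.

    Computes, for every k, the area A(k) under the empirical CDF of
    off-diagonal consensus values, the relative change
    Delta(k) = (A(k) - A(k-1)) / A(k-1) (Delta(k_min) = A(k_min)), and the
    proportion of ambiguous clustering (PAC).

    The default selection (``method="pac"``) takes the k minimizing PAC —
    the cleanest consensus matrix — breaking exact ties toward the larger k
    (a merge of true clusters can be perfectly stable, a split of one never
    is).  ``method="delta"`` instead takes the largest k whose Delta exceeds
    ``delta_threshold`` (falling back to argmax Delta); on unambiguous
    two-group data this threshold reading systematically inflates k, because
    splitting a homogeneous group still adds CDF area, which is why PAC is
    the default.  The selection is flagged low-confidence when even the
    chosen k leaves more than 20% of pairs ambiguous (min PAC > 0.2).
    """
    ks = sorted(consensus_by_k)
    if len(ks) < 2:
        raise ValueError("k range must contain at least two values")
    area = {k: _cdf_area(consensus_by_k[k]) for k in ks}
    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    pac = {k: pac_score(consensus_by_k[k], *pac_window) for k in ks}

    if max(area.values()) - min(area.values()) < 1e-12:
        warnings.warn("degenerate consensus matrices; returning smallest k", stacklevel=2)
        return ks[0], area, delta, pac, True

    if method == "pac":
        best = min(pac.values())
        chosen = max(k for k in ks if pac[k] == best)
    elif method == "delta":
        exceeding = [k for k in ks if delta[k] > delta_threshold]
        chosen = max(exceeding) if exceeding else max(ks, key=lambda k: delta[k])
    else:
        raise ValueError(f"unknown selection method: {method}")
    low_confidence = min(pac.values()) > 0.2
    if low_confidence:
        logger.warning("every k has PAC > 0.2; cluster structure is weak")
    return chosen, area, delta, pac, low_confidence


def consensus_cluster(
    m: ProteinMatrix,
    panel: list[str] | None = None,
    k_range: range | list[int] = range(2, 7),
    iterations: int = 1000,
    resample_fraction: float = 0.8,
    delta_threshold: float = 0.1,
    selection_method: str = "pac",
    seed: int | np.random.Generator = 0,
) -> ConsensusResult:
    """Full consensus pipeline over a k range, with optimal-k selection."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = _panel_values(m, panel)
    result = ConsensusResult(samples=m.samples, consensus={}, cosample_counts={}, assignments={})
    for k in sorted(k_range):
        cons, counts = consensus_matrix(
            x, k, iterations=iterations, resample_fraction=resample_fraction, rng=rng
        )
        result.consensus[k] = cons
        result.cosample_counts[k] = counts
        result.assignments[k] = assign_clusters(cons, k)
    chosen, area, delta, pac, low_conf = select_k(
        result.consensus, delta_threshold=delta_threshold, method=selection_method
    )
    result.chosen_k = chosen
    result.cdf_area = area
    result.delta_area = delta
    result.pac = pac
    result.low_confidence = low_conf
    return result


@dataclass(frozen=True)
class OxphosLabeling:
    labels: pd.Series  # per-sample {low-OXPHOS, high-OXPHOS}
    cluster_scores: dict[int, float]  # per-cluster mean panel score


def label_oxphos(cluster_labels: np.ndarray, panel_scores: pd.Series) -> OxphosLabeling:
    """Name the two clusters by mean panel score: larger mean = high-OXPHOS."""
    clusters = np.unique(cluster_labels)
    if len(clusters) != 2:
        raise ValueError("OXPHOS labeling is defined only for the two-cluster solution")
    scores = panel_scores.to_numpy(dtype=float)
    means = {int(c): float(np.nanmean(scores[cluster_labels == c])) for c in clusters}
    c0, c1 = sorted(means)
    if means[c0] == means[c1]:
        warnings.warn("equal cluster means; labeling the smaller cluster high-OXPHOS", stacklevel=2)
        sizes = {c: int(np.sum(cluster_labels == c)) for c in (c0, c1)}
        high = min(sizes, key=lambda c: (sizes[c], c))
    else:
        high = max(means, key=lambda c: means[c])
    labels = pd.Series(
        np.where(cluster_labels == high, HIGH_OXPHOS, LOW_OXPHOS),
        index=panel_scores.index,
        name="oxphos",
    )
    return OxphosLabeling(labels=labels, cluster_scores=means)


def ward_order(m: ProteinMatrix, panel: list[str] | None = None) -> tuple[np.ndarray, list[int]]:
    """Ward linkage on Euclidean distances; returns (merge tree, leaf order).

    Missing values are imputed by per-protein median before computing
    distances (logged), matching the imputation used for clustering.
    """
    if m.values.shape[0] < 2:
        raise ValueError("ward_order needs at least two samples")
    if m.values.isna().any().any():
        logger.info("imputing missing values by protein median before Ward linkage")
    x = _panel_values(m, panel)
    tree = linkage(x, method="ward", metric="euclidean")
    from scipy.cluster.hierarchy import leaves_list

    return tree, leaves_list(tree).tolist()
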