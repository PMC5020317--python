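"""Volunteer engagement profiling by cluster analysis.

The four engagement metrics are min-max normalised to [0, 1], explored
with Ward hierarchical clustering (within-group-sum-of-squares by k as
an elbow diagnostic), partitioned with best-of-restarts k-means, and
validated with the average silhouette width (ASW).  The number of
profiles k is chosen as the argmax of ASW over the candidate range; a
partition is accepted as sufficient only when ASW >= 0.51.  With k = 3
the profiles are named, in ascending mean observation count,
``dabbler`` / ``steady`` / ``enthusiast``.

Usage::

    profiler = EngagementProfiler(metrics_table, k_range=range(2, 9))
    results = profiler.fit(seed=17)
    results.summary()
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .engagement import METRIC_COLUMNS

__all__ = [
    "EngagementProfiler",
    "ProfileResults",
    "normalize_metrics",
    "ward_tree",
    "select_k",
    "kmeans_profiles",
    "average_silhouette_width",
    "metric_correlations",
    "ASW_THRESHOLD",
    "PROFILE_NAMES",
]

ASW_THRESHOLD = 0.51
PROFILE_NAMES = ("dabbler", "steady", "enthusiast")


def normalize_metrics(table: pd.DataFrame, columns=METRIC_COLUMNS) -> np.ndarray:
    """Min-max scale each metric column to span [0, 1].

    A constant column has no range and is mapped to all zeros (with a
    warning); at least two volunteers are required.
    """
    if len(table) < 2:
        raise ValueError("normalisation needs at least 2 volunteers")
    X = table[list(columns)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("engagement metrics contain non-finite values")
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    degenerate = rng == 0
    if degenerate.any():
        names = [c for c, d in zip(columns, degenerate) if d]
        warnings.warn(f"constant metric column(s) mapped to 0: {names}")
    rng = np.where(degenerate, 1.0, rng)
    Xn = (X - lo) / rng
    Xn[:, degenerate] = 0.0
    return Xn


def ward_tree(X: np.ndarray, k_max: int = 8):
    """Ward-linkage agglomeration plus the WSS-by-k elbow curve.

    Returns ``(Z, wss_by_k)`` where ``Z`` is a scipy linkage matrix and
    ``wss_by_k`` maps each k in 1..k_max to the within-group sum of
    squares of the partition obtained by cutting the tree at k.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("ward_tree requires finite values")
    Z = linkage(X, method="ward")
    wss_by_k = {}
    for k in range(1, min(k_max, len(X)) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        wss_by_k[k] = _wss(X, labels)
    return Z, wss_by_k


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def kmeans_profiles(
    X: np.ndarray, k: int, seed: int = 0, n_restarts: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Best-of-restarts Lloyd k-means with k-means++ seeding.

    Returns ``(labels, centroids)``; deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if k < 1 or k > len(X):
        raise ValueError(f"k={k} out of range for n={len(X)} points")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_


def average_silhouette_width(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score (b - a) / max(a, b) over all points.

    Requires at least two non-empty clusters; points in singleton
    clusters contribute 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least two clusters")
    return float(silhouette_score(np.asarray(X, dtype=float), labels))


def _elbow_k(wss_by_k: dict[int, float], candidates) -> int:
    """Elbow of the WSS curve: the last large relative improvement.

    For each candidate k the drop ratio ``(WSS(k-1) - WSS(k)) /
    (WSS(k) - WSS(k+1))`` measures how much better k does than its
    successor; the argmax is the elbow.  Requires WSS at k+1 for the
    largest candidate.
    """
    drops = {
        k: wss_by_k[k - 1] - wss_by_k[k] for k in wss_by_k if k - 1 in wss_by_k
    }
    tss = max(wss_by_k.get(1, max(wss_by_k.values())), 1.0)
    usable = [k for k in candidates if k in drops and k + 1 in drops]
    if not usable:
        raise ValueError("WSS curve too short for elbow selection")
    return max(usable, key=lambda k: drops[k] / max(drops[k + 1], 1e-12 * tss))


def select_k(
    wss_by_k: dict[int, float],
    asw_by_k: dict[int, float],
    threshold: float = ASW_THRESHOLD,
    policy: str = "elbow",
) -> int | None:
    """Choose the number of profiles and validate it by silhouette.

    ``policy="elbow"`` (default): k sits at the elbow of the Ward WSS
    curve (the last large relative improvement) and is accepted only if
    its ASW reaches ``threshold`` — the silhouette is a sufficiency
    check, as in the >= 0.51 rule, not an objective.  On engagement
    cohorts the cluster geometry is hierarchical (two adjacent profiles
    plus one extreme one), where maximising ASW collapses to k = 2;
    the elbow recovers the finer structure.

    ``policy="argmax"``: k maximising ASW, accepted under the same
    threshold (with ``threshold=-1`` this always returns the argmax).

    Returns None ("insufficient partitioning") when the chosen k fails
    the threshold.
    """
    if not asw_by_k:
        raise ValueError("no candidate k supplied")
    if policy == "argmax":
        k = max(sorted(asw_by_k), key=lambda kk: asw_by_k[kk])
    elif policy == "elbow":
        k = _elbow_k(wss_by_k, sorted(asw_by_k))
    else:
        raise ValueError(f"unknown selection policy {policy!r}")
    if asw_by_k[k] < threshold:
        return None
    return k


def metric_correlations(table: pd.DataFrame, columns=METRIC_COLUMNS):
    """Pairwise Spearman rank correlations among the engagement metrics.

    Returns ``(rho, p)`` DataFrames; constant columns yield NaN.
    """
    if len(table) < 3:
        raise ValueError("correlations need at least 3 volunteers")
    cols = list(columns)
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i >= j:
                continue
            x, y = table[a].to_numpy(float), table[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = spearmanr(x, y)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval


@dataclass
class ProfileResults:
    """Fitted engagement-profile clustering.

    Attributes
    ----------
    k : selected number of profiles (argmax-ASW k, or the forced k).
    accepted : True when the best ASW reaches the sufficiency threshold.
    assignments : profile name per volunteer (index = recorder_id).
    centroids_normalized / centroids_raw : k x 4 centroid matrices,
        rows ordered by ascending mean raw ``n_observations``.
    wss_by_k : Ward elbow diagnostic.
    asw_by_k : silhouette by candidate k; ``asw`` is the selected one.
    """

    model: "EngagementProfiler"
    k: int
    accepted: bool
    seed: int
    assignments: pd.Series
    labels: np.ndarray
    centroids_normalized: pd.DataFrame
    centroids_raw: pd.DataFrame
    wss_by_k: dict[int, float]
    asw_by_k: dict[int, float]
    asw: float

    @property
    def profile_names(self) -> list[str]:
        return list(self.centroids_raw.index)

    def summary(self) -> pd.DataFrame:
        """Profile table: raw-unit mean centroids, counts and shares.

        Percentages are rounded to the nearest whole number; the share
        of single-day volunteers within each profile is included.
        """
        raw = self.model.metrics
        out = []
        n_total = len(raw)
        for name in self.profile_names:
            mask = (self.assignments == name).to_numpy()
            sub = raw[mask]
            row = {
                "profile": name,
                "n_observations": sub["n_observations"].mean(),
                "activity_ratio": sub["activity_ratio"].mean(),
                "relative_activity_duration": sub["relative_activity_duration"].mean(),
                "variation_in_periodicity": sub["variation_in_periodicity"].mean(),
                "n_volunteers": int(mask.sum()),
                "percent_volunteers": int(round(100 * mask.sum() / n_total)),
            }
            if "single_day_flag" in raw.columns and mask.sum():
                row["percent_single_day"] = int(
                    round(100 * sub["single_day_flag"].mean())
                )
            out.append(row)
        return pd.DataFrame(out).set_index("profile")

    def diagnostics(self) -> dict:
        return {
            "k": self.k,
            "accepted": self.accepted,
            "asw": self.asw,
            "asw_by_k": {int(k): float(v) for k, v in self.asw_by_k.items()},
            "wss_by_k": {int(k): float(v) for k, v in self.wss_by_k.items()},
            "seed": self.seed,
        }


class EngagementProfiler:
    """Clustering model over a volunteer engagement-metrics table.

    Parameters
    ----------
    metrics
        Output of :func:`citrec.engagement.engagement_table` (or any
        table with the four metric columns, indexed by recorder).
    k_range
        Candidate profile counts, default 2..8.
    asw_threshold
        Minimum average silhouette width for a partition to be accepted
        as a sufficient partitioning (default 0.51).
    n_restarts
        k-means restarts per candidate k.
    """

    def __init__(
        self,
        metrics: pd.DataFrame,
        k_range=range(2, 9),
        asw_threshold: float = ASW_THRESHOLD,
        n_restarts: int = 25,
        selection: str = "elbow",
    ):
        missing = [c for c in METRIC_COLUMNS if c not in metrics.columns]
        if missing:
            raise ValueError(f"metrics table lacks columns {missing}")
        self.metrics = metrics
        self.k_range = [k for k in k_range if 2 <= k <= len(metrics)]
        if not self.k_range:
            raise ValueError("k_range empty after bounding by cohort size")
        self.asw_threshold = asw_threshold
        self.n_restarts = n_restarts
        self.selection = selection

    @classmethod
    def from_records(cls, records: pd.DataFrame, window=None, **kwargs):
        """Build directly from cleaned records via the engagement module."""
        from .engagement import engagement_table

        return cls(engagement_table(records, window), **kwargs)

    def fit(self, seed: int = 0, k: int | None = None) -> ProfileResults:
        """Cluster the normalised metrics and validate the partition.

        With ``k=None`` every candidate in ``k_range`` is fitted and the
        argmax-ASW solution selected; passing ``k`` forces that cluster
        count (ASW is still reported, with ``accepted`` reflecting the
        threshold).
        """
        X = normalize_metrics(self.metrics)
        # WSS one step past k_max so the largest candidate has a drop ratio.
        _, wss_by_k = ward_tree(X, k_max=max(self.k_range) + 1)

        candidates = [k] if k is not None else self.k_range
        fits, asw_by_k = {}, {}
        for kk in candidates:
            labels, centers = kmeans_profiles(X, kk, seed=seed, n_restarts=self.n_restarts)
            asw_by_k[kk] = average_silhouette_width(X, labels)
            fits[kk] = (labels, centers)

        if k is not None:  # forced cluster count: validate only
            chosen = k if asw_by_k[k] >= self.asw_threshold else None
        else:
            chosen = select_k(wss_by_k, asw_by_k, self.asw_threshold, self.selection)
        accepted = chosen is not None
        if chosen is None:  # insufficient partitioning: report argmax anyway
            chosen = max(sorted(asw_by_k), key=lambda kk: asw_by_k[kk])
        labels, centers = fits[chosen]

        # Order profiles by ascending mean raw observation count.
        raw = self.metrics[METRIC_COLUMNS]
        mean_obs = [
            raw["n_observations"].to_numpy()[labels == lab].mean()
            for lab in range(chosen)
        ]
        order = np.argsort(mean_obs, kind="stable")
        names = (
            list(PROFILE_NAMES)
            if chosen == 3
            else [f"profile_{i + 1}" for i in range(chosen)]
        )
        relabel = {int(old): names[new] for new, old in enumerate(order)}
        assignments = pd.Series(
            [relabel[int(l)] for l in labels], index=self.metrics.index, name="profile"
        )
        centroids_norm = pd.DataFrame(
            centers[order], index=names, columns=METRIC_COLUMNS
        )
        centroids_raw = pd.DataFrame(
            [raw.to_numpy(float)[labels == old].mean(axis=0) for old in order],
            index=names,
            columns=METRIC_COLUMNS,
        )
        return ProfileResults(
            model=self,
            k=chosen,
            accepted=accepted,
            seed=seed,
            assignments=assignments,
            labels=labels,
            centroids_normalized=centroids_norm,
            centroids_raw=centroids_raw,
            wss_by_k=wss_by_k,
            asw_by_k=asw_by_k,
            asw=asw_by_k[chosen],
        )
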