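"""Migration-strategy classification and depth-use profiling.

Animals are classified into migration strategies by k-means clustering on
the southernmost latitude each track reaches (k = 3 by default: remain
near the tagging latitudes / migrate to mid latitudes / migrate far
south).  Cluster labels are reported as 'a', 'b', 'c', ... ordered by
descending mean southernmost latitude, so 'a' is always the
shortest-range strategy.

Depth use is summarised as the proportion of tracking days whose maximum
depth falls in each of eight standard bins, plus the fraction of days
spent within the epipelagic zone (0-200 m).
"""

from __future__ import annotations

import string

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

#: right-closed daily-maximum-depth bins, metres
DEPTH_BIN_EDGES = [0.0, 25.0, 50.0, 100.0, 200.0, 500.0, 750.0, 1000.0,
                   np.inf]
DEPTH_BIN_LABELS = ["0-25", "26-50", "51-100", "101-200", "201-500",
                    "501-750", "751-1000", ">1000"]

EPIPELAGIC_MAX_M = 200.0


def southernmost_latitude(track: pd.DataFrame) -> float:
    """Minimum latitude over a track of best daily locations."""
    if len(track) == 0:
        raise ValueError("empty track")
    return float(track["lat"].min())


class StrategyClassifier(BaseEstimator, ClusterMixin):
    """K-means migration-strategy clustering, scikit-learn style.

    Fits k-means (k-means++ initialisation, ``n_init`` restarts, best
    within-cluster sum of squares kept) to the 1-D southernmost-latitude
    values and relabels the clusters 'a', 'b', 'c', ... by descending mean
    latitude; ties in the mean are broken by cluster size (larger first).

    Attributes
    ----------
    labels_ : ndarray of strategy letters per animal
    cluster_centers_ : cluster mean latitudes, one per strategy letter
    inertia_ : within-cluster sum of squares of the best restart
    """

    def __init__(self, k: int = 3, seed: int = 7, n_init: int = 25):
        self.k = k
        self.seed = seed
        self.n_init = n_init

    def fit(self, X, y=None):
        lat = np.asarray(X, dtype=float).reshape(-1, 1)
        if len(np.unique(lat)) < self.k:
            raise ValueError(
                f"k={self.k} exceeds the number of distinct latitudes")
        km = KMeans(n_clusters=self.k, init="k-means++", n_init=self.n_init,
                    random_state=self.seed)
        raw = km.fit_predict(lat)
        centers = km.cluster_centers_.ravel()
        sizes = np.bincount(raw, minlength=self.k)
        # northernmost (largest-mean) cluster becomes 'a'
        order = sorted(range(self.k), key=lambda c: (-centers[c], -sizes[c]))
        letters = string.ascii_lowercase
        relabel = {c: letters[r] for r, c in enumerate(order)}
        self.labels_ = np.array([relabel[c] for c in raw])
        self.cluster_centers_ = centers[order]
        self.inertia_ = float(km.inertia_)
        self._km = km
        self._relabel = relabel
        return self

    def predict(self, X):
        raw = self._km.predict(np.asarray(X, dtype=float).reshape(-1, 1))
        return np.array([self._relabel[c] for c in raw])


def kmeans_strategies(latitudes, k: int = 3, seed: int = 7,
                      animal_ids=None) -> pd.DataFrame:
    """Cluster southernmost latitudes into strategy groups.

    Returns a DataFrame (animal_id, southernmost_lat, strategy) with
    labels ordered a > b > c by mean latitude.
    """
    lat = np.asarray(latitudes, dtype=float)
    clf = StrategyClassifier(k=k, seed=seed).fit(lat)
    if animal_ids is None:
        animal_ids = [f"animal{i}" for i in range(len(lat))]
    return pd.DataFrame({"animal_id": list(animal_ids),
                         "southernmost_lat": lat,
                         "strategy": clf.labels_})


def depth_bin_proportions(daily_max_depths) -> pd.Series:
    """Proportion of days in each depth bin.

    Bins are right-closed — [0, 25], (25, 50], (50, 100], (100, 200],
    (200, 500], (500, 750], (750, 1000], (1000, inf) — matching
    integer-metre bin labels like "26-50 m".
    """
    d = np.asarray(daily_max_depths, dtype=float)
    if (d < 0).any():
        raise ValueError("negative depth")
    if len(d) == 0:
        raise ValueError("no depths given")
    idx = np.searchsorted(DEPTH_BIN_EDGES[1:-1], d, side="left")
    counts = np.bincount(idx, minlength=len(DEPTH_BIN_LABELS))
    return pd.Series(counts / len(d), index=DEPTH_BIN_LABELS,
                     name="proportion")


def epipelagic_fraction(daily_max_depths) -> float:
    """Fraction of days with maximum depth within 0-200 m."""
    d = np.asarray(daily_max_depths, dtype=float)
    if (d < 0).any():
        raise ValueError("negative depth")
    if len(d) == 0:
        raise ValueError("no depths given")
    return float((d <= EPIPELAGIC_MAX_M).mean())


def strategy_depth_table(depths_by_animal: dict[str, np.ndarray],
                         assignments: pd.DataFrame) -> pd.DataFrame:
    """Mean depth-bin proportions per strategy.

    ``assignments`` is the output of :func:`kmeans_strategies`;
    ``depths_by_animal`` maps animal_id to its daily maximum depths.
    """
    strat = assignments.set_index("animal_id")["strategy"]
    rows = {}
    for s in sorted(strat.unique()):
        ids = strat.index[strat == s]
        props = [depth_bin_proportions(depths_by_animal[a]) for a in ids
                 if a in depths_by_animal]
        if props:
            rows[s] = pd.concat(props, axis=1).mean(axis=1)
    return pd.DataFrame(rows).T
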