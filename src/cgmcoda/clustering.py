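"""Categorization of glucose periods by k-means on ilr coordinates.

Because ilr coordinates are isometric to the Aitchison geometry, plain
Euclidean k-means on them clusters compositions by their log-ratio
similarity.  24-h days and 6-h periods are clustered separately; internal
validity indices (Calinski-Harabasz, Dunn, Silhouette) inform the choice
of k together with the clinical interpretability of the groups.  Fitted
groups are mapped to the clinical letters (V..Z for days, A..D for 6-h
periods) by ordering the group centers on the first balance, so the most
hypoglycemia-dominated group always comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from .composition import PART_LABELS, Composition
from .coordinates import compositional_center

LETTERS_24H = ("V", "W", "X", "Y", "Z")
LETTERS_6H = ("A", "B", "C", "D")


@dataclass(frozen=True)
class ClusterModel:
    """A fitted k-means categorization of period coordinates."""

    k: int
    centers: np.ndarray          # (k, D-1) in ilr space
    labels: np.ndarray           # (n,) integer categories in [0, k)
    inertia: float
    seed: int | None
    n_init: int

    def letter_map(self, letters=None) -> dict[int, str]:
        """Deterministic cluster-to-letter assignment.

        Groups are sorted by the first ilr coordinate of their centers in
        decreasing order (hypoglycemia-dominant first) and assigned the
        clinical letters in that order.
        """
        if letters is None:
            letters = LETTERS_24H
        if self.k > len(letters):
            raise ValueError(f"need {self.k} letters, have {len(letters)}")
        order = np.argsort(-self.centers[:, 0], kind="stable")
        return {int(lab): letters[pos] for pos, lab in enumerate(order)}

    def letters(self, letters=None) -> np.ndarray:
        m = self.letter_map(letters)
        return np.asarray([m[int(l)] for l in self.labels])


def kmeans_coords(coords, k: int, n_init: int = 25, seed: int | None = None) -> ClusterModel:
    """Best-of-``n_init`` Lloyd k-means on ilr coordinates.

    Initial centers are drawn at random ``n_init`` times (25 by default)
    and the solution with the lowest within-cluster sum of squares is
    kept; results are deterministic given ``seed``.
    """
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available rows")
    km = KMeans(n_clusters=k, init="random", n_init=n_init,
                random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return ClusterModel(k=k, centers=km.cluster_centers_, labels=labels,
                        inertia=float(km.inertia_), seed=seed, n_init=n_init)


def _check_labels(X: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("internal validity indices need at least 2 clusters")
    return groups


def calinski_harabasz(coords, labels) -> float:
    """Calinski-Harabasz index: (between-SS/(k-1)) / (within-SS/(n-k))."""
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    _check_labels(X, np.asarray(labels))
    return float(calinski_harabasz_score(X, labels))


def dunn(coords, labels) -> float:
    """Dunn index: min inter-cluster distance over max intra-cluster diameter.

    Inter-cluster distance is the minimum pairwise distance between points
    of different clusters; the diameter is the maximum pairwise distance
    within a cluster.
    """
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    labels = np.asarray(labels)
    groups = _check_labels(X, labels)
    diam = max(
        (pdist(X[g]).max() if len(g) > 1 else 0.0) for g in groups
    )
    inter = min(
        cdist(X[gi], X[gj]).min()
        for a, gi in enumerate(groups)
        for gj in groups[a + 1:]
    )
    if diam == 0:
        return float("inf")
    return float(inter / diam)


def silhouette(coords, labels) -> float:
    """Mean silhouette width; singleton clusters contribute 0."""
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    labels = np.asarray(labels)
    _check_labels(X, labels)
    return float(silhouette_samples(X, labels).mean())


def select_k(coords, k_range, n_init: int = 25, seed: int | None = None) -> pd.DataFrame:
    """Validity-index table over candidate k values.

    No automatic winner is declared: the choice of k weighs these indices
    against the clinical interpretability of the resulting groups.
    """
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    rows = []
    for k in k_range:
        model = kmeans_coords(X, k, n_init=n_init, seed=seed)
        rows.append({
            "k": int(k),
            "calinski_harabasz": calinski_harabasz(X, model.labels),
            "dunn": dunn(X, model.labels),
            "silhouette": silhouette(X, model.labels),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupProfile:
    """Per-group compositional characterization.

    ``centers`` holds the closed compositional center of each group in
    minutes; ``log_ratios`` the natural log of each group center part over
    the overall center part.  A log-ratio of 4.12 on a part means the
    group's relative time in that range is ``exp(4.12) ~ 61`` times the
    overall mean; multiplied by the overall center minutes it gives the
    group's expected minutes in the range.
    """

    groups: tuple
    overall_center: Composition
    centers: pd.DataFrame      # rows = groups, columns = parts, minutes
    log_ratios: pd.DataFrame   # rows = groups, columns = parts


def group_log_ratio_profile(compositions, labels, C: float = 1440.0) -> GroupProfile:
    """Group centers (closed to ``C`` minutes) and log-ratios vs the overall
    center.

    Positive values flag parts where the group sits above the overall
    composition, negative values below; ``exp(log_ratio) * overall_part``
    recovers the group center part exactly.
    """
    X = np.asarray([np.asarray(c, dtype=float) for c in compositions])
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("labels and compositions length mismatch")
    groups = [g for g in pd.unique(labels)]
    overall = compositional_center(X, C)
    centers, lrs = {}, {}
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) == 0:
            raise ValueError(f"group {g!r} is empty")
        cg = compositional_center(X[idx], C)
        centers[g] = np.asarray(cg)
        lrs[g] = np.log(np.asarray(cg) / np.asarray(overall))
    centers_df = pd.DataFrame.from_dict(centers, orient="index", columns=PART_LABELS)
    lr_df = pd.DataFrame.from_dict(lrs, orient="index", columns=PART_LABELS)
    return GroupProfile(tuple(groups), overall, centers_df, lr_df)


def fold_change(log_ratio) -> np.ndarray | float:
    """Multiplicative reading of a group-vs-overall log-ratio."""
    return np.exp(log_ratio)


def expected_minutes(overall_part_minutes, log_ratio) -> np.ndarray | float:
    """Group minutes in a range implied by the overall center and log-ratio."""
    return overall_part_minutes * np.exp(log_ratio)
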