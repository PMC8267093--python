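"""Call-type classification: z-scored features, k-means, noise removal.

Calls are clustered in standardized 12-feature space with k = 10; the
cluster identified as noise (shortest mean duration and smallest mean
frequency dynamic) is removed, and the remaining nine clusters are renumbered
1..9 by descending centroid peak frequency to give the call types.  The type
indices are therefore a property of this package's convention, not of any
particular published figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .io_formats import FEATURE_COLUMNS


@dataclass
class CallTypeModel:
    """Fitted typing model: standardization constants + centroids in z-space."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    centroids: np.ndarray           # k x p, z-space
    k: int
    seed: int
    restarts: int
    inertia: float
    noise_cluster: int | None = None      # original cluster id flagged as noise
    relabel: dict[int, int] = field(default_factory=dict)  # original id -> 1..9

    def standardize(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].to_numpy(dtype=float)
        return (X - self.means) / self.sds

    def assign(self, features: pd.DataFrame) -> np.ndarray:
        """Nearest-centroid raw cluster ids (before noise relabeling)."""
        Z = self.standardize(features)
        d = ((Z[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)

    def predict_types(self, features: pd.DataFrame) -> np.ndarray:
        """Call types 1..9 (0 = noise) for new data; requires noise removal."""
        if not self.relabel:
            raise ValueError("model has no type relabeling; run remove_noise_cluster")
        raw = self.assign(features)
        return np.array([self.relabel.get(int(c), 0) for c in raw])

    def centroid_table(self) -> pd.DataFrame:
        """Centroids in original feature units, indexed by raw cluster id."""
        X = self.centroids * self.sds + self.means
        return pd.DataFrame(X, columns=self.feature_names)

    def summary(self) -> str:
        tab = self.centroid_table()
        lines = [f"Call-type model: k={self.k}, restarts={self.restarts}, "
                 f"seed={self.seed}, inertia={self.inertia:.2f}"]
        if self.noise_cluster is not None:
            lines.append(f"noise cluster (removed): {self.noise_cluster}")
        if self.relabel:
            inv = {v: k for k, v in self.relabel.items()}
            for t in sorted(inv):
                row = tab.loc[inv[t]]
                lines.append(f"type {t}: peak {row['peak_freq_hz']:.0f} Hz, "
                             f"dur {row['duration_ms']:.1f} ms, "
                             f"dynamic {row['freq_dynamic_hz']:.0f} Hz")
        return "\n".join(lines)


def fit_call_types(features: pd.DataFrame, k: int = 10, restarts: int = 25,
                   seed: int = 0) -> tuple[CallTypeModel, np.ndarray]:
    """z-score the 12 features and fit k-means (k-means++, best of restarts).

    Returns the model and raw cluster labels (0..k-1).  Deterministic given
    the seed.
    """
    names = [c for c in FEATURE_COLUMNS if c in features.columns]
    if len(names) != len(FEATURE_COLUMNS):
        missing = set(FEATURE_COLUMNS) - set(names)
        raise ValueError(f"missing feature columns: {sorted(missing)}")
    X = features[list(names)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if X.shape[0] < k:
        raise ValueError(f"k={k} exceeds the number of calls ({X.shape[0]})")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    for name, s in zip(names, sds):
        if s <= 0:
            raise ValueError(f"degenerate feature {name!r} (zero variance)")
    Z = (X - means) / sds
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                random_state=seed).fit(Z)
    model = CallTypeModel(feature_names=list(names), means=means, sds=sds,
                          centroids=km.cluster_centers_, k=k, seed=seed,
                          restarts=restarts, inertia=float(km.inertia_))
    return model, km.labels_.astype(int)


def remove_noise_cluster(model: CallTypeModel, labels: np.ndarray,
                         features: pd.DataFrame, rule: str = "auto",
                         noise_cluster: int | None = None,
                         max_silhouette_n: int = 5000,
                         ) -> tuple[CallTypeModel, np.ndarray]:
    """Drop the noise cluster and renumber the rest 1..9.

    Default rule: the cluster ranking first on BOTH shortest mean duration and
    smallest mean frequency dynamic; if no cluster is first on both, the
    cluster with the lowest mean silhouette is taken.  ``noise_cluster``
    overrides the rule.  Returns the updated model and per-call types
    (1..n_types, 0 for calls of the removed cluster).
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    if rule == "manual" or noise_cluster is not None:
        if noise_cluster is None:
            raise ValueError("manual rule requires noise_cluster")
        noise = int(noise_cluster)
        if noise not in present:
            raise ValueError(f"cluster {noise} has no calls")
    else:
        tab = features.groupby(labels)[["duration_ms", "freq_dynamic_hz"]].mean()
        dur_rank = tab["duration_ms"].rank(method="min")
        dyn_rank = tab["freq_dynamic_hz"].rank(method="min")
        both = tab.index[(dur_rank == 1) & (dyn_rank == 1)]
        if len(both) == 1:
            noise = int(both[0])
        else:  # fall back to the lowest mean silhouette
            Z = model.standardize(features)
            if Z.shape[0] > max_silhouette_n:
                rng = np.random.default_rng(model.seed)
                idx = rng.choice(Z.shape[0], max_silhouette_n, replace=False)
            else:
                idx = np.arange(Z.shape[0])
            sil = silhouette_samples(Z[idx], labels[idx])
            sil_mean = pd.Series(sil).groupby(labels[idx]).mean()
            noise = int(sil_mean.idxmin())
    keep = [int(c) for c in present if c != noise]
    # renumber by descending centroid peak frequency (original units)
    tab = model.centroid_table()
    order = sorted(keep, key=lambda c: -tab.loc[c, "peak_freq_hz"])
    relabel = {c: t for t, c in enumerate(order, start=1)}
    new_model = CallTypeModel(
        feature_names=model.feature_names, means=model.means, sds=model.sds,
        centroids=model.centroids, k=model.k, seed=model.seed,
        restarts=model.restarts, inertia=model.inertia,
        noise_cluster=noise, relabel=relabel)
    types = np.array([relabel.get(int(c), 0) for c in labels])
    return new_model, types


def occurrence_table(types: np.ndarray, animal_ids, groups,
                     n_types: int = 9) -> pd.DataFrame:
    """Per-animal call-type occurrence probabilities.

    Noise calls (type 0) are excluded; animals left with no typed calls are
    dropped.  Rows sum to 1.  Columns ``type_1`` .. ``type_{n_types}`` plus
    ``group``.
    """
    df = pd.DataFrame({"type": np.asarray(types),
                       "animal_id": np.asarray(animal_ids),
                       "group": np.asarray(groups)})
    df = df[df["type"] > 0]
    rows = []
    for (animal, group), sub in df.groupby(["animal_id", "group"]):
        counts = sub["type"].value_counts()
        probs = [counts.get(t, 0) / len(sub) for t in range(1, n_types + 1)]
        rows.append({"animal_id": animal, "group": group,
                     **{f"type_{t}": p for t, p in zip(range(1, n_types + 1), probs)}})
    return pd.DataFrame(rows).set_index("animal_id")


def match_clusters(labels_a: np.ndarray, labels_b: np.ndarray) -> dict[int, int]:
    """Hungarian matching of label sets by maximal overlap (a -> b)."""
    ua, ub = np.unique(labels_a), np.unique(labels_b)
    cost = np.zeros((ua.size, ub.size))
    for i, a in enumerate(ua):
        for j, b in enumerate(ub):
            cost[i, j] = -np.sum((labels_a == a) & (labels_b == b))
    ri, ci = linear_sum_assignment(cost)
    return {int(ua[i]): int(ub[j]) for i, j in zip(ri, ci)}
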