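"""Oblique principal-component variable clustering (VARCLUS-style).

Divisive procedure on standardized variables: start from one cluster, split
the cluster whose correlation-matrix second eigenvalue is largest (while it
is at or above the split threshold) by rotating its first two principal
components with a quartimax criterion and assigning each member to the
rotated component it correlates with best, then sweep variables between
clusters until no move improves its squared correlation with a cluster's
first principal component.  Each final cluster is scored by its first
principal component over member variables; a large variable set can thereby
be replaced by a few cluster scores with little loss of information.

``VarClus`` follows the Model/Results convention: construct from data, call
``fit()``, inspect the :class:`VarClusResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .groupstats import kruskal_wallis, steel_dwass

_MAX_SWEEPS = 20


def _first_pc_weights(corr_sub: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Unit-norm first-PC weights of a correlation submatrix, plus the first
    two eigenvalues.  Sign fixed so the largest-|weight| entry is positive."""
    vals, vecs = np.linalg.eigh(corr_sub)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    w = vecs[:, 0]
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    lam2 = float(vals[1]) if vals.size > 1 else 0.0
    return w, float(vals[0]), lam2


class VarClus:
    """Variable-clustering model for an observations x variables matrix.

    Parameters
    ----------
    data : DataFrame or ndarray
        Observations in rows.  Column names become variable names.
    split_threshold : float
        A cluster is split while its second eigenvalue is >= this value
        (default 1.0, the average-variance rule).
    max_clusters : int or None
        Upper bound on the number of clusters (default: number of variables).
    """

    def __init__(self, data, varnames: list[str] | None = None,
                 split_threshold: float = 1.0, max_clusters: int | None = None):
        if isinstance(data, pd.DataFrame):
            self.varnames = list(data.columns)
            X = data.to_numpy(dtype=float)
        else:
            X = np.asarray(data, dtype=float)
            self.varnames = varnames or [f"x{i}" for i in range(X.shape[1])]
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("need a 2-D matrix with at least 2 variables")
        if X.shape[0] < 3:
            raise ValueError(f"need at least 3 observations, got {X.shape[0]}")
        sds = X.std(axis=0, ddof=1)
        for j, s in enumerate(sds):
            if s <= 1e-10 * (1.0 + abs(float(X[:, j].mean()))):
                raise ValueError(f"variable {self.varnames[j]!r} is constant")
        self._means = X.mean(axis=0)
        self._sds = sds
        self.Z = (X - self._means) / sds
        self.corr = np.corrcoef(self.Z, rowvar=False)
        self.split_threshold = float(split_threshold)
        self.max_clusters = max_clusters or X.shape[1]

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "VarClusResults":
        clusters: list[list[int]] = [list(range(len(self.varnames)))]
        while len(clusters) < self.max_clusters:
            lam2s = [self._second_eig(c) for c in clusters]
            worst = int(np.argmax(lam2s))
            if lam2s[worst] < self.split_threshold:
                break
            left, right = self._split(clusters[worst])
            if not left or not right:
                break
            clusters[worst:worst + 1] = [left, right]
            clusters = self._reassign(clusters)
        return self._results(clusters)

    def _second_eig(self, members: list[int]) -> float:
        if len(members) < 2:
            return 0.0
        sub = self.corr[np.ix_(members, members)]
        return _first_pc_weights(sub)[2]

    def _split(self, members: list[int]) -> tuple[list[int], list[int]]:
        sub = self.corr[np.ix_(members, members)]
        vals, vecs = np.linalg.eigh(sub)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        # loadings of the first two components (correlations with members)
        L = vecs[:, :2] * np.sqrt(np.maximum(vals[:2], 0.0))
        Lr, _ = rotate_factors(L, "quartimax")
        assign = np.argmax(Lr ** 2, axis=1)  # ties -> first component
        left = [m for m, a in zip(members, assign) if a == 0]
        right = [m for m, a in zip(members, assign) if a == 1]
        if not left or not right:  # degenerate rotation: peel the best second-PC variable
            j = int(np.argmax(np.abs(L[:, 1])))
            right = [members[j]]
            left = [m for m in members if m != members[j]]
        return left, right

    def _reassign(self, clusters: list[list[int]]) -> list[list[int]]:
        p = len(self.varnames)
        for _ in range(_MAX_SWEEPS):
            weights = [self._scores_weights(c) for c in clusters]
            scores = [self.Z[:, c] @ w for c, w in zip(clusters, weights)]
            member_of = np.empty(p, dtype=int)
            for ci, c in enumerate(clusters):
                member_of[c] = ci
            moved = False
            for v in range(p):
                r2 = [np.corrcoef(self.Z[:, v], s)[0, 1] ** 2 for s in scores]
                best = int(np.argmax(r2))
                if best != member_of[v] and len(clusters[member_of[v]]) > 1:
                    clusters[member_of[v]].remove(v)
                    clusters[best].append(v)
                    member_of[v] = best
                    moved = True
            if not moved:
                break
        return [sorted(c) for c in clusters]

    def _scores_weights(self, members: list[int]) -> np.ndarray:
        if len(members) == 1:
            return np.array([1.0])
        sub = self.corr[np.ix_(members, members)]
        return _first_pc_weights(sub)[0]

    def _results(self, clusters: list[list[int]]) -> "VarClusResults":
        clusters = sorted((sorted(c) for c in clusters), key=lambda c: c[0])
        weights, lam2s = [], []
        for c in clusters:
            weights.append(self._scores_weights(c))
            lam2s.append(self._second_eig(c))
        scores = np.column_stack([self.Z[:, c] @ w for c, w in zip(clusters, weights)])
        own_r2 = np.empty(len(self.varnames))
        next_r2 = np.empty(len(self.varnames))
        for ci, c in enumerate(clusters):
            for v in c:
                r2 = [np.corrcoef(self.Z[:, v], scores[:, cj])[0, 1] ** 2
                      for cj in range(len(clusters))]
                own_r2[v] = r2[ci]
                next_r2[v] = max((r for cj, r in enumerate(r2) if cj != ci),
                                 default=0.0)
        return VarClusResults(
            model=self, clusters=clusters, weights=weights,
            second_eigenvalues=np.array(lam2s), own_r2=own_r2, next_r2=next_r2)


@dataclass
class VarClusResults:
    """Fitted variable clustering: membership, scoring weights, diagnostics."""

    model: VarClus
    clusters: list[list[int]]
    weights: list[np.ndarray]
    second_eigenvalues: np.ndarray
    own_r2: np.ndarray
    next_r2: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def membership(self) -> dict[str, int]:
        """variable name -> 1-based cluster id."""
        out = {}
        for ci, c in enumerate(self.clusters, start=1):
            for v in c:
                out[self.model.varnames[v]] = ci
        return out

    def transform(self, data) -> pd.DataFrame:
        """Cluster scores for data, standardized with the fitting statistics.

        On the fitting data every score column has mean 0.
        """
        if isinstance(data, pd.DataFrame):
            missing = set(self.model.varnames) - set(data.columns)
            if missing:
                raise ValueError(f"missing variables: {sorted(missing)}")
            X = data[self.model.varnames].to_numpy(dtype=float)
        else:
            X = np.asarray(data, dtype=float)
            if X.shape[1] != len(self.model.varnames):
                raise ValueError("wrong number of variables")
        Z = (X - self.model._means) / self.model._sds
        cols = {f"cluster_{ci + 1}": Z[:, c] @ w
                for ci, (c, w) in enumerate(zip(self.clusters, self.weights))}
        return pd.DataFrame(cols)

    def summary(self) -> str:
        lines = [f"Variable clustering: {self.n_clusters} clusters, "
                 f"split threshold {self.model.split_threshold}",
                 f"{'variable':<20} {'cluster':>7} {'own R2':>8} {'next R2':>8}"]
        for ci, c in enumerate(self.clusters, start=1):
            for v in c:
                lines.append(f"{self.model.varnames[v]:<20} {ci:>7} "
                             f"{self.own_r2[v]:>8.3f} {self.next_r2[v]:>8.3f}")
        lines.append("second eigenvalues at termination: "
                     + ", ".join(f"{x:.3f}" for x in self.second_eigenvalues))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "membership": self.membership,
            "weights": {f"cluster_{ci + 1}":
                        {self.model.varnames[v]: float(w)
                         for v, w in zip(c, ws)}
                        for ci, (c, ws) in enumerate(zip(self.clusters, self.weights))},
            "second_eigenvalues": [float(x) for x in self.second_eigenvalues],
            "own_r2": {self.model.varnames[v]: float(self.own_r2[v])
                       for v in range(len(self.model.varnames))},
        }


def cluster_scores(results: VarClusResults, data) -> pd.DataFrame:
    """Observations x clusters score matrix (first-PC scores)."""
    return results.transform(data)


def compare_cluster_scores(scores: pd.DataFrame, groups, unit: str = "call",
                           animal_ids=None, alpha: float = 0.05) -> dict:
    """Kruskal-Wallis + Steel-Dwass on each cluster score across groups.

    With ``unit='animal'``, each animal's mean score is one observation
    (requires ``animal_ids``).  Groups with fewer than 2 observations are
    excluded (their names listed under ``excluded_groups``).
    """
    groups = pd.Series(np.asarray(groups), index=scores.index, name="group")
    if unit == "animal":
        if animal_ids is None:
            raise ValueError("unit='animal' requires animal_ids")
        ids = pd.Series(np.asarray(animal_ids), index=scores.index)
        agg = scores.groupby([ids.rename("animal_id"), groups]).mean().reset_index()
        groups = agg["group"]
        scores = agg[list(scores.columns)]
    out: dict[str, dict] = {}
    counts = groups.value_counts()
    keep = counts[counts >= 2].index
    excluded = sorted(set(counts.index) - set(keep))
    mask = groups.isin(keep).to_numpy()
    for col in scores.columns:
        vals = scores.loc[mask, col].to_numpy()
        labs = groups[mask].to_numpy()
        H, df, p = kruskal_wallis(vals, labs)
        report = steel_dwass(vals, labs, alpha=alpha)
        out[col] = {"kruskal_wallis": {"H": H, "df": df, "p": p},
                    "steel_dwass": report,
                    "excluded_groups": excluded}
    return out
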