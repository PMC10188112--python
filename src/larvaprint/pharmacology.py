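"""Pharmaco-behavioral matching: rank a query fingerprint against a drug
fingerprint library by Pearson correlation, and build a hierarchical
clustergram of query + library.

The matching logic mirrors the screen design in which a mutant's behavioral
fingerprint is compared with fingerprints of wild-type larvae exposed to a
large panel of psychoactive compounds: compounds whose fingerprints
correlate most strongly with the mutant are candidate phenocopies of its
pathway. Clustering uses correlation distance (1 − Pearson r) with average
linkage; both are configurable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fingerprints import correlate

__all__ = [
    "FingerprintLibrary",
    "rank_library",
    "cluster_fingerprints",
    "LinkageTree",
    "LibraryRanker",
    "FingerprintClusterer",
]


@dataclass
class FingerprintLibrary:
    """Named condition fingerprints: a conditions × measures Z-score matrix.

    Conditions are compound × dose treatments (each dose a distinct
    condition); ``annotations`` optionally carries a free-text target class
    per condition.
    """

    z: pd.DataFrame
    annotations: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.z.index.has_duplicates:
            raise ValueError("duplicate condition names in library")
        if self.z.columns.has_duplicates:
            raise ValueError("duplicate measure names in library")
        if self.annotations is not None:
            self.annotations = self.annotations.reindex(self.z.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.z.index)

    @property
    def measures(self) -> list[str]:
        return list(self.z.columns)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FingerprintLibrary":
        df = pd.read_csv(path, index_col=0)
        ann = None
        if "annotation" in df.columns:
            ann = df["annotation"]
            df = df.drop(columns="annotation")
        return cls(z=df.astype(float), annotations=ann)

    def to_csv(self, path: str | Path) -> None:
        df = self.z.copy()
        if self.annotations is not None:
            df.insert(0, "annotation", self.annotations)
        df.to_csv(path, index_label="condition")


def rank_library(
    query: pd.Series, lib: FingerprintLibrary, min_overlap: int = 5
) -> pd.DataFrame:
    """Rank library conditions by Pearson correlation with the query.

    Returns a DataFrame with columns ``condition``, ``r``, ``n_overlap``
    sorted by r descending (ties broken by condition name). Conditions with
    fewer than ``min_overlap`` shared non-missing measures, or an undefined
    correlation, are dropped from the ranking.
    """
    rows = []
    for cond in lib.conditions:
        row = lib.z.loc[cond]
        shared = query.index.intersection(row.index)
        qv, rv = query.loc[shared], row.loc[shared]
        n_overlap = int((qv.notna() & rv.notna()).sum())
        if n_overlap < min_overlap:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = correlate(qv, rv, min_overlap=min_overlap)
        if np.isnan(r):
            continue
        rows.append((cond, r, n_overlap))
    if not rows:
        warnings.warn("no library condition meets the overlap requirement")
        return pd.DataFrame(columns=["condition", "r", "n_overlap"])
    out = pd.DataFrame(rows, columns=["condition", "r", "n_overlap"])
    out = out.sort_values(["r", "condition"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class LinkageTree:
    """Agglomerative tree in scipy linkage format plus leaf names.

    ``linkage`` rows are (left id, right id, height, cluster size); leaves
    are numbered 0..n−1 in input-row order, merged clusters n, n+1, ...
    """

    linkage: np.ndarray
    labels: list[str]
    _children: dict[int, tuple[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        self._children = {
            n + k: (int(l), int(r)) for k, (l, r, *_r) in enumerate(self.linkage)
        }

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def canonical(self):
        """Order-independent nested form: leaf → name; merge →
        (round(height), sorted children). Two trees over the same items are
        topologically identical iff their canonical forms are equal."""
        n = len(self.labels)

        def rec(node: int):
            if node < n:
                return self.labels[node]
            left, right = self._children[node]
            h = float(self.linkage[node - n, 2])
            return (round(h, 10), tuple(sorted(map(str, (rec(left), rec(right))))))

        return rec(2 * n - 2) if n > 1 else self.labels[0]

    def leaf_order(self) -> list[str]:
        n = len(self.labels)

        def rec(node: int) -> list[int]:
            if node < n:
                return [node]
            left, right = self._children[node]
            return rec(left) + rec(right)

        return [self.labels[i] for i in rec(2 * n - 2)] if n > 1 else list(self.labels)

    def to_dict(self) -> dict:
        n = len(self.labels)

        def rec(node: int) -> dict:
            if node < n:
                return {"name": self.labels[node]}
            left, right = self._children[node]
            return {
                "height": float(self.linkage[node - n, 2]),
                "children": [rec(left), rec(right)],
            }

        return rec(2 * n - 2)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _correlation_distances(X: pd.DataFrame, min_overlap: int) -> np.ndarray:
    """Pairwise 1 − Pearson r, pairwise-complete over non-missing measures."""
    n = len(X)
    vals = X.to_numpy(float)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(vals[i]) | np.isnan(vals[j]))
            if ok.sum() < min_overlap:
                raise ValueError(
                    f"rows {X.index[i]!r} and {X.index[j]!r} share only "
                    f"{int(ok.sum())} measures (< {min_overlap})"
                )
            a, b = vals[i, ok], vals[j, ok]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                raise ValueError(
                    f"correlation undefined for rows {X.index[i]!r} and {X.index[j]!r}"
                )
            D[i, j] = D[j, i] = 1.0 - float(np.corrcoef(a, b)[0, 1])
    return D


_TIE_TOL = 1e-12


def _agglomerate(D: np.ndarray, labels: list[str], linkage: str = "average") -> LinkageTree:
    """Agglomeration with Lance–Williams updates and name-based tie-breaking.

    Among pairs at the minimal distance (to within a relative tolerance),
    the pair with the lexicographically smallest (min leaf name, max leaf
    name) key merges first, which makes the tree invariant to input row
    order even under exact ties.
    """
    if linkage != "average":
        raise ValueError(f"unsupported linkage {linkage!r}")
    n = len(labels)
    active: dict[int, dict] = {
        i: {"size": 1, "min_name": str(labels[i])} for i in range(n)
    }
    dist = {frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        d_min = min(dist[frozenset((i, j))]
                    for i in active for j in active if i < j)
        tol = _TIE_TOL * max(1.0, abs(d_min))
        candidates = [
            (i, j)
            for i in active
            for j in active
            if i < j and dist[frozenset((i, j))] <= d_min + tol
        ]
        i, j = min(
            candidates,
            key=lambda p: tuple(sorted((active[p[0]]["min_name"], active[p[1]]["min_name"]))),
        )
        si, sj = active[i]["size"], active[j]["size"]
        Z[step] = (i, j, dist[frozenset((i, j))], si + sj)
        new = {
            "size": si + sj,
            "min_name": min(active[i]["min_name"], active[j]["min_name"]),
        }
        for k in active:
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (si * dik + sj * djk) / (si + sj)
        del dist[frozenset((i, j))]
        del active[i], active[j]
        active[next_id] = new
        next_id += 1
    return LinkageTree(linkage=Z, labels=[str(x) for x in labels])


def cluster_fingerprints(
    rows: pd.DataFrame,
    metric: str = "correlation",
    linkage: str = "average",
    min_overlap: int = 3,
) -> LinkageTree:
    """Hierarchical clustergram of fingerprint rows (query + library).

    Distance is 1 − Pearson r (pairwise-complete); linkage is average
    (UPGMA). An undefined correlation for any pair is a hard error naming
    the pair. The result is deterministic and invariant to row order.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to cluster")
    if metric == "correlation":
        D = _correlation_distances(rows, min_overlap)
    elif metric == "euclidean":
        vals = rows.to_numpy(float)
        if np.isnan(vals).any():
            raise ValueError("euclidean metric requires complete rows")
        D = np.sqrt(((vals[:, None, :] - vals[None, :, :]) ** 2).sum(-1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return _agglomerate(D, list(rows.index), linkage=linkage)


# ---------------------------------------------------------------------------
# estimator surface


class LibraryRanker(BaseEstimator):
    """Match a query fingerprint to its nearest library conditions.

    fit stores the library; :meth:`rank` returns the full correlation
    ranking, :meth:`predict` the best-matching condition name.
    """

    def __init__(self, min_overlap: int = 5):
        self.min_overlap = min_overlap

    def fit(self, library: FingerprintLibrary, y=None) -> "LibraryRanker":
        if not isinstance(library, FingerprintLibrary):
            library = FingerprintLibrary(z=pd.DataFrame(library))
        self.library_ = library
        return self

    def rank(self, query: pd.Series) -> pd.DataFrame:
        if not hasattr(self, "library_"):
            raise ValueError("LibraryRanker is not fitted")
        return rank_library(query, self.library_, min_overlap=self.min_overlap)

    def predict(self, query: pd.Series) -> str:
        ranked = self.rank(query)
        if ranked.empty:
            raise ValueError("no condition meets the overlap requirement")
        return str(ranked["condition"].iloc[0])


class FingerprintClusterer(BaseEstimator):
    """Agglomerative clustergram estimator over fingerprint rows."""

    def __init__(self, metric: str = "correlation", linkage: str = "average",
                 min_overlap: int = 3):
        self.metric = metric
        self.linkage = linkage
        self.min_overlap = min_overlap

    def fit(self, X: pd.DataFrame, y=None) -> "FingerprintClusterer":
        self.tree_ = cluster_fingerprints(
            X, metric=self.metric, linkage=self.linkage, min_overlap=self.min_overlap
        )
        self.linkage_ = self.tree_.linkage
        self.leaf_order_ = self.tree_.leaf_order()
        return self
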