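"""Behavioral fingerprints: sibling-referenced Z-scores, group summaries,
Euclidean phenotype distance, and fingerprint correlation.

A fingerprint is the vector of per-measure Z-scores of one larva relative to
its control-sibling cohort: z = (x − mean_ref) / sd_ref, with sd_ref the
sample standard deviation (denominator n−1) over the reference larvae. The
reference group's mean fingerprint is thereby the origin, so the Euclidean
norm of a fingerprint measures the overall magnitude of a phenotype.
Missing measures stay missing (NaN); they are excluded from distances and
handled pairwise-complete in correlations, never imputed as 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .bouts import MEASURES

__all__ = [
    "FingerprintScaler",
    "zscore_fingerprints",
    "group_fingerprint",
    "euclidean_distance",
    "distances",
    "correlate",
]


class FingerprintScaler(TransformerMixin, BaseEstimator):
    """Z-score larvae against the within-clutch reference (control) group.

    Fit learns the per-measure mean and sample standard deviation (ddof=1)
    of the reference group; transform maps any parameter table into
    fingerprint space. Measures with zero variance in the reference group
    are flagged and produced as missing.

    Parameters
    ----------
    reference_group : str
        Group label of the control siblings (e.g. ``"wt"``).

    Attributes
    ----------
    center_ : pd.Series
        Reference-group mean per measure.
    scale_ : pd.Series
        Reference-group sample sd per measure; NaN where degenerate.
    measures_ : list of str
        Measure columns seen at fit.
    n_reference_ : pd.Series
        Number of non-missing reference larvae per measure.
    """

    def __init__(self, reference_group: str = "wt"):
        self.reference_group = reference_group

    def fit(self, X: pd.DataFrame, y=None) -> "FingerprintScaler":
        X, groups = _split_groups(X, y)
        ref = X.loc[np.asarray(groups) == self.reference_group]
        if len(ref) < 2:
            raise ValueError(
                f"reference group {self.reference_group!r} needs >= 2 larvae, got {len(ref)}"
            )
        n = ref.notna().sum()
        if (n < 2).any():
            bad = list(n.index[n < 2])
            raise ValueError(f"reference group has < 2 non-missing larvae for measures {bad}")
        self.measures_ = list(X.columns)
        self.center_ = ref.mean()
        self.scale_ = ref.std(ddof=1)
        self.n_reference_ = n
        degenerate = self.scale_.index[(self.scale_ == 0) | self.scale_.isna()]
        if len(degenerate):
            warnings.warn(
                f"zero reference variance for measures {list(degenerate)}; "
                "marked missing in all fingerprints"
            )
            self.scale_ = self.scale_.mask(self.scale_ == 0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "center_"):
            raise ValueError("FingerprintScaler is not fitted")
        X = _strip_group(X)
        missing = [m for m in self.measures_ if m not in X.columns]
        if missing:
            raise ValueError(f"input lacks fitted measures {missing}")
        return (X[self.measures_] - self.center_) / self.scale_


def _strip_group(X: pd.DataFrame) -> pd.DataFrame:
    return X.drop(columns="group") if "group" in X.columns else X


def _split_groups(X: pd.DataFrame, y) -> tuple[pd.DataFrame, pd.Series]:
    if y is None:
        if "group" not in X.columns:
            raise ValueError("pass group labels as y or as a 'group' column")
        y = X["group"]
    return _strip_group(X), pd.Series(np.asarray(y), index=X.index)


def zscore_fingerprints(
    params: pd.DataFrame,
    groups: pd.Series | None = None,
    reference_group: str = "wt",
) -> pd.DataFrame:
    """Fingerprints (per-larva Z-score vectors) for a parameter table.

    Thin wrapper over :class:`FingerprintScaler`; fingerprints are produced
    for every larva, including the reference larvae themselves.
    """
    return FingerprintScaler(reference_group).fit(params, groups).transform(params)


def group_fingerprint(fingerprints: pd.DataFrame, groups: pd.Series | None = None,
                      group: str | None = None) -> pd.DataFrame:
    """Per-measure mean ± SEM summary of a group's fingerprints.

    Returns a DataFrame indexed by measure with columns ``mean_z``,
    ``sem_z`` and ``n`` (non-missing members). SEM for n=1 is reported
    missing, not 0.
    """
    z = _strip_group(fingerprints)
    if group is not None:
        if groups is None:
            if "group" not in fingerprints.columns:
                raise ValueError("group labels required to select a group")
            groups = fingerprints["group"]
        z = z.loc[np.asarray(groups) == group]
    if len(z) == 0:
        raise ValueError(f"group {group!r} has no members")
    n = z.notna().sum()
    sd = z.std(ddof=1)  # NaN when n == 1
    return pd.DataFrame({"mean_z": z.mean(), "sem_z": sd / np.sqrt(n), "n": n})


def euclidean_distance(z: pd.Series | np.ndarray) -> float:
    """Euclidean norm of a fingerprint over its non-missing measures.

    The reference-group mean sits at the origin of fingerprint space, so
    this is the distance of a larva from its control-sibling centroid.
    """
    z = np.asarray(z, dtype=float)
    ok = ~np.isnan(z)
    if not ok.any():
        raise ValueError("fingerprint has no non-missing measures")
    return float(np.sqrt(np.sum(z[ok] ** 2)))


def distances(fingerprints: pd.DataFrame) -> pd.DataFrame:
    """Per-larva Euclidean distances with the measure count used.

    Distances over differing measure subsets are not directly comparable;
    ``n_measures`` makes the subset auditable.
    """
    z = _strip_group(fingerprints)
    out = pd.DataFrame(
        {
            "n_measures": z.notna().sum(axis=1),
            "distance": [euclidean_distance(row.to_numpy()) for _, row in z.iterrows()],
        },
        index=z.index,
    )
    return out


def correlate(a, b, min_overlap: int = 5) -> float:
    """Pearson correlation of two fingerprints over shared non-missing
    measures, aligned by measure name when Series are given.

    Raises if fewer than ``min_overlap`` measures are shared; returns NaN
    (with a warning) when either side has zero variance on the overlap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be a positive integer")
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        shared = a.index.intersection(b.index)
        av, bv = a.loc[shared].to_numpy(float), b.loc[shared].to_numpy(float)
    else:
        av, bv = np.asarray(a, float), np.asarray(b, float)
        if av.shape != bv.shape:
            raise ValueError("fingerprints have different measure sets and no names to align by")
    ok = ~(np.isnan(av) | np.isnan(bv))
    if ok.sum() < min_overlap:
        raise ValueError(f"only {int(ok.sum())} shared non-missing measures (< {min_overlap})")
    av, bv = av[ok], bv[ok]
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        warnings.warn("zero variance on the shared measures; correlation undefined")
        return float("nan")
    return float(np.corrcoef(av, bv)[0, 1])
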