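"""Condition-specific peak statistics for single-cell accessibility data.

Per peak, the intensity distributions of the two conditions (e.g. wild type
vs mutant cells of one cluster) are compared with one-tailed Wilcoxon
rank-sum and Kolmogorov–Smirnov tests in both directions. A peak is deemed
significant in a direction when the raw p-values pass fixed thresholds
(defaults 0.001 for Wilcoxon and 0.01 for KS, both tests required); no
multiple-testing correction is applied at this filtering step. The number
of significant peaks is then referred to an empirical null built by
shuffling the condition labels across cells (group sizes preserved),
recounting per shuffle, and applying the add-one estimator

    p_empirical = (1 + #{null count >= observed}) / (1 + n_shuffles).

A separate rule classifies bulk differential regions from a consumed
(ratio, FDR) table: up/down at FDR < 0.01 by the sign of the ratio, and an
"unaffected" control class at FDR > 0.95 with ratio inside (0.995, 1.005).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "PeakIntensityMatrix",
    "PermutationNull",
    "wilcoxon_one_tailed",
    "ks_one_tailed",
    "peak_significance",
    "permutation_null",
    "classify_regions",
    "PeakDifferentialTest",
]

DEFAULT_WILCOXON_P = 0.001
DEFAULT_KS_P = 0.01
DEFAULT_EXACT_CUTOFF = 12


@dataclass
class PeakIntensityMatrix:
    """Peaks × cells intensity matrix with a two-condition cell labeling.

    ``intensity`` rows are peaks, columns cells; ``condition`` maps every
    cell to one of exactly two labels, each with at least 2 cells.
    ``planted_peaks``, when present, records ground-truth differential
    peaks from the simulator.
    """

    intensity: pd.DataFrame
    condition: pd.Series
    planted_peaks: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.intensity = self.intensity.astype(float)
        self.condition = pd.Series(self.condition).astype(str)
        if (self.intensity.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        missing = [c for c in self.intensity.columns if c not in self.condition.index]
        if missing:
            raise ValueError(f"cells without a condition label: {missing[:5]}")
        self.condition = self.condition.loc[list(self.intensity.columns)]
        counts = self.condition.value_counts()
        if len(counts) != 2:
            raise ValueError(f"need exactly two conditions, got {list(counts.index)}")
        if (counts < 2).any():
            raise ValueError(f"every condition needs >= 2 cells, got {counts.to_dict()}")

    @property
    def peaks(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def cells(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def labels(self) -> tuple[str, str]:
        """The two condition labels, sorted for determinism."""
        return tuple(sorted(self.condition.unique()))  # type: ignore[return-value]

    @classmethod
    def from_csv(cls, matrix_path: str | Path, labels_path: str | Path) -> "PeakIntensityMatrix":
        mat = pd.read_csv(matrix_path, index_col=0)
        lab = pd.read_csv(labels_path, dtype=str)
        if not {"cell", "condition"} <= set(lab.columns):
            raise ValueError("labels CSV must have columns cell,condition")
        return cls(intensity=mat, condition=lab.set_index("cell")["condition"])

    def to_csv(self, matrix_path: str | Path, labels_path: str | Path) -> None:
        self.intensity.to_csv(matrix_path, index_label="peak")
        pd.DataFrame({"cell": self.condition.index, "condition": self.condition.to_numpy()}).to_csv(
            labels_path, index=False
        )


# ---------------------------------------------------------------------------
# scalar tests


def _as_sample(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("samples must be non-empty")
    return x


def wilcoxon_one_tailed(
    x, y, alternative: str = "greater", exact_cutoff: int = DEFAULT_EXACT_CUTOFF
) -> float:
    """One-tailed Wilcoxon rank-sum (Mann–Whitney) p-value.

    ``alternative="greater"`` tests whether ``x`` is stochastically greater
    than ``y``. Tie-free samples with total size <= ``exact_cutoff`` use the
    exact null distribution; larger or tied samples use the normal
    approximation with tie and continuity corrections.
    """
    x, y = _as_sample(x), _as_sample(y)
    if alternative not in ("greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_cutoff and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def ks_one_tailed(x, y, alternative: str = "greater") -> tuple[float, float]:
    """One-tailed two-sample Kolmogorov–Smirnov statistic and p-value.

    ``alternative="greater"`` tests whether ``x`` is stochastically greater
    than ``y``: D = sup_t (F_y(t) − F_x(t)), clamped at 0. The p-value is
    the one-sided asymptotic bound exp(−2 D² n_e) with effective size
    n_e = |x||y|/(|x|+|y|), clamped to (0, 1].
    """
    x, y = _as_sample(x), _as_sample(y)
    if alternative == "less":
        x, y = y, x
    elif alternative != "greater":
        raise ValueError(f"unknown alternative {alternative!r}")
    grid = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    D = float(max(0.0, np.max(fy - fx)))
    n_e = x.size * y.size / (x.size + y.size)
    p = float(min(1.0, np.exp(-2.0 * D * D * n_e)))
    return D, p


# ---------------------------------------------------------------------------
# vectorized per-peak machinery (shared by observed tests and shuffles)


class _MatrixTests:
    """Precomputed per-peak structures for fast tests under relabelings.

    Under label shuffling the intensity values never move, so per-peak
    ranks, tie corrections, sort orders and distinct-value boundaries are
    all label-independent and computed once.
    """

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float)
        P, N = self.values.shape
        self.N = N
        self.ranks = stats.rankdata(self.values, axis=1)
        # tie term sum(t^3 - t) per row
        sv = np.sort(self.values, axis=1)
        newgrp = np.concatenate(
            [np.ones((P, 1), dtype=bool), sv[:, 1:] != sv[:, :-1]], axis=1
        )
        grp = np.cumsum(newgrp, axis=1) - 1
        counts = np.zeros((P, N))
        rows = np.repeat(np.arange(P), N)
        np.add.at(counts, (rows, grp.ravel()), 1.0)
        self.tie_term = (counts**3 - counts).sum(axis=1)
        self.order = np.argsort(self.values, axis=1, kind="stable")
        # distinct-value boundaries in sorted order (last index of each run)
        self.boundary = np.concatenate(
            [sv[:, :-1] != sv[:, 1:], np.ones((P, 1), dtype=bool)], axis=1
        )

    def wilcoxon_p(self, a_masks: np.ndarray, n_a: int, n_b: int):
        """Asymptotic one-sided rank-sum p-values for many labelings.

        ``a_masks``: (L, N) boolean, True marking condition-A cells.
        Returns (p_a_greater, p_b_greater), each (P, L).
        """
        N = self.N
        r_a = self.ranks @ a_masks.T.astype(float)  # (P, L)
        u_a = r_a - n_a * (n_a + 1) / 2.0
        mu = n_a * n_b / 2.0
        var = n_a * n_b / 12.0 * ((N + 1) - self.tie_term / (N * (N - 1.0)))
        sd = np.sqrt(var)[:, None]  # (P, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_a = (u_a - mu - 0.5) / sd
            z_b = ((n_a * n_b - u_a) - mu - 0.5) / sd
        p_a = stats.norm.sf(z_a)
        p_b = stats.norm.sf(z_b)
        degenerate = var <= 0  # all N values tied: no evidence either way
        p_a[degenerate, :] = 1.0
        p_b[degenerate, :] = 1.0
        return p_a, p_b

    def ks_D(self, a_masks: np.ndarray, n_a: int, n_b: int):
        """One-sided KS statistics for many labelings; returns (D_a, D_b),
        each (P, L), chunked over labelings to bound memory."""
        P, N = self.values.shape
        L = a_masks.shape[0]
        D_a = np.empty((P, L))
        D_b = np.empty((P, L))
        chunk = max(1, int(4_000_000 // max(1, P * N)))
        bmask = self.boundary[None, :, :]
        for lo in range(0, L, chunk):
            am = a_masks[lo : lo + chunk].astype(float)
            a_sorted = am[:, self.order]  # (S, P, N)
            f_a = np.cumsum(a_sorted, axis=2) / n_a
            f_b = np.cumsum(1.0 - a_sorted, axis=2) / n_b
            diff = f_b - f_a
            D_a[:, lo : lo + chunk] = (
                np.where(bmask, diff, -np.inf).max(axis=2).clip(min=0.0).T
            )
            D_b[:, lo : lo + chunk] = (
                np.where(bmask, -diff, -np.inf).max(axis=2).clip(min=0.0).T
            )
        return D_a, D_b

    def ks_p(self, D: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
        n_e = n_a * n_b / (n_a + n_b)
        return np.minimum(1.0, np.exp(-2.0 * D * D * n_e))


def _direction_significance(p_w, p_ks, wilcoxon_p, ks_p, rule):
    if rule == "both":
        return (p_w < wilcoxon_p) & (p_ks < ks_p)
    if rule == "either":
        return (p_w < wilcoxon_p) | (p_ks < ks_p)
    raise ValueError(f"unknown combination rule {rule!r}")


def peak_significance(
    mat: PeakIntensityMatrix,
    wilcoxon_p: float = DEFAULT_WILCOXON_P,
    ks_p: float = DEFAULT_KS_P,
    rule: str = "both",
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
) -> pd.DataFrame:
    """Per-peak one-tailed tests in both directions with significance calls.

    Returns a long DataFrame with one row per (peak, direction), where
    ``direction`` names the condition whose intensity distribution is
    tested as stochastically greater. Raw p-values only — no correction.
    """
    lab_a, lab_b = mat.labels
    a_mask = (mat.condition == lab_a).to_numpy()
    n_a, n_b = int(a_mask.sum()), int((~a_mask).sum())
    values = mat.intensity.to_numpy()

    if values.shape[1] <= exact_cutoff:
        # small clusters: per-peak scalar path (exact Wilcoxon where tie-free)
        rows = []
        for pk, row in zip(mat.peaks, values):
            x, y = row[a_mask], row[~a_mask]
            for direction, (u, v) in ((lab_a, (x, y)), (lab_b, (y, x))):
                pw = wilcoxon_one_tailed(u, v, "greater", exact_cutoff)
                _, pk_p = ks_one_tailed(u, v, "greater")
                rows.append((pk, direction, pw, pk_p))
        out = pd.DataFrame(rows, columns=["peak", "direction", "p_wilcoxon", "p_ks"])
    else:
        mt = _MatrixTests(values)
        masks = a_mask[None, :]
        pw_a, pw_b = mt.wilcoxon_p(masks, n_a, n_b)
        D_a, D_b = mt.ks_D(masks, n_a, n_b)
        pks_a = mt.ks_p(D_a, n_a, n_b)
        pks_b = mt.ks_p(D_b, n_a, n_b)
        frames = []
        for direction, pw, pks in ((lab_a, pw_a, pks_a), (lab_b, pw_b, pks_b)):
            frames.append(
                pd.DataFrame(
                    {
                        "peak": mat.peaks,
                        "direction": direction,
                        "p_wilcoxon": pw[:, 0],
                        "p_ks": pks[:, 0],
                    }
                )
            )
        out = pd.concat(frames, ignore_index=True)
        # one row per (peak, direction) in input peak order
        order = {p: i for i, p in enumerate(mat.peaks)}
        out = out.sort_values(
            by=["peak", "direction"],
            key=lambda s: s.map(order) if s.name == "peak" else s,
            kind="mergesort",
            ignore_index=True,
        )
    out["significant"] = _direction_significance(
        out["p_wilcoxon"].to_numpy(), out["p_ks"].to_numpy(), wilcoxon_p, ks_p, rule
    )
    out.attrs["thresholds"] = {"wilcoxon_p": wilcoxon_p, "ks_p": ks_p}
    out.attrs["combination_rule"] = rule
    return out


def _count_significant(
    values: np.ndarray,
    a_masks: np.ndarray,
    wilcoxon_p: float,
    ks_p: float,
    rule: str,
    exact_cutoff: int,
) -> np.ndarray:
    """Number of significant peaks (either direction, counted once per
    peak) for each labeling in ``a_masks`` (L, N)."""
    n_a = int(a_masks[0].sum())
    n_b = values.shape[1] - n_a
    if not np.all(a_masks.sum(axis=1) == n_a):
        raise AssertionError("a shuffle changed the group sizes")
    if values.shape[1] <= exact_cutoff:
        counts = np.zeros(a_masks.shape[0], dtype=int)
        for li, am in enumerate(a_masks):
            c = 0
            for row in values:
                x, y = row[am], row[~am]
                sig = False
                for u, v in ((x, y), (y, x)):
                    pw = wilcoxon_one_tailed(u, v, "greater", exact_cutoff)
                    _, pkp = ks_one_tailed(u, v, "greater")
                    if _direction_significance(pw, pkp, wilcoxon_p, ks_p, rule):
                        sig = True
                        break
                c += sig
            counts[li] = c
        return counts
    mt = _MatrixTests(values)
    pw_a, pw_b = mt.wilcoxon_p(a_masks, n_a, n_b)
    D_a, D_b = mt.ks_D(a_masks, n_a, n_b)
    sig_a = _direction_significance(pw_a, mt.ks_p(D_a, n_a, n_b), wilcoxon_p, ks_p, rule)
    sig_b = _direction_significance(pw_b, mt.ks_p(D_b, n_a, n_b), wilcoxon_p, ks_p, rule)
    return (sig_a | sig_b).sum(axis=0).astype(int)


@dataclass
class PermutationNull:
    """Label-shuffling null for the number of significant peaks."""

    n_shuffles: int
    null_counts: np.ndarray
    observed: int
    p_empirical: float
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_shuffles": int(self.n_shuffles),
            "observed": int(self.observed),
            "p_empirical": float(self.p_empirical),
            "null_counts": [int(c) for c in self.null_counts],
        }


def permutation_null(
    mat: PeakIntensityMatrix,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator | None = None,
    wilcoxon_p: float = DEFAULT_WILCOXON_P,
    ks_p: float = DEFAULT_KS_P,
    rule: str = "both",
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
) -> PermutationNull:
    """Empirical null for the count of significant peaks.

    Each shuffle permutes the condition labels over cells (group sizes and
    every peak's value multiset preserved) and recounts significant peaks
    (both directions, deduplicated per peak). The empirical p-value uses
    the add-one estimator, so its smallest attainable value is
    1/(1 + n_shuffles).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lab_a, _ = mat.labels
    a_mask = (mat.condition == lab_a).to_numpy()
    values = mat.intensity.to_numpy()
    N = values.shape[1]

    observed = int(
        _count_significant(values, a_mask[None, :], wilcoxon_p, ks_p, rule, exact_cutoff)[0]
    )
    perms = np.argsort(rng.random((n_shuffles, N)), axis=1)
    shuffled_masks = a_mask[perms]
    null_counts = _count_significant(
        values, shuffled_masks, wilcoxon_p, ks_p, rule, exact_cutoff
    )
    p_emp = (1.0 + int((null_counts >= observed).sum())) / (1.0 + n_shuffles)
    return PermutationNull(
        n_shuffles=n_shuffles,
        null_counts=null_counts,
        observed=observed,
        p_empirical=p_emp,
        thresholds={"wilcoxon_p": wilcoxon_p, "ks_p": ks_p, "rule": rule},
    )


# ---------------------------------------------------------------------------
# bulk region classification


def classify_regions(
    stats_table: pd.DataFrame,
    sig_fdr: float = 0.01,
    unaffected_fdr: float = 0.95,
    ratio_window: tuple[float, float] = (0.995, 1.005),
) -> pd.Series:
    """Classify bulk differential regions as up / down / unaffected / none.

    ``stats_table`` needs columns ``ratio`` (mutant/WT accessibility) and
    ``fdr``, indexed by region (or with a ``region`` column). Rules:
    up iff fdr < sig_fdr and ratio > 1; down iff fdr < sig_fdr and
    ratio < 1; unaffected iff fdr > unaffected_fdr and the ratio lies
    strictly inside ``ratio_window``; everything else none.
    """
    df = stats_table
    if "region" in df.columns:
        df = df.set_index("region")
    ratio = df["ratio"].to_numpy(float)
    fdr = df["fdr"].to_numpy(float)
    bad = np.flatnonzero(ratio <= 0)
    if bad.size:
        raise ValueError(f"region {df.index[bad[0]]!r} has non-positive ratio")
    if ((fdr < 0) | (fdr > 1)).any():
        raise ValueError("fdr values must lie in [0, 1]")
    out = np.full(len(df), "none", dtype=object)
    out[(fdr < sig_fdr) & (ratio > 1)] = "up"
    out[(fdr < sig_fdr) & (ratio < 1)] = "down"
    lo, hi = ratio_window
    out[(fdr > unaffected_fdr) & (ratio > lo) & (ratio < hi)] = "unaffected"
    return pd.Series(out, index=df.index, name="class")


# ---------------------------------------------------------------------------
# estimator surface


class PeakDifferentialTest(BaseEstimator):
    """Estimator wrapping the per-peak tests and the permutation null.

    fit runs both one-tailed tests in both directions on a
    :class:`PeakIntensityMatrix` (or a peaks × cells DataFrame plus cell
    labels ``y``) and stores the results; :meth:`permutation_null` then
    builds the label-shuffling null for the significant-peak count.
    """

    def __init__(
        self,
        wilcoxon_p: float = DEFAULT_WILCOXON_P,
        ks_p: float = DEFAULT_KS_P,
        rule: str = "both",
        exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
    ):
        self.wilcoxon_p = wilcoxon_p
        self.ks_p = ks_p
        self.rule = rule
        self.exact_cutoff = exact_cutoff

    def fit(self, X, y=None) -> "PeakDifferentialTest":
        if isinstance(X, PeakIntensityMatrix):
            mat = X
        else:
            X = pd.DataFrame(X)
            if y is None:
                raise ValueError("cell condition labels y are required")
            mat = PeakIntensityMatrix(
                intensity=X, condition=pd.Series(np.asarray(y), index=X.columns)
            )
        self.matrix_ = mat
        self.results_ = peak_significance(
            mat, self.wilcoxon_p, self.ks_p, self.rule, self.exact_cutoff
        )
        sig = self.results_[self.results_["significant"]]
        self.significant_peaks_ = sorted(set(sig["peak"]), key=mat.peaks.index)
        self.n_significant_ = len(self.significant_peaks_)
        return self

    def permutation_null(
        self, n_shuffles: int = 1000, seed: int | None = None
    ) -> PermutationNull:
        if not hasattr(self, "matrix_"):
            raise ValueError("PeakDifferentialTest is not fitted")
        return permutation_null(
            self.matrix_,
            n_shuffles=n_shuffles,
            seed=seed,
            wilcoxon_p=self.wilcoxon_p,
            ks_p=self.ks_p,
            rule=self.rule,
            exact_cutoff=self.exact_cutoff,
        )
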