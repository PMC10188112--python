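import itertools

import numpy as np
import pandas as pd
import pytest

import larvaprint as lp
from larvaprint.peakstats import _MatrixTests


def wilcoxon_enumeration_oracle(x, y):
    """Exact one-sided (x greater) rank-sum p by enumerating all C(n+m, n)
    assignments of the pooled ranks to the x sample. Tie-free input only."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    rx = ranks[: len(x)].sum()
    n = len(x)
    total = 0
    at_least = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        total += 1
        if ranks[list(combo)].sum() >= rx - 1e-9:
            at_least += 1
    return at_least / total


def ks_sweep_oracle(x, y):
    """Brute-force one-sided KS: sweep every pooled value as threshold and
    compute the signed ECDF difference F_y - F_x by counting."""
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.sum(x <= t) / len(x)
        fy = np.sum(y <= t) / len(y)
        best = max(best, fy - fx)
    return best


class TestWilcoxonOneTailed:
    def test_disjoint_samples_exact_p(self):
        # all 20 rank assignments enumerable by hand: only one puts x on top
        assert lp.wilcoxon_one_tailed([4, 5, 6], [1, 2, 3], "greater") == pytest.approx(0.05)

    def test_identical_samples_no_evidence(self):
        p = lp.wilcoxon_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "greater")
        assert p >= 0.5

    def test_matches_enumeration_oracle_small_tie_free(self):
        rng = np.random.default_rng(77)
        for _ in range(40):
            nx, ny = rng.integers(1, 5, size=2)
            pooled = rng.permutation(np.arange(1.0, nx + ny + 1))  # tie-free
            x, y = pooled[:nx], pooled[nx:]
            p = lp.wilcoxon_one_tailed(x, y, "greater")
            assert p == pytest.approx(wilcoxon_enumeration_oracle(x, y), abs=1e-12)

    def test_complementary_tails_share_boundary_atom(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            pooled = rng.permutation(np.arange(1.0, 9.0))
            x, y = pooled[:4], pooled[4:]
            pg = lp.wilcoxon_one_tailed(x, y, "greater")
            pl = lp.wilcoxon_one_tailed(y, x, "greater")
            assert pg + pl >= 1.0 - 1e-12

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            lp.wilcoxon_one_tailed([], [1.0], "greater")

    def test_large_sample_uses_tie_corrected_normal(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x = rng.integers(0, 6, 30).astype(float)
        y = rng.integers(0, 6, 25).astype(float)
        expected = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
        assert lp.wilcoxon_one_tailed(x, y, "greater") == pytest.approx(float(expected))


class TestKSOneTailed:
    def test_disjoint_supports(self):
        D, p = lp.ks_one_tailed([4, 5, 6], [1, 2, 3], "greater")
        assert D == pytest.approx(1.0)
        assert p == pytest.approx(np.exp(-2 * 1.5), abs=1e-12)

    def test_identical_samples(self):
        D, p = lp.ks_one_tailed([1.0, 2.0], [1.0, 2.0], "greater")
        assert D == 0.0 and p == 1.0

    def test_matches_ecdf_sweep_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            x = rng.integers(0, 10, rng.integers(2, 15)).astype(float)
            y = rng.integers(0, 10, rng.integers(2, 15)).astype(float)
            D, _ = lp.ks_one_tailed(x, y, "greater")
            assert D == pytest.approx(ks_sweep_oracle(x, y), abs=1e-12)

    def test_less_is_mirror_of_greater(self):
        rng = np.random.default_rng(14)
        x, y = rng.standard_normal(8), rng.standard_normal(9)
        assert lp.ks_one_tailed(x, y, "less")[0] == pytest.approx(
            lp.ks_one_tailed(y, x, "greater")[0], abs=1e-15
        )


class TestPeakSignificance:
    def test_constant_peak_never_significant(self):
        mat = lp.PeakIntensityMatrix(
            intensity=pd.DataFrame(
                np.ones((1, 8)), index=["p1"], columns=[f"c{i}" for i in range(8)]
            ),
            condition=pd.Series(
                ["A"] * 4 + ["B"] * 4, index=[f"c{i}" for i in range(8)]
            ),
        )
        res = lp.peak_significance(mat)
        assert not res["significant"].any()
        assert (res["p_wilcoxon"] == 1.0).all() and (res["p_ks"] == 1.0).all()

    def test_vectorized_path_matches_scalar_tests(self):
        rng = np.random.default_rng(10)
        X = rng.negative_binomial(2, 0.15, size=(30, 40)).astype(float)
        cells = [f"c{i}" for i in range(40)]
        mat = lp.PeakIntensityMatrix(
            intensity=pd.DataFrame(X, index=[f"p{i}" for i in range(30)], columns=cells),
            condition=pd.Series(["A"] * 21 + ["B"] * 19, index=cells),
        )
        res = lp.peak_significance(mat).set_index(["peak", "direction"])
        a = mat.condition.to_numpy() == "A"
        for i in [0, 7, 29]:
            x, y = X[i, a], X[i, ~a]
            assert res.loc[(f"p{i}", "A"), "p_wilcoxon"] == pytest.approx(
                lp.wilcoxon_one_tailed(x, y, "greater", exact_cutoff=0), abs=1e-12
            )
            assert res.loc[(f"p{i}", "B"), "p_ks"] == pytest.approx(
                lp.ks_one_tailed(y, x, "greater")[1], abs=1e-12
            )

    def test_planted_peaks_enriched(self):
        sim = lp.simulate_peak_matrix(
            lp.PeakSimConfig(
                n_peaks=300,
                n_cells={"wt": 50, "mut": 50},
                fraction_differential=0.1,
                effect_size=4.0,
                seed=7,
            )
        )
        res = lp.peak_significance(sim)
        sig = set(res.loc[res["significant"], "peak"])
        planted = set(sim.planted_peaks)
        assert len(sig & planted) / len(planted) >= 0.8
        # null peaks called at roughly the per-direction threshold rate
        null_calls = len(sig - planted)
        assert null_calls <= 10

    def test_either_rule_is_more_permissive(self):
        sim = lp.simulate_peak_matrix(
            lp.PeakSimConfig(n_peaks=100, fraction_differential=0.2, effect_size=2.0, seed=3)
        )
        n_both = lp.peak_significance(sim, rule="both")["significant"].sum()
        n_either = lp.peak_significance(sim, rule="either")["significant"].sum()
        assert n_either >= n_both

    def test_estimator_surface(self):
        sim = lp.simulate_peak_matrix(
            lp.PeakSimConfig(n_peaks=50, fraction_differential=0.2, effect_size=6.0, seed=1)
        )
        est = lp.PeakDifferentialTest().fit(sim)
        assert est.n_significant_ == len(est.significant_peaks_)
        assert set(est.significant_peaks_) <= set(sim.peaks)


class TestPermutationNull:
    def test_plus_one_identity_when_observed_tops_null(self):
        sim = lp.simulate_peak_matrix(
            lp.PeakSimConfig(
                n_peaks=100, fraction_differential=0.3, effect_size=8.0, seed=21
            )
        )
        null = lp.permutation_null(sim, n_shuffles=1000, seed=2)
        assert null.observed > max(null.null_counts)
        assert null.p_empirical == pytest.approx(1.0 / 1001.0)

    def test_observed_zero_gives_p_one(self):
        sim = lp.simulate_peak_matrix(
            lp.PeakSimConfig(n_peaks=40, fraction_differential=0.0, seed=3)
        )
        null = lp.permutation_null(sim, n_shuffles=50, seed=4)
        if null.observed == 0:
            assert null.p_empirical == 1.0
        assert 1.0 / 51.0 <= null.p_empirical <= 1.0

    def test_shuffles_preserve_group_sizes_and_values(self):
        sim = lp.simulate_peak_matrix(lp.PeakSimConfig(n_peaks=20, seed=5))
        null = lp.permutation_null(sim, n_shuffles=20, seed=6)
        assert len(null.null_counts) == 20

    def test_reproducible_from_seed(self):
        sim = lp.simulate_peak_matrix(lp.PeakSimConfig(n_peaks=30, seed=8))
        a = lp.permutation_null(sim, n_shuffles=30, seed=9)
        b = lp.permutation_null(sim, n_shuffles=30, seed=9)
        np.testing.assert_array_equal(a.null_counts, b.null_counts)
        assert a.p_empirical == b.p_empirical

    def test_small_cluster_scalar_path(self):
        # 3+3 cells routes through the exact/scalar machinery
        cells = [f"c{i}" for i in range(6)]
        rng = np.random.default_rng(11)
        mat = lp.PeakIntensityMatrix(
            intensity=pd.DataFrame(
                rng.random((5, 6)) * 10, index=[f"p{i}" for i in range(5)], columns=cells
            ),
            condition=pd.Series(["A"] * 3 + ["B"] * 3, index=cells),
        )
        null = lp.permutation_null(mat, n_shuffles=25, seed=1)
        assert null.observed == 0  # 3v3 cannot reach p < 0.001
        assert null.p_empirical == 1.0


class TestClassifyRegions:
    @pytest.mark.parametrize(
        "fdr,ratio,expected",
        [
            (0.005, 1.5, "up"),
            (0.005, 0.5, "down"),
            (0.97, 1.000, "unaffected"),
            (0.50, 1.2, "none"),
            (0.96, 1.1, "none"),   # calm FDR but ratio outside window
            (0.005, 1.0, "none"),  # significant FDR but ratio exactly 1
            (0.95, 1.0, "none"),   # boundary: fdr must be strictly > 0.95
            (0.96, 0.995, "none"),  # boundary: ratio must be strictly inside
        ],
    )
    def test_rule_fixtures(self, fdr, ratio, expected):
        table = pd.DataFrame({"region": ["r1"], "ratio": [ratio], "fdr": [fdr]})
        assert lp.classify_regions(table).loc["r1"] == expected

    def test_classes_partition(self):
        rng = np.random.default_rng(23)
        table = pd.DataFrame(
            {
                "region": [f"r{i}" for i in range(500)],
                "ratio": rng.lognormal(0, 0.01, 500),
                "fdr": rng.random(500),
            }
        )
        classes = lp.classify_regions(table)
        assert set(classes.unique()) <= {"up", "down", "unaffected", "none"}
        # bit-exact reproducibility
        pd.testing.assert_series_equal(classes, lp.classify_regions(table))

    def test_nonpositive_ratio_rejected(self):
        table = pd.DataFrame({"region": ["r1"], "ratio": [0.0], "fdr": [0.5]})
        with pytest.raises(ValueError, match="r1"):
            lp.classify_regions(table)


class TestNullCalibrationQuick:
    def test_wilcoxon_type_I_rate_near_nominal(self):
        # pooled per-direction rejection rate at p<0.01 across null peaks
        rng = np.random.default_rng(300)
        rate_n = 0
        rejections = 0
        for seed in range(5):
            sim = lp.simulate_peak_matrix(
                lp.PeakSimConfig(n_peaks=400, fraction_differential=0.0, seed=1000 + seed)
            )
            mt = _MatrixTests(sim.intensity.to_numpy())
            a = (sim.condition == sim.labels[0]).to_numpy()
            pa, pb = mt.wilcoxon_p(a[None, :], int(a.sum()), int((~a).sum()))
            rejections += int((pa < 0.01).sum() + (pb < 0.01).sum())
            rate_n += 2 * 400
        from scipy import stats

        lo, hi = stats.binom.interval(0.999, rate_n, 0.01)
        assert lo <= rejections <= hi
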