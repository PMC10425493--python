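"""Median-of-ratios normalisation, NB Wald tests, BH adjustment, ANOVA/Dunnett."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bmtime import deg


def _counts(arr, probes=None, samples=None):
    arr = np.asarray(arr)
    probes = probes or [f"G{i}_1" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=probes, columns=samples)


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        counts = _counts([[10, 10, 10], [200, 200, 200]])
        assert np.allclose(deg.size_factors(counts), 1.0)

    def test_two_by_two_doubling(self):
        """sample2 = 2 x sample1 -> s = (1/sqrt(2), sqrt(2)) exactly."""
        counts = _counts([[10, 20], [100, 200]])
        s = deg.size_factors(counts)
        assert s.iloc[0] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert s.iloc[1] == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_zero_probe_excluded_from_reference(self):
        # the probe with a zero must not influence the factors
        counts = _counts([[10, 20], [0, 500]])
        s = deg.size_factors(counts)
        assert s.iloc[1] / s.iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_error_without_allpositive_probe(self):
        with pytest.raises(ValueError, match="positive counts"):
            deg.size_factors(_counts([[0, 5], [5, 0]]))

    def test_scaling_one_sample_scales_factors_relatively(self):
        """Scaling sample j by c multiplies s_j/s_k by c for every k != j.

        (The absolute factors all shift by c^(1/n) through the per-probe
        geometric means — visible already in the 2x2 doubling example — so
        the scaling identity of median-of-ratios is a relative one.)
        """
        rng = np.random.default_rng(0)
        counts = _counts(rng.integers(5, 500, size=(40, 6)))
        s0 = deg.size_factors(counts)
        scaled = counts.copy()
        scaled["s2"] = counts["s2"] * 3
        s1 = deg.size_factors(scaled)
        others = [c for c in counts.columns if c != "s2"]
        for k in others:
            assert s1["s2"] / s1[k] == pytest.approx(3 * s0["s2"] / s0[k],
                                                     rel=1e-9)
        # between-sample normalised profiles of the untouched samples agree
        z0 = deg.normalized_counts(counts, s0)
        z1 = deg.normalized_counts(scaled, s1)
        ratio = (z1[others] / z0[others]).to_numpy()
        assert np.allclose(ratio, ratio[0, 0])


class TestBH:
    def test_stepup_hand_example(self):
        assert np.allclose(deg.adjust_bh([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert deg.adjust_bh([0.3]) == pytest.approx([0.3])
        assert np.allclose(deg.adjust_bh([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            deg.adjust_bh([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_monotone_and_dominates_raw(self, p):
        q = deg.adjust_bh(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestNBWald:
    def _setup(self, Yt, Yc, alpha=0.05):
        counts = _counts(np.hstack([Yt, Yc]))
        tr = list(counts.columns[: Yt.shape[1]])
        ct = list(counts.columns[Yt.shape[1]:])
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(alpha, index=counts.index)
        return counts, tr, ct, sf, disp

    def test_identical_groups_null(self):
        Y = np.array([[10, 20, 30], [200, 150, 180]])
        counts, tr, ct, sf, disp = self._setup(Y, Y)
        res = deg.nb_wald_test(counts, tr, ct, sf, disp)
        assert np.allclose(res["log2FoldChange"], 0.0, atol=1e-8)
        assert np.allclose(res["pvalue"], 1.0)

    def test_label_swap_negates_lfc_preserves_p(self):
        rng = np.random.default_rng(1)
        Yt = rng.poisson(300, (30, 3))
        Yc = rng.poisson(150, (30, 3))
        counts, tr, ct, sf, disp = self._setup(Yt, Yc)
        a = deg.nb_wald_test(counts, tr, ct, sf, disp)
        b = deg.nb_wald_test(counts, ct, tr, sf, disp)
        assert np.allclose(a["log2FoldChange"], -b["log2FoldChange"], atol=1e-6)
        assert np.allclose(a["pvalue"], b["pvalue"], atol=1e-8)

    def test_all_zero_probe_untestable(self):
        Yt = np.array([[0, 0, 0], [50, 60, 70]])
        Yc = np.array([[0, 0, 0], [50, 60, 70]])
        counts, tr, ct, sf, disp = self._setup(Yt, Yc)
        res = deg.nb_wald_test(counts, tr, ct, sf, disp)
        assert res["pvalue"].iloc[0] == 1.0
        assert res["log2FoldChange"].iloc[0] == 0.0

    def test_matches_statsmodels_glm(self):
        """Cross-check beta and SE against an independent NB GLM fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        Yt = rng.poisson(400, (5, 4))
        Yc = rng.poisson(100, (5, 4))
        alpha = 0.08
        counts, tr, ct, sf, disp = self._setup(Yt, Yc, alpha)
        res = deg.nb_wald_test(counts, tr, ct, sf, disp)
        y = np.concatenate([Yt[0], Yc[0]])
        X = np.column_stack([np.ones(8), np.r_[np.ones(4), np.zeros(4)]])
        glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        assert res["log2FoldChange"].iloc[0] == pytest.approx(
            glm.params[1] / np.log(2), rel=1e-4)
        assert res["lfcSE"].iloc[0] == pytest.approx(
            glm.bse[1] / np.log(2), rel=0.05)

    def test_requires_two_samples_per_group(self):
        counts = _counts([[1, 2, 3]])
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        with pytest.raises(ValueError, match="2 samples"):
            deg.nb_wald_test(counts, ["s0"], ["s1", "s2"], sf, disp)


class TestDispersions:
    def _run(self, alpha, n_groups=6, n_rep=50, mu=300.0, seed=0):
        rng = np.random.default_rng(seed)
        G = 300
        if alpha == 0:
            Y = rng.poisson(mu, (G, n_groups * n_rep))
        else:
            lam = rng.gamma(1 / alpha, alpha * mu, (G, n_groups * n_rep))
            Y = rng.poisson(lam)
        counts = _counts(Y)
        sf = pd.Series(1.0, index=counts.columns)
        groups = np.repeat(np.arange(n_groups), n_rep)
        return deg.estimate_dispersions(counts, sf, groups)

    def test_poisson_data_near_zero(self):
        assert self._run(0.0).median() < 0.01

    def test_nb_data_recovers_alpha(self):
        med = self._run(0.1).median()
        assert 0.05 <= med <= 0.2

    def test_constant_counts_zero(self):
        counts = _counts(np.full((5, 6), 100))
        sf = pd.Series(1.0, index=counts.columns)
        alpha = deg.estimate_dispersions(counts, sf, [0, 0, 0, 1, 1, 1])
        assert np.allclose(alpha, 0.0)

    def test_single_replicate_design_rejected(self):
        counts = _counts(np.full((5, 3), 100))
        sf = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError, match="2 replicates"):
            deg.estimate_dispersions(counts, sf, [0, 1, 2])


class TestAnovaDunnett:
    def test_identical_groups_near_one(self):
        g = {"ctrl": [1.0, 1.1, 0.9], "a": [1.0, 1.1, 0.9], "b": [1.0, 1.1, 0.9]}
        _, pvals = deg.anova_dunnett(g, "ctrl")
        assert all(p > 0.9 for p in pvals.values())

    def test_single_comparison_reduces_to_t_test(self):
        rng = np.random.default_rng(3)
        a, c = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        _, pvals = deg.anova_dunnett({"ctrl": c, "a": a}, "ctrl")
        t_p = stats.ttest_ind(a, c).pvalue
        assert pvals["a"] == pytest.approx(t_p, abs=0.01)

    def test_degenerate_zero_variance(self):
        same = {"ctrl": [2.0, 2.0], "a": [2.0, 2.0]}
        p, pv = deg.anova_dunnett(same, "ctrl")
        assert p == 1.0 and pv["a"] == 1.0
        diff = {"ctrl": [2.0, 2.0], "a": [3.0, 3.0]}
        p, pv = deg.anova_dunnett(diff, "ctrl")
        assert p == 0.0 and pv["a"] == 0.0

    def test_familywise_error_against_monte_carlo(self):
        """Null 3-groups-vs-control: P(min adjusted p < 0.05) ~ 0.05."""
        rng = np.random.default_rng(12)
        hits = 0
        n_trials = 400
        for i in range(n_trials):
            groups = {k: rng.normal(0, 1, 3) for k in ("ctrl", "a", "b", "c")}
            _, pv = deg.anova_dunnett(groups, "ctrl", seed=i)
            hits += min(pv.values()) < 0.05
        assert hits / n_trials == pytest.approx(0.05, abs=0.025)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="control label"):
            deg.anova_dunnett({"a": [1, 2, 3]}, "ctrl")
        with pytest.raises(ValueError, match="non-control"):
            deg.anova_dunnett({"ctrl": [1, 2, 3]}, "ctrl")
        with pytest.raises(ValueError, match="replicates"):
            deg.anova_dunnett({"ctrl": [1.0], "a": [1, 2]}, "ctrl")


def test_normalize_reporter():
    assert np.allclose(deg.normalize_reporter([5, 7, 9]), [0, 2, 4])
    assert np.allclose(deg.normalize_reporter([3, 3, 3]), 0.0)
    assert np.allclose(deg.normalize_reporter([4.0]), [0.0])
    with pytest.raises(ValueError, match="empty"):
        deg.normalize_reporter([])


def test_deg_time_series_counts_and_peak(small_sim, small_run):
    """Inert compound stays near zero; the active compound's counts rise."""
    workdir, report, _ = small_run
    inert = report["compounds"]["inert_control"]["significant_degs_per_time"]
    assert sum(inert.values()) <= 3
    active = report["compounds"]["metalotox"]["significant_degs_per_time"]
    assert active["24"] > 20
    assert active["1"] <= 5


def test_peak_time_tie_breaks_earlier():
    """Counts (0, 3, 10, 10) at times (1, 2, 4, 6) peak at the earlier 4 h."""
    assert deg.peak_time(pd.Series({1.0: 0, 2.0: 3, 4.0: 10, 6.0: 10})) == 4.0
    assert deg.peak_time(pd.Series({6.0: 10, 1.0: 0, 4.0: 10, 2.0: 3})) == 4.0


def test_pca_coordinates_shape(small_sim):
    _, counts, metadata, _ = small_sim
    coords = deg.pca_coordinates(counts.iloc[:, :12])
    assert coords.shape == (12, 2)
    assert list(coords.columns) == ["PC1", "PC2"]
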