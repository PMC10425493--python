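"""Benchmark-time engine: responses, trend test, bounds, filters, summaries."""

import numpy as np
import pandas as pd
import pytest

from bmtime import models
from bmtime.bmt import (
    TimeResponse,
    accumulation_curve,
    apply_retention_filters,
    bmt_confidence,
    build_time_response,
    compute_bmt,
    earliest_response_genes,
    fit_5pl,
    fit_5pl_predict,
    prefilter,
    resolve_bmr,
    williams_trend_test,
)
from bmtime.deg import size_factors


def _flat_design(n_times=9, reps=3):
    times = [1.0, 2, 4, 6, 8, 12, 16, 20, 24][:n_times]
    rows = []
    for lab, veh in (("cmpd", False), ("DMSO", True)):
        for t in times:
            for r in range(1, reps + 1):
                rows.append((f"{lab}_t{t:g}_r{r}", lab, 1.0, t, r, veh))
    return pd.DataFrame(rows, columns=["sample_id", "compound", "concentration",
                                       "time_h", "replicate", "is_vehicle"])


class TestBuildTimeResponse:
    def test_treated_equal_control_gives_zero(self):
        md = _flat_design()
        rng = np.random.default_rng(0)
        base = np.repeat(rng.integers(200, 800, size=(20, 1)), 54, axis=1)
        counts = pd.DataFrame(base, index=[f"G{i}_1" for i in range(20)],
                              columns=list(md["sample_id"]))
        responses = build_time_response(counts, md, "cmpd")
        for tr in responses.values():
            assert np.max(np.abs(tr.y)) < 1e-9
            assert abs(tr.anchor_values().mean()) < 1e-12  # centred anchor

    def test_doubling_treated_counts_shifts_response_by_one(self):
        md = _flat_design()
        counts = pd.DataFrame(2000, index=["G0_1"], columns=list(md["sample_id"]))
        doubled = counts.copy()
        at8 = md[(md["compound"] == "cmpd") & (md["time_h"] == 8.0)]["sample_id"]
        doubled[list(at8)] *= 2
        sf = pd.Series(1.0, index=counts.columns)
        r0 = build_time_response(counts, md, "cmpd", sf=sf)["G0_1"]
        r1 = build_time_response(doubled, md, "cmpd", sf=sf)["G0_1"]
        shift = r1.y[r1.t == 8.0] - r0.y[r0.t == 8.0]
        assert np.allclose(shift, 1.0, atol=2e-3)  # log2 identity (pc-limited)
        assert np.allclose(r1.y[r1.t == 4.0], r0.y[r0.t == 4.0])

    def test_anchor_structure(self):
        md = _flat_design()
        counts = pd.DataFrame(500, index=["G0_1"], columns=list(md["sample_id"]))
        tr = build_time_response(counts, md, "cmpd")["G0_1"]
        assert tr.levels[0] == 0.0
        assert (tr.t == 0).sum() == 27  # one contrast per control replicate
        assert len(tr.levels) == 10


class TestWilliams:
    def test_constant_data_p_one(self, times30):
        tr = TimeResponse("x", times30, np.full_like(times30, 2.0))
        p, fc = williams_trend_test(tr, n_perm=200, seed=0)
        assert p == 1.0

    def test_noiseless_trend_hits_permutation_floor(self, times30):
        y = np.repeat(np.arange(10.0), 3)
        tr = TimeResponse("x", times30, y)
        n_perm = 500
        p, _ = williams_trend_test(tr, n_perm=n_perm, seed=1)
        assert p == pytest.approx(2.0 / (n_perm + 1))

    def test_decreasing_trend_detected(self, times30):
        rng = np.random.default_rng(4)
        y = -np.repeat(np.linspace(0, 3, 10), 3) + rng.normal(0, 0.2, 30)
        p, fc = williams_trend_test(TimeResponse("x", times30, y),
                                    n_perm=500, seed=2)
        assert p < 0.01
        assert fc > 2.0

    def test_max_fc_is_over_level_means(self, times30):
        y = np.zeros(30)
        y[times30 == 8.0] = [3.0, 0.0, 0.0]  # level mean 1.0
        _, fc = williams_trend_test(TimeResponse("x", times30, y),
                                    n_perm=50, seed=0)
        assert fc == pytest.approx(1.0)

    def test_too_few_levels_rejected(self):
        tr = TimeResponse("x", np.array([0.0, 0.0, 1.0, 1.0]),
                          np.array([0.0, 0.1, 1.0, 1.2]))
        with pytest.raises(ValueError, match="ordered levels"):
            williams_trend_test(tr, n_perm=10, seed=0)


def test_prefilter_thresholds(times30):
    rng = np.random.default_rng(9)
    strong = models.curve("Hill", [0, 3, 4, 3], times30) + rng.normal(0, 0.2, 30)
    weak = models.curve("Hill", [0, 0.5, 4, 3], times30) + rng.normal(0, 0.2, 30)
    flat = rng.normal(0, 0.2, 30)
    responses = {
        "strong_1": TimeResponse("strong_1", times30, strong),
        "weak_1": TimeResponse("weak_1", times30, weak),
        "flat_1": TimeResponse("flat_1", times30, flat),
    }
    tab = prefilter(responses, n_perm=300, seed=5)
    assert bool(tab.loc["strong_1", "eligible"])
    assert not tab.loc["weak_1", "eligible"]  # trend but |FC| below cut
    assert not tab.loc["flat_1", "eligible"]


def test_resolve_bmr(times30):
    rng = np.random.default_rng(0)
    y = rng.normal(0, 0.5, 30)
    tr = TimeResponse("x", times30, y)
    assert resolve_bmr("abs:1.0", tr) == 1.0
    assert resolve_bmr(0.7, tr) == 0.7
    sd = np.std(tr.anchor_values(), ddof=1)
    assert resolve_bmr("sd:1.349", tr) == pytest.approx(1.349 * sd)
    with pytest.raises(ValueError):
        resolve_bmr("pct:5", tr)
    with pytest.raises(ValueError):
        resolve_bmr(-1.0, tr)


class TestRetention:
    def _df(self, bmt, bmtl, bmtu, fitp):
        return pd.DataFrame({"BMT": [bmt], "BMTL": [bmtl], "BMTU": [bmtu],
                             "fitPValue": [fitp]})

    def test_window_and_strictness(self):
        assert not apply_retention_filters(
            self._df(25.0, 20, 30, 0.5))["retained"].iloc[0]  # beyond 24 h
        assert not apply_retention_filters(
            self._df(0.05, 0.02, 0.2, 0.5))["retained"].iloc[0]  # below 6 min
        assert not apply_retention_filters(
            self._df(5.0, 1.0, 40.0, 0.5))["retained"].iloc[0]  # ratio == 40
        assert not apply_retention_filters(
            self._df(5.0, 3.0, 8.0, 0.1))["retained"].iloc[0]  # fitP == 0.1
        assert apply_retention_filters(
            self._df(5.0, 3.0, 8.0, 0.11))["retained"].iloc[0]

    def test_nan_bounds_never_retained(self):
        out = apply_retention_filters(self._df(5.0, np.nan, np.nan, 0.5))
        assert not out["retained"].iloc[0]


class TestConfidence:
    def test_noiseless_ratio_tends_to_one(self, times30):
        y = models.curve("Hill", [0, 3, 6, 3], times30)
        fit = models.fit_family("Hill", times30, y)
        bmtl, bmtu = bmt_confidence(fit, TimeResponse("x", times30, y), 1.0,
                                    n_boot=60, seed=3)
        assert bmtu / bmtl < 1.01

    def test_ratio_grows_with_noise(self, times30):
        med = []
        for sigma in (0.1, 0.4):
            ratios = []
            for rep in range(8):
                rng = np.random.default_rng(100 * rep + int(sigma * 10))
                y = models.curve("Hill", [0, 3, 6, 3], times30) + rng.normal(
                    0, sigma, 30)
                fit = models.fit_family("Hill", times30, y)
                lo, hi = bmt_confidence(fit, TimeResponse("x", times30, y), 1.0,
                                        n_boot=50, seed=rng)
                if np.isfinite(lo) and lo > 0 and np.isfinite(hi):
                    ratios.append(hi / lo)
            med.append(np.median(ratios))
        assert med[1] > med[0]


def test_time_unit_equivariance(times30):
    """Refitting with minutes rescales the BMT by 60 and nothing else."""
    rng = np.random.default_rng(21)
    y = models.curve("Exp4", [0, 2.5, 0.25], times30) + rng.normal(0, 0.2, 30)
    out = {}
    for unit, scale in (("h", 1.0), ("min", 60.0)):
        t = times30 * scale
        best = models.select_best(models.fit_all(t, y))
        out[unit] = (best, compute_bmt(best, 1.0, t.max()))
    assert out["min"][1] == pytest.approx(60.0 * out["h"][1], rel=1e-3)
    assert out["min"][0].fit_p == pytest.approx(out["h"][0].fit_p, abs=1e-6)


class TestAccumulation:
    def test_step_curve_example(self):
        acc = accumulation_curve([2.0, 2.0, 5.0])
        assert list(acc["time_h"]) == [2.0, 5.0]
        assert list(acc["cumulative_count"]) == [2, 3]

    def test_final_count_and_monotone(self):
        rng = np.random.default_rng(0)
        bmts = rng.uniform(0.5, 24, 50)
        acc = accumulation_curve(bmts)
        assert acc["cumulative_count"].iloc[-1] == 50
        assert (np.diff(acc["cumulative_count"]) > 0).all()
        assert (np.diff(acc["time_h"]) > 0).all()

    def test_empty(self):
        assert accumulation_curve([]).empty


class TestEarliestGenes:
    def _tables(self):
        def tab(rows):
            df = pd.DataFrame(rows, columns=["probe", "gene", "log2FoldChange",
                                             "padj"]).set_index("probe")
            return df

        return {
            4.0: tab([("A_1", "A", 3.0, 0.001), ("B_1", "B", 2.0, 0.001),
                      ("C_1", "C", 5.0, 0.5)]),
            20.0: tab([("A_1", "A", 3.5, 0.001), ("C_1", "C", 4.0, 0.001)]),
            24.0: tab([("C_1", "C", 4.2, 0.001), ("D_1", "D", -2.5, 0.005)]),
        }

    def test_first_time_and_tie_rule(self):
        out = earliest_response_genes(self._tables())
        assert list(out["gene"]) == ["A", "B", "C", "D"]  # |lfc| 3 > 2 at 4 h
        assert out.loc[out["gene"] == "C", "first_time_h"].iloc[0] == 20.0
        assert out.loc[out["gene"] == "D", "direction"].iloc[0] == "down"

    def test_no_significant_genes(self):
        tabs = {1.0: self._tables()[4.0].assign(padj=0.9)}
        assert earliest_response_genes(tabs).empty


class TestFivePL:
    def test_generate_and_refit_exact(self, times30):
        p_true = np.array([-0.2, 3.0, 0.7, 2.0, 1.5])
        t = np.unique(times30)
        x = np.log10(t + 0.1)
        from bmtime.bmt import _5pl_curve

        y = _5pl_curve(x, p_true)
        fit = fit_5pl(t, y)
        assert np.allclose(fit.params, p_true, atol=1e-4)
        assert np.allclose(fit(t), y, atol=1e-6)

    def test_constant_data_predicts_constant(self, times30):
        tr = TimeResponse("x", times30, np.full(30, 1.7))
        assert fit_5pl_predict(tr, 6.0) == pytest.approx(1.7, abs=1e-6)

    def test_4pl_reduction(self, times30):
        from bmtime.bmt import _5pl_curve

        t = np.unique(times30)
        x = np.log10(t + 0.1)
        y = _5pl_curve(x, np.array([0.0, 2.0, 0.8, 1.5, 1.0]))  # s = 1 truth
        full = fit_5pl(t, y)
        reduced = fit_5pl(t, y, fix_s=1.0)
        grid = np.linspace(0.5, 24, 40)
        assert np.allclose(full(grid), reduced(grid), atol=1e-3)

    def test_needs_five_levels(self):
        t = np.repeat([0.0, 2, 8, 24], 3)
        with pytest.raises(ValueError, match="5 distinct"):
            fit_5pl(t, np.zeros_like(t))

    def test_predict_on_responder(self, times30):
        rng = np.random.default_rng(6)
        y = models.curve("Hill", [0, 3, 6, 3], times30) + rng.normal(0, 0.15, 30)
        tr = TimeResponse("x", times30, y)
        pred = fit_5pl_predict(tr, 4.76)
        # at the BMT the planted curve sits near 1 log2 unit
        assert pred == pytest.approx(1.0, abs=0.5)
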