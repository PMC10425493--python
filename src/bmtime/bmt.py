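"""Benchmark-time engine: trend prefilter, curve fitting, BMT derivation.

The workflow mirrors benchmark-dose practice transposed to the time axis:
per-probe log2 fold-change responses over the time grid (with a constructed
t = 0 anchor from control replicates) are prefiltered with a Williams-type
trend test, fitted with ten parametric families, the lowest-AIC fit is
inverted at a benchmark response (BMR) to give the benchmark time (BMT),
parametric-bootstrap confidence bounds BMTL/BMTU are attached, and results
are filtered (BMT inside the tested window, BMTU/BMTL < 40, goodness-of-fit
p > 0.1) before summarisation as accumulation curves, earliest-response gene
rankings, and 5-parameter-logistic predicted fold changes at the BMT.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import models
from .deg import normalized_counts, size_factors
from .io import probe_to_gene, select_samples

#: default retention filters
RATIO_MAX = 40.0
FIT_P_MIN = 0.1
T_MIN = 0.1  # hours (6 min), lower bound of the reporting window

DEFAULT_BMR_SPEC = "sd:1.349"
PSEUDOCOUNT = 0.5


@dataclass
class TimeResponse:
    """Per-probe replicate responses (log2FC vs time-matched control) over time.

    t and y are flat, observation-aligned arrays; t includes the 0-h anchor
    level built from control-only contrasts, whose values are centred at 0.
    """

    probe: str
    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.y = np.asarray(self.y, float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must align")

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.t)

    def anchor_values(self) -> np.ndarray:
        return self.y[self.t == self.t.min()]

    def level_means(self, include_anchor: bool = False) -> pd.Series:
        lv = self.levels if include_anchor else self.levels[1:]
        return pd.Series({float(l): self.y[self.t == l].mean() for l in lv})


def build_time_response(counts: pd.DataFrame, metadata: pd.DataFrame,
                        compound: str, sf: pd.Series | None = None,
                        pseudocount: float = PSEUDOCOUNT) -> dict[str, TimeResponse]:
    """Per-probe time responses for one compound.

    At each time t the per-replicate response is log2(normalised treated +
    pc) - log2(mean normalised control at t + pc).  The t = 0 anchor holds
    control-only contrasts — each control replicate against the mean of the
    other replicates at its time point, pooled over time points and centred at
    zero — so the anchor carries replicate noise at zero mean, the analogue of
    the zero-dose group in dose-response modelling.
    """
    treated_md, control_md = select_samples(metadata, compound)
    cols = list(treated_md["sample_id"]) + list(control_md["sample_id"])
    if sf is None:
        sf = size_factors(counts[cols])
    z = normalized_counts(counts[cols], sf.reindex(cols))
    times = sorted(treated_md["time_h"].unique())

    t_list, y_blocks = [], []
    # anchor: leave-one-out control contrasts at every time point
    for t in times:
        csel = control_md.loc[control_md["time_h"] == t, "sample_id"].tolist()
        zc = z[csel].to_numpy()
        for i in range(len(csel)):
            others = np.delete(zc, i, axis=1).mean(axis=1)
            y_blocks.append(np.log2(zc[:, i] + pseudocount)
                            - np.log2(others + pseudocount))
            t_list.append(0.0)
    n_anchor = len(t_list)

    for t in times:
        tsel = treated_md.loc[treated_md["time_h"] == t, "sample_id"].tolist()
        csel = control_md.loc[control_md["time_h"] == t, "sample_id"].tolist()
        cmean = z[csel].to_numpy().mean(axis=1)
        for s in tsel:
            y_blocks.append(np.log2(z[s].to_numpy() + pseudocount)
                            - np.log2(cmean + pseudocount))
            t_list.append(float(t))

    t_obs = np.asarray(t_list)
    Y = np.column_stack(y_blocks)  # probes x observations
    Y[:, :n_anchor] -= Y[:, :n_anchor].mean(axis=1, keepdims=True)
    return {p: TimeResponse(p, t_obs, Y[i]) for i, p in enumerate(counts.index)}


# ---------------------------------------------------------------------------
# Williams-type trend prefilter
# ---------------------------------------------------------------------------

def _amalgamated_stats(level_means, n_levels, mean0, n0, pooled_var):
    """Williams statistics (increasing, decreasing) from treatment-level means.

    The isotonic amalgamated mean of the highest level equals the extreme of
    the weighted suffix means of the ordered level means (max for an
    increasing trend, min for a decreasing one).
    """
    w = n_levels.astype(float)
    sw = np.cumsum((level_means * w)[..., ::-1], axis=-1)
    cw = np.cumsum(w[::-1])
    suffix = sw / cw
    amal_up = suffix.max(axis=-1)
    amal_dn = suffix.min(axis=-1)
    se = np.sqrt(pooled_var * (1.0 / n_levels[-1] + 1.0 / n0))
    se = np.maximum(se, 1e-300)
    return (amal_up - mean0) / se, (mean0 - amal_dn) / se


def williams_trend_test(tr: TimeResponse, n_perm: int = 1000,
                        seed: int | np.random.Generator = 0):
    """Williams-type trend test across ordered time levels, by permutation.

    The statistic is the isotonically amalgamated mean of the last level minus
    the anchor mean, standardised by the pooled within-level error.  Both
    trend directions are tested; p = min(1, 2 * min one-sided p), each
    one-sided p from ``n_perm`` permutations of observations across levels
    with an add-one correction.  Returns (p, max |level-mean log2FC|).
    """
    levels = tr.levels
    if levels.size < 3:
        raise ValueError("need the anchor plus >= 2 ordered levels")
    order = np.argsort(tr.t, kind="stable")
    y = tr.y[order]
    t = tr.t[order]
    n_l = np.array([(t == l).sum() for l in levels])
    starts = np.concatenate([[0], np.cumsum(n_l)[:-1]])
    N = y.size
    L = levels.size

    def stats_for(ym):
        sums = np.add.reduceat(ym, starts, axis=-1)
        means = sums / n_l
        ss_within = (ym ** 2).sum(axis=-1) - (n_l * means ** 2).sum(axis=-1)
        dof = N - L
        pooled = np.maximum(ss_within / dof, 0.0)
        return _amalgamated_stats(means[..., 1:], n_l[1:], means[..., 0],
                                  n_l[0], pooled)

    up_obs, dn_obs = stats_for(y)
    max_fc = float(np.max(np.abs(
        np.add.reduceat(y, starts)[1:] / n_l[1:])))

    if not np.isfinite(up_obs) or (np.var(y) == 0.0):
        return 1.0, max_fc

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, N)), axis=1)
    yp = y[idx]
    up_p, dn_p = stats_for(yp)
    p_up = (1.0 + np.sum(up_p >= up_obs)) / (n_perm + 1.0)
    p_dn = (1.0 + np.sum(dn_p >= dn_obs)) / (n_perm + 1.0)
    return float(min(1.0, 2.0 * min(p_up, p_dn))), max_fc


def prefilter(responses: dict[str, TimeResponse], alpha: float = 0.05,
              lfc_threshold: float = 1.0, n_perm: int = 1000,
              seed: int = 0) -> pd.DataFrame:
    """Williams prefilter over all probes: p < alpha and max |log2FC| > threshold.

    Returns a per-probe table (williams_p, max_abs_lfc, eligible); each probe
    uses an independent child RNG stream of ``seed`` so the scan is
    deterministic and order-independent.
    """
    root = np.random.default_rng(seed)
    streams = root.spawn(len(responses))
    rows = []
    for (probe, tr), rng in zip(responses.items(), streams):
        p, fc = williams_trend_test(tr, n_perm=n_perm, seed=rng)
        rows.append((probe, p, fc, (p < alpha) and (fc > lfc_threshold)))
    return pd.DataFrame(rows, columns=["probe", "williams_p", "max_abs_lfc",
                                       "eligible"]).set_index("probe")


# ---------------------------------------------------------------------------
# BMT derivation
# ---------------------------------------------------------------------------

def resolve_bmr(bmr_spec, tr: TimeResponse) -> float:
    """Resolve a BMR spec to an absolute log2FC.

    'sd:<f>' means f times the anchor (t = 0) response standard deviation —
    the continuous-endpoint convention (default factor 1.349); 'abs:<b>' or a
    bare number is an absolute log2 fold change.
    """
    if isinstance(bmr_spec, (int, float)):
        b = float(bmr_spec)
    elif bmr_spec.startswith("sd:"):
        anchor = tr.anchor_values()
        sd = float(np.std(anchor, ddof=1)) if anchor.size > 1 else 0.0
        b = float(bmr_spec[3:]) * sd
    elif bmr_spec.startswith("abs:"):
        b = float(bmr_spec[4:])
    else:
        raise ValueError(f"bad BMR spec {bmr_spec!r}")
    if b <= 0:
        raise ValueError("resolved BMR must be positive")
    return b


def compute_bmt(fit: models.ModelFit, bmr: float,
                t_max_observed: float) -> float | None:
    """Smallest t > 0 with |mu(t) - mu(0)| = BMR; None if unreached before
    10x the last observed time."""
    return models.benchmark_time(fit.family, fit.theta, bmr,
                                 t_max=10.0 * t_max_observed)


def bmt_confidence(fit: models.ModelFit, tr: TimeResponse, bmr: float,
                   level: float = 0.90, n_boot: int = 250,
                   seed: int | np.random.Generator = 0):
    """Percentile parametric-bootstrap confidence bounds (BMTL, BMTU).

    Gaussian residuals are resampled onto the fitted curve; each replicate is
    refitted within the same family (seeded from the original estimate) and
    its BMT recomputed at the *fixed* resolved BMR.  The residual scale is the
    unbiased estimate sqrt(RSS/(n - p)), and each replicate draws its own
    sigma from the scaled inverse-chi-square sampling distribution so that the
    uncertainty of the variance estimate propagates into the bounds.
    Replicates whose refit does not converge count as failures; replicates
    whose curve never reaches the BMR contribute +inf (they widen the upper
    bound).  More than 50% failures yields undefined (nan, nan) bounds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # unbiased residual variance: the MLE rss/n is too small once the mean
    # function spends several parameters on 30-odd points
    dof = max(fit.n_obs - models.N_MEAN_PARAMS[fit.family], 1)
    sigma = math.sqrt(max(fit.rss, 0.0) / dof)
    mu = fit(tr.t)
    t_last = float(tr.t.max())
    bmts, failures = [], 0
    for _ in range(n_boot):
        sigma_b = sigma * math.sqrt(dof / rng.chisquare(dof))
        yb = mu + rng.normal(0.0, sigma_b, size=mu.shape)
        try:
            fb = models.fit_family(fit.family, tr.t, yb, hint=fit.theta)
        except Exception:
            failures += 1
            continue
        if not fb.converged:
            failures += 1
            continue
        b = compute_bmt(fb, bmr, t_last)
        bmts.append(np.inf if b is None else b)
    if failures > 0.5 * n_boot or not bmts:
        return float("nan"), float("nan")
    lo = (1.0 - level) / 2.0
    arr = np.asarray(bmts)
    # 'lower'/'higher' avoid interpolating between finite and infinite BMTs
    return (float(np.quantile(arr, lo, method="lower")),
            float(np.quantile(arr, 1.0 - lo, method="higher")))


def apply_retention_filters(results: pd.DataFrame, t_min: float = T_MIN,
                            t_max: float = 24.0, ratio_max: float = RATIO_MAX,
                            fit_p_min: float = FIT_P_MIN) -> pd.DataFrame:
    """Set the retained flag: BMT inside [t_min, t_max], BMTU/BMTL strictly
    below ratio_max, and fit p value strictly above fit_p_min."""
    r = results.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = r["BMTU"] / r["BMTL"]
    r["ratio"] = ratio
    r["retained"] = (
        r["BMT"].between(t_min, t_max)
        & (ratio < ratio_max)
        & (r["fitPValue"] > fit_p_min)
    ).fillna(False)
    return r


def bmt_analysis(responses: dict[str, TimeResponse], eligible=None,
                 bmr_spec=DEFAULT_BMR_SPEC, n_boot: int = 250,
                 level: float = 0.90, seed: int = 0, t_min: float = T_MIN,
                 t_max: float | None = None, ratio_max: float = RATIO_MAX,
                 fit_p_min: float = FIT_P_MIN,
                 predict_5pl: bool = True) -> pd.DataFrame:
    """Full per-probe BMT table for the eligible probes.

    Fits all ten families, selects by AIC, inverts at the resolved BMR,
    bootstraps confidence bounds, applies the retention filters, and (by
    default) adds the weighted 5-PL predicted log2FC at the BMT for probes
    with a defined BMT.
    """
    probes = list(responses) if eligible is None else [p for p in responses if p in set(eligible)]
    root = np.random.default_rng(seed)
    streams = root.spawn(max(len(probes), 1))
    rows = []
    for probe, rng in zip(probes, streams):
        tr = responses[probe]
        t_last = float(tr.t.max())
        fits = models.fit_all(tr.t, tr.y)
        try:
            best = models.select_best(fits)
        except ValueError:
            continue
        bmr = resolve_bmr(bmr_spec, tr)
        bmt = compute_bmt(best, bmr, t_last)
        if bmt is None:
            bmtl = bmtu = float("nan")
            bmt_val = float("nan")
        else:
            bmt_val = float(bmt)
            bmtl, bmtu = bmt_confidence(best, tr, bmr, level=level,
                                        n_boot=n_boot, seed=rng)
        pred = float("nan")
        if predict_5pl and np.isfinite(bmt_val):
            try:
                pred = fit_5pl_predict(tr, bmt_val)
            except Exception:
                pred = float("nan")
        rows.append({
            "probe": probe, "gene": probe_to_gene(probe),
            "best_model": best.family,
            "params": json.dumps([round(float(v), 10) for v in best.theta]),
            "AIC": best.aic, "fitPValue": best.fit_p, "bmr": bmr,
            "BMT": bmt_val, "BMTL": bmtl, "BMTU": bmtu,
            "predicted_lfc_at_BMT": pred,
        })
    cols = ["probe", "gene", "best_model", "params", "AIC", "fitPValue",
            "bmr", "BMT", "BMTL", "BMTU", "predicted_lfc_at_BMT"]
    res = pd.DataFrame(rows, columns=cols).set_index("probe")
    if t_max is None:
        t_max = max((float(tr.t.max()) for tr in responses.values()), default=24.0)
    return apply_retention_filters(res, t_min=t_min, t_max=t_max,
                                   ratio_max=ratio_max, fit_p_min=fit_p_min)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def accumulation_curve(bmts) -> pd.DataFrame:
    """Cumulative count of genes whose BMT falls at or before each time.

    Returns a (time_h, cumulative_count) step table — the ECDF in count units,
    monotone non-decreasing and right-continuous.  Empty input gives an empty
    curve.
    """
    arr = np.sort(np.asarray(list(bmts), dtype=float))
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return pd.DataFrame(columns=["time_h", "cumulative_count"])
    times, counts = np.unique(arr, return_counts=True)
    return pd.DataFrame({"time_h": times, "cumulative_count": np.cumsum(counts)})


def earliest_response_genes(tables: dict[float, pd.DataFrame],
                            alpha: float = 0.01,
                            lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Genes ranked by the earliest time they meet the DEG cut-off.

    A gene is significant at a time point if any of its probes is (padj <
    alpha and |log2FC| > threshold); its reported fold change is the
    largest-magnitude significant probe at that first time.  Ties in first
    time are broken by |log2FC| descending.
    """
    first: dict[str, tuple[float, float]] = {}
    for t in sorted(tables):
        tab = tables[t]
        sig = tab[(tab["padj"] < alpha) & (tab["log2FoldChange"].abs() > lfc_threshold)]
        for gene, sub in sig.groupby("gene"):
            if gene in first:
                continue
            lfc = sub.loc[sub["log2FoldChange"].abs().idxmax(), "log2FoldChange"]
            first[gene] = (float(t), float(lfc))
    if not first:
        return pd.DataFrame(columns=["gene", "first_time_h", "log2FoldChange",
                                     "direction"])
    out = pd.DataFrame(
        [(g, t, l, "up" if l > 0 else "down") for g, (t, l) in first.items()],
        columns=["gene", "first_time_h", "log2FoldChange", "direction"])
    out["_a"] = out["log2FoldChange"].abs()
    out = (out.sort_values(["first_time_h", "_a"], ascending=[True, False])
              .drop(columns="_a").reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# five-parameter logistic prediction
# ---------------------------------------------------------------------------

@dataclass
class FivePLFit:
    """Weighted 5-PL fit y = B + (T - B) / (1 + 10**(b*(xmid - x)))**s on
    x = log10(t + offset); ``orient`` is -1 when the response was flipped so
    that the fitted top stays above the bottom."""

    params: np.ndarray  # (B, T, xmid, b, s) in oriented space
    orient: float
    offset: float
    weights: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True

    def __call__(self, t):
        x = np.log10(np.asarray(t, float) + self.offset)
        return self.orient * _5pl_curve(x, self.params)


def _5pl_curve(x, p):
    B, T, xm, b, s = p
    # the saturating tail may overflow to inf; the ratio then correctly -> 0
    with np.errstate(over="ignore"):
        return B + (T - B) / np.power(
            1.0 + np.power(10.0, np.clip(b * (xm - x), -30.0, 30.0)), s)


def fit_5pl(t, y, offset: float = 0.1, weights=None,
            fix_s: float | None = None) -> FivePLFit:
    """Fit a 5-PL (asymmetric sigmoid) to (t, y) on a log10 time axis.

    The response is oriented so the top asymptote is the larger one; pass
    ``fix_s=1`` for the symmetric 4-PL reduction.  Deterministic data-derived
    multi-starts; raises if no start converges.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if np.unique(t).size < 5:
        raise ValueError("need >= 5 distinct time levels for a 5-PL fit")
    x = np.log10(t + offset)
    early = y[t <= np.quantile(t, 0.2)].mean()
    late = y[t >= np.quantile(t, 0.8)].mean()
    orient = -1.0 if late < early else 1.0
    yo = orient * y
    w = np.ones_like(yo) if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)

    lo = np.array([-np.inf, -np.inf, x.min() - 2.0, 1e-3, 0.05])
    hi = np.array([np.inf, np.inf, x.max() + 2.0, 50.0, 20.0])
    if fix_s is not None:
        lo[4] = fix_s - 1e-9
        hi[4] = fix_s + 1e-9

    def resid(p):
        return sw * (_5pl_curve(x, p) - yo)

    b0, t0 = float(np.min(yo)), float(np.max(yo))
    if t0 - b0 < 1e-6:
        t0 = b0 + 1e-6
    starts = []
    for xm in (np.median(x), np.quantile(x, 0.35), np.quantile(x, 0.7)):
        for b in (0.5, 1.5, 4.0):
            starts.append([b0, t0, xm, b, 1.0 if fix_s is None else fix_s])
    best, best_cost = None, np.inf
    for x0 in starts:
        try:
            res = optimize.least_squares(resid, np.clip(x0, lo + 1e-12, hi - 1e-12),
                                         bounds=(lo, hi), max_nfev=500)
        except Exception:
            continue
        if res.cost < best_cost and np.all(np.isfinite(res.x)):
            best, best_cost = res.x, res.cost
    if best is None:
        raise RuntimeError("5-PL fit failed to converge")
    return FivePLFit(params=best, orient=orient, offset=offset, weights=w)


def fit_5pl_predict(tr: TimeResponse, bmt: float, offset: float = 0.1,
                    eps: float = 1e-4) -> float:
    """Weighted-5-PL predicted log2FC at the BMT.

    An unweighted fit supplies residual-based weights w_i = 1/max(eps, r_i^2)
    for a single weighted refit; if either fit fails, falls back to monotone
    interpolation of the per-time mean responses.
    """
    try:
        f0 = fit_5pl(tr.t, tr.y, offset=offset)
        r = f0(tr.t) - tr.y
        w = 1.0 / np.maximum(eps, r ** 2)
        f1 = fit_5pl(tr.t, tr.y, offset=offset, weights=w)
        return float(f1(bmt))
    except (RuntimeError, ValueError):
        means = tr.level_means(include_anchor=True)
        return float(np.interp(bmt, means.index.to_numpy(), means.to_numpy()))
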