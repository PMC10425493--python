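"""Parametric time-response families, least-squares fitting, and benchmark-point inversion.

The ten families are the classical continuous benchmark-dose models applied to the
time axis: Linear, Poly2-4, Power, Hill, and four exponential forms.  Responses are
log2 fold changes versus time-matched controls, so curves may take either sign and
the exponential plateau models (Exp4/Exp5) are parameterised in "baseline +
amplitude" form,

    Exp4:  f(t) = a + M * (1 - exp(-b t))
    Exp5:  f(t) = a + M * (1 - exp(-(b t)^d))

which is the classical a*(c - (c-1)*exp(-b t)) with M = a*(c-1); the benchmark
point depends only on f(t) - f(0) = M*(1 - exp(-b t)) and is identical in both
parameterisations, but this form stays well conditioned when the baseline is
near zero.

All fits are Gaussian least squares with deterministic, data-derived multi-starts;
no global random state is consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

FAMILIES: tuple[str, ...] = (
    "Linear", "Poly2", "Poly3", "Poly4",
    "Power", "Hill", "Exp2", "Exp3", "Exp4", "Exp5",
)

#: number of mean-function parameters per family
N_MEAN_PARAMS: dict[str, int] = {
    "Linear": 2, "Poly2": 3, "Poly3": 4, "Poly4": 5,
    "Power": 3, "Hill": 4, "Exp2": 2, "Exp3": 3, "Exp4": 3, "Exp5": 4,
}

#: upper bound on shape exponents (Power delta, Hill n, Exp3/Exp5 d); the
#: standard benchmark-dose constraint preventing step-function degeneracy.
SHAPE_MAX = 18.0

_RSS_FLOOR = 1e-30
_EXP_CLIP = 60.0  # cap on exponent arguments to avoid overflow during search


def curve(family: str, theta, t):
    """Evaluate the mean function of ``family`` with parameters ``theta`` at ``t``.

    ``t`` may be a scalar or array; times must be non-negative.
    """
    t = np.asarray(t, dtype=float)
    th = np.asarray(theta, dtype=float)
    if family == "Linear":
        return th[0] + th[1] * t
    if family in ("Poly2", "Poly3", "Poly4"):
        return np.polynomial.polynomial.polyval(t, th)
    if family == "Power":
        g, b, d = th
        return g + b * np.power(t, d)
    if family == "Hill":
        g, v, k, n = th
        tn = np.power(t, n)
        return g + v * tn / (k ** n + tn)
    if family == "Exp2":
        a, b = th
        return a * np.exp(np.clip(b * t, -_EXP_CLIP, _EXP_CLIP))
    if family == "Exp3":
        a, b, d = th
        z = np.sign(b) * np.power(np.abs(b) * t, d)
        return a * np.exp(np.clip(z, -_EXP_CLIP, _EXP_CLIP))
    if family == "Exp4":
        a, m, b = th
        return a + m * (1.0 - np.exp(-np.clip(b * t, 0, _EXP_CLIP)))
    if family == "Exp5":
        a, m, b, d = th
        return a + m * (1.0 - np.exp(-np.clip(np.power(b * t, d), 0, _EXP_CLIP)))
    raise ValueError(f"unknown model family: {family!r}")


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximised Gaussian log-likelihood at the MLE variance rss/n."""
    rss = max(float(rss), _RSS_FLOOR)
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


@dataclass
class ModelFit:
    """A fitted time-response curve for one family.

    AIC uses the Gaussian likelihood at the MLE variance with the mean-parameter
    count plus one (the common variance), so constants cancel identically across
    families: for equal parameter counts, AIC1 - AIC2 = n * ln(RSS1/RSS2).
    fit_p is the likelihood-ratio goodness-of-fit p value against the saturated
    per-time-level-means model (chi-square, df = #levels - #mean params).
    """

    family: str
    theta: np.ndarray
    rss: float
    n_obs: int
    n_levels: int
    rss_saturated: float
    converged: bool = True

    @property
    def n_params(self) -> int:
        return N_MEAN_PARAMS[self.family] + 1  # + common variance

    @property
    def loglik(self) -> float:
        return gaussian_loglik(self.rss, self.n_obs)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def fit_p(self) -> float:
        df = self.n_levels - N_MEAN_PARAMS[self.family]
        if df <= 0:
            return 1.0
        lr = self.n_obs * math.log(
            max(self.rss, _RSS_FLOOR) / max(self.rss_saturated, _RSS_FLOOR)
        )
        return float(stats.chi2.sf(max(lr, 0.0), df))

    def __call__(self, t):
        return curve(self.family, self.theta, t)


def saturated_rss(t: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of the per-time-level means model."""
    rss = 0.0
    for lv in np.unique(t):
        yy = y[t == lv]
        rss += float(np.sum((yy - yy.mean()) ** 2))
    return rss


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _lin_solve(X: np.ndarray, y: np.ndarray):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return coef, float(r @ r)


def _fit_poly(t, y, deg):
    X = np.vander(t, deg + 1, increasing=True)
    coef, rss = _lin_solve(X, y)
    return coef, rss, True


def _fit_power(t, y, hint=None):
    # profile: for fixed delta the model is linear in (gamma, beta)
    def prss(d):
        X = np.column_stack([np.ones_like(t), np.power(t, d)])
        return _lin_solve(X, y)[1]

    if hint is not None:
        grid = np.array([float(np.clip(hint[2], 1.0, SHAPE_MAX))])
    else:
        grid = np.arange(1.0, SHAPE_MAX + 1e-9, 0.5)
    best = grid[int(np.argmin([prss(d) for d in grid]))]
    res = optimize.minimize_scalar(
        prss, bounds=(max(1.0, best - 0.5), min(SHAPE_MAX, best + 0.5)),
        method="bounded", options={"xatol": 1e-10},
    )
    d = float(res.x) if res.fun <= prss(best) else float(best)
    X = np.column_stack([np.ones_like(t), np.power(t, d)])
    coef, rss = _lin_solve(X, y)
    return np.array([coef[0], coef[1], d]), rss, True


def _fit_hill(t, y, hint=None):
    tpos = t[t > 0]

    def prss(k, n):
        tn = np.power(t, n)
        X = np.column_stack([np.ones_like(t), tn / (k ** n + tn)])
        return _lin_solve(X, y)

    if hint is not None:
        pairs = [(float(np.clip(hint[2], 1e-6, 1e6)),
                  float(np.clip(hint[3], 1e-3, SHAPE_MAX)))]
    else:
        kgrid = np.unique(np.concatenate([
            np.quantile(tpos, [0.15, 0.35, 0.5, 0.7, 0.9]),
            [0.5 * tpos.min(), 2.0 * tpos.max()],
        ]))
        ngrid = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 13.0, SHAPE_MAX])
        pairs = [(k, n) for k in kgrid for n in ngrid]

    best_kn, best_rss = None, np.inf
    for k, n in pairs:
        _, rss = prss(k, n)
        if rss < best_rss:
            best_rss, best_kn = rss, (k, n)

    def obj(psi):
        k = math.exp(psi[0])
        n = math.exp(psi[1])
        if not (1e-3 <= n <= SHAPE_MAX) or not (1e-6 <= k <= 1e6):
            return 1e30
        return prss(k, n)[1]

    res = optimize.minimize(
        obj, [math.log(best_kn[0]), math.log(best_kn[1])],
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-14,
                 "maxiter": 120 if hint is not None else 400},
    )
    if np.isfinite(res.fun) and res.fun <= best_rss:
        k, n = math.exp(res.x[0]), math.exp(res.x[1])
    else:
        k, n = best_kn
    n = min(max(n, 1e-3), SHAPE_MAX)
    coef, rss = prss(k, n)
    return np.array([coef[0], coef[1], k, n]), rss, True


def _time_scale(t):
    tpos = t[t > 0]
    return float(tpos.max()) if tpos.size else 1.0


def _bgrid(T, n=10):
    return np.geomspace(0.03 / T, 30.0 / T, n)


def _fit_exp2(t, y, hint=None):
    # a * exp(b t): linear in a for fixed b -> 1-D profile over signed b
    T = _time_scale(t)

    def prss(b):
        g = curve("Exp2", [1.0, b], t)
        denom = float(g @ g)
        a = float(g @ y) / denom if denom > 0 else 0.0
        r = y - a * g
        return float(r @ r), a

    cands = np.concatenate([_bgrid(T), -_bgrid(T), [0.0]])
    if hint is not None:
        cands = np.concatenate([[hint[1]], cands])
    rss_b = [prss(b)[0] for b in cands]
    b0 = float(cands[int(np.argmin(rss_b))])
    span = 50.0 / T
    lo, hi = (b0 / 4, b0 * 4) if b0 > 0 else ((b0 * 4, b0 / 4) if b0 < 0 else (-span, span))
    res = optimize.minimize_scalar(lambda b: prss(b)[0], bounds=(lo, hi),
                                   method="bounded", options={"xatol": 1e-10})
    b = float(res.x) if res.fun <= min(rss_b) else b0
    rss, a = prss(b)
    return np.array([a, b]), rss, True


def _nm_refine(obj, x0, maxiter=150):
    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-13,
                                     "maxiter": maxiter})
    return res.x, res.fun


def _fit_exp3(t, y, hint=None):
    # a * exp(sign(b) (|b| t)^d): linear in a for fixed (b, d)
    T = _time_scale(t)

    def prss(b, d):
        g = curve("Exp3", [1.0, b, d], t)
        denom = float(g @ g)
        a = float(g @ y) / denom if denom > 0 else 0.0
        r = y - a * g
        return float(r @ r), a

    cands = [(b, d) for b in np.concatenate([_bgrid(T, 7), -_bgrid(T, 7)])
             for d in (1.0, 2.0, 4.0, 9.0, SHAPE_MAX)]
    if hint is not None:
        cands.insert(0, (float(hint[1]), float(np.clip(hint[2], 1.0, SHAPE_MAX))))
    rss_c = [prss(b, d)[0] for b, d in cands]
    b0, d0 = cands[int(np.argmin(rss_c))]
    sign = 1.0 if b0 >= 0 else -1.0

    def obj(psi):
        d = psi[1]
        if not (1.0 <= d <= SHAPE_MAX):
            return 1e30
        return prss(sign * math.exp(psi[0]), d)[0]

    psi, fun = _nm_refine(obj, [math.log(max(abs(b0), 1e-12)), d0],
                          maxiter=60 if hint is not None else 150)
    if fun <= min(rss_c) and 1.0 <= psi[1] <= SHAPE_MAX:
        b, d = sign * math.exp(psi[0]), float(psi[1])
    else:
        b, d = b0, d0
    rss, a = prss(b, d)
    return np.array([a, b, d]), rss, True


def _fit_exp4(t, y, hint=None):
    # a + M (1 - exp(-b t)): linear in (a, M) for fixed b -> 1-D profile
    T = _time_scale(t)

    def prss(b):
        u = curve("Exp4", [0.0, 1.0, b], t)
        X = np.column_stack([np.ones_like(t), u])
        coef, rss = _lin_solve(X, y)
        return rss, coef

    cands = _bgrid(T, 14)
    if hint is not None:
        cands = np.concatenate([[abs(hint[2])], cands])
    rss_b = [prss(b)[0] for b in cands]
    b0 = float(cands[int(np.argmin(rss_b))])
    res = optimize.minimize_scalar(lambda b: prss(b)[0], bounds=(b0 / 5, b0 * 5),
                                   method="bounded", options={"xatol": 1e-10})
    b = float(res.x) if res.fun <= min(rss_b) else b0
    rss, coef = prss(b)
    return np.array([coef[0], coef[1], b]), rss, True


def _fit_exp5(t, y, hint=None):
    # a + M (1 - exp(-(b t)^d)): linear in (a, M) for fixed (b, d)
    T = _time_scale(t)

    def prss(b, d):
        u = curve("Exp5", [0.0, 1.0, b, d], t)
        X = np.column_stack([np.ones_like(t), u])
        coef, rss = _lin_solve(X, y)
        return rss, coef

    cands = [(b, d) for b in _bgrid(T, 8)
             for d in (1.0, 2.0, 4.0, 9.0, SHAPE_MAX)]
    if hint is not None:
        cands.insert(0, (abs(float(hint[2])), float(np.clip(hint[3], 1.0, SHAPE_MAX))))
    rss_c = [prss(b, d)[0] for b, d in cands]
    b0, d0 = cands[int(np.argmin(rss_c))]

    def obj(psi):
        d = psi[1]
        if not (1.0 <= d <= SHAPE_MAX):
            return 1e30
        return prss(math.exp(psi[0]), d)[0]

    psi, fun = _nm_refine(obj, [math.log(max(b0, 1e-12)), d0],
                          maxiter=60 if hint is not None else 150)
    if fun <= min(rss_c) and 1.0 <= psi[1] <= SHAPE_MAX:
        b, d = math.exp(psi[0]), float(psi[1])
    else:
        b, d = b0, d0
    rss, coef = prss(b, d)
    return np.array([coef[0], coef[1], b, d]), rss, True


def fit_family(family: str, t, y, hint=None) -> ModelFit:
    """Least-squares fit of one family to (t, y) observations.

    hint, if given, seeds the multi-start list with a known-good parameter
    vector (used by the bootstrap to refit perturbed data quickly).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be matching 1-D arrays")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    levels = np.unique(t)
    sat = saturated_rss(t, y)

    if family == "Linear":
        theta, rss, ok = _fit_poly(t, y, 1)
    elif family in ("Poly2", "Poly3", "Poly4"):
        theta, rss, ok = _fit_poly(t, y, int(family[-1]))
    elif family == "Power":
        theta, rss, ok = _fit_power(t, y, hint)
    elif family == "Hill":
        theta, rss, ok = _fit_hill(t, y, hint)
    elif family == "Exp2":
        theta, rss, ok = _fit_exp2(t, y, hint)
    elif family == "Exp3":
        theta, rss, ok = _fit_exp3(t, y, hint)
    elif family == "Exp4":
        theta, rss, ok = _fit_exp4(t, y, hint)
    elif family == "Exp5":
        theta, rss, ok = _fit_exp5(t, y, hint)
    else:
        raise ValueError(f"unknown model family: {family!r}")

    return ModelFit(
        family=family, theta=np.asarray(theta, float), rss=float(rss),
        n_obs=t.size, n_levels=levels.size, rss_saturated=sat, converged=bool(ok),
    )


def fit_all(t, y, families=FAMILIES) -> dict[str, ModelFit]:
    return {fam: fit_family(fam, t, y) for fam in families}


def select_best(fits, tie_tol: float = 1e-6) -> ModelFit:
    """Lowest-AIC converged fit; AIC ties go to fewer parameters, then family order.

    Accepts a dict or list of ModelFit; raises if no fit converged.
    """
    pool = list(fits.values()) if isinstance(fits, dict) else list(fits)
    pool = [f for f in pool if f.converged and np.isfinite(f.rss)]
    if not pool:
        raise ValueError("no converged fits to select from")
    best_aic = min(f.aic for f in pool)
    tied = [f for f in pool if f.aic <= best_aic + tie_tol]
    tied.sort(key=lambda f: (f.n_params, FAMILIES.index(f.family)))
    return tied[0]


# ---------------------------------------------------------------------------
# benchmark-point inversion
# ---------------------------------------------------------------------------

def bmt_closed_form(family: str, theta, bmr: float):
    """Closed-form benchmark time for Linear, Power, and Hill; None elsewhere.

    The benchmark time is the smallest t > 0 with |f(t) - f(0)| = bmr.
    Returns None when the change never reaches bmr, and NotImplemented-like
    None is never used: families without a closed form raise ValueError.
    """
    if bmr <= 0:
        raise ValueError("bmr must be positive")
    th = np.asarray(theta, float)
    if family == "Linear":
        b1 = th[1]
        return None if b1 == 0 else bmr / abs(b1)
    if family == "Power":
        _, b, d = th
        return None if b == 0 else (bmr / abs(b)) ** (1.0 / d)
    if family == "Hill":
        _, v, k, n = th
        if abs(v) <= bmr:
            return None
        return k * (bmr / (abs(v) - bmr)) ** (1.0 / n)
    raise ValueError(f"no closed form for family {family!r}")


def bmt_numeric(family: str, theta, bmr: float, t_max: float,
                n_grid: int = 2000) -> float | None:
    """First crossing of |f(t) - f(0)| = bmr on (0, t_max] by grid scan + brentq."""
    if bmr <= 0:
        raise ValueError("bmr must be positive")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    f0 = float(curve(family, theta, 0.0))

    def g(t):
        return np.abs(curve(family, theta, t) - f0) - bmr

    grid = np.concatenate([
        np.geomspace(t_max * 1e-8, t_max * 1e-2, n_grid // 4),
        np.linspace(t_max * 1e-2, t_max, n_grid - n_grid // 4),
    ])
    vals = g(grid)
    idx = np.nonzero(vals >= 0)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    lo = 0.0 if i == 0 else grid[i - 1]
    hi = grid[i]
    if vals[i] == 0.0:
        return float(hi)
    if lo == 0.0:
        lo = t_max * 1e-12
        if g(lo) >= 0:
            return float(lo)
    return float(optimize.brentq(g, lo, hi, xtol=1e-14, rtol=1e-13))


def benchmark_time(family: str, theta, bmr: float, t_max: float = 100.0,
                   prefer_closed: bool = True) -> float | None:
    """Benchmark time for any family: closed form where available, else numeric.

    Searches (0, t_max]; callers wanting the conventional "10x last observed
    time" horizon pass that value.  Returns None when the response never
    departs from baseline by bmr within the horizon.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family: {family!r}")
    if prefer_closed and family in ("Linear", "Power", "Hill"):
        t = bmt_closed_form(family, theta, bmr)
        if t is not None and t > t_max:
            return None
        return t
    return bmt_numeric(family, theta, bmr, t_max)
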