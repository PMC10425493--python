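"""Normalisation and per-time-point differential expression.

Counts are normalised with the median-of-ratios method; per-time-point
treated-vs-control tests use a negative-binomial Wald test at fixed per-probe
dispersion, with p values adjusted by Benjamini-Hochberg.  A probe is called
significant at the study's thresholds: adjusted p < 0.01 and |log2FC| > 1
(fold change > |2|).

The dispersion estimator here is deliberately simple — a method-of-moments
estimate pooled across replicate groups, shrunk toward a fitted
mean-dispersion trend — not a re-implementation of the full empirical-Bayes
machinery of dedicated DEG packages.  It is estimated once per compound across
all time points and reused in each small per-time-point test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import probe_to_gene, select_samples

logger = logging.getLogger(__name__)

DEG_ALPHA = 0.01
DEG_LFC = 1.0
_LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over reference probes of y_gj / geometric-mean_g(y), where the
    reference set is the probes with strictly positive counts in every sample.
    """
    arr = counts.to_numpy(dtype=float)
    ref = np.all(arr > 0, axis=1)
    if not ref.any():
        raise ValueError("no probe has positive counts in all samples")
    logs = np.log(arr[ref])
    gm = logs.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logs - gm, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    return counts / sf.reindex(counts.columns).to_numpy()


def estimate_dispersions(counts: pd.DataFrame, sf: pd.Series,
                         grouping, shrink_weight: float = 0.3,
                         max_dispersion: float = 20.0) -> pd.Series:
    """Per-probe NB dispersion by moments, shrunk toward a mean-dispersion trend.

    grouping: per-sample labels of replicate groups (same compound, time, and
    arm).  Within each group with >= 2 replicates, the normalised-count
    variance in excess of the Poisson expectation yields a raw alpha; raw
    values are floored at zero and averaged (1 - w) with a fitted trend
    alpha(mu) = a1 + a0/mu (weight w = ``shrink_weight``).
    """
    grouping = np.asarray(grouping)
    z = normalized_counts(counts, sf).to_numpy()
    inv_s = 1.0 / sf.reindex(counts.columns).to_numpy()

    ss = np.zeros(z.shape[0])
    df = 0
    mean_inv_s = []
    cols_used = np.zeros(z.shape[1], bool)
    for g in np.unique(grouping):
        idx = grouping == g
        ng = int(idx.sum())
        if ng < 2:
            continue
        zg = z[:, idx]
        ss += np.sum((zg - zg.mean(axis=1, keepdims=True)) ** 2, axis=1)
        df += ng - 1
        cols_used |= idx
        mean_inv_s.append(inv_s[idx].mean() * (ng - 1))
    if df == 0:
        raise ValueError("dispersion estimation needs a group with >= 2 replicates")
    var = ss / df
    c = float(np.sum(mean_inv_s) / df)  # df-weighted mean of 1/s over used groups
    mu = z[:, cols_used].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu * c) / mu ** 2
    raw = np.where(mu > 0, np.clip(raw, 0.0, max_dispersion), 0.0)

    # parametric trend alpha(mu) = a1 + a0/mu fitted by least squares on
    # positive-mean probes, coefficients clipped to be non-negative
    pos = mu > 0
    if pos.sum() >= 2:
        X = np.column_stack([np.ones(pos.sum()), 1.0 / mu[pos]])
        coef, *_ = np.linalg.lstsq(X, raw[pos], rcond=None)
        a1, a0 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        a1, a0 = float(np.median(raw)), 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a1 + a0 / np.maximum(mu, 1e-12), a1)
    alpha = (1.0 - shrink_weight) * raw + shrink_weight * np.clip(trend, 0, max_dispersion)
    out = pd.Series(np.clip(alpha, 0.0, max_dispersion), index=counts.index,
                    name="dispersion")
    out.attrs["method"] = f"moments+trend(w={shrink_weight})"
    return out


def _fit_group(Y: np.ndarray, s: np.ndarray, alpha: np.ndarray,
               n_iter: int = 60, tol: float = 1e-12):
    """Vectorised per-probe NB MLE of a single group mean on the log scale.

    Model: y_j ~ NB(mean = s_j * q, dispersion alpha); solves the score
    equation for eta = ln q by Newton iterations (the log-likelihood is
    concave in eta at fixed alpha).  Returns (eta, fisher_info) arrays; probes
    with all-zero counts get q floored at half a pooled count so that the Wald
    machinery stays defined (callers flag them).
    """
    tot = Y.sum(axis=1)
    S = s.sum()
    q0 = np.maximum(tot / S, 0.5 / S)
    eta = np.log(q0)
    for _ in range(n_iter):
        mu = np.exp(eta)[:, None] * s[None, :]
        w = 1.0 + alpha[:, None] * mu
        score = np.sum((Y - mu) / w, axis=1)
        info = np.sum(mu / w, axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.maximum(eta, np.log(0.5 / S))
    mu = np.exp(eta)[:, None] * s[None, :]
    info = np.sum(mu / (1.0 + alpha[:, None] * mu), axis=1)
    return eta, info


def nb_wald_test(counts: pd.DataFrame, samples_treated, samples_control,
                 sf: pd.Series, dispersions: pd.Series,
                 alpha: float = DEG_ALPHA, lfc_threshold: float = DEG_LFC) -> pd.DataFrame:
    """Negative-binomial Wald test, treated vs control, at fixed dispersions.

    Per probe the group means are fitted by maximum likelihood with per-sample
    size-factor offsets; the log2 fold change is the difference of fitted log
    means, its standard error comes from the observed (= expected, log link)
    information, and the Wald p is two-sided normal.  Probes with zero counts
    in both groups are flagged untestable (p = 1, lfc = 0).
    """
    treated = list(samples_treated)
    control = list(samples_control)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need at least 2 samples per group")
    Yt = counts[treated].to_numpy(float)
    Yc = counts[control].to_numpy(float)
    st = sf.reindex(treated).to_numpy()
    sc = sf.reindex(control).to_numpy()
    a = dispersions.reindex(counts.index).to_numpy()
    if np.any(~np.isfinite(a)):
        raise ValueError("dispersions missing for some probes")

    eta_t, info_t = _fit_group(Yt, st, a)
    eta_c, info_c = _fit_group(Yc, sc, a)
    beta = eta_t - eta_c
    se = np.sqrt(1.0 / np.maximum(info_t, 1e-12) + 1.0 / np.maximum(info_c, 1e-12))
    z = beta / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    untestable = (Yt.sum(axis=1) == 0) & (Yc.sum(axis=1) == 0)
    beta[untestable] = 0.0
    pvalue[untestable] = 1.0

    base_mean = np.concatenate(
        [Yt / st[None, :], Yc / sc[None, :]], axis=1).mean(axis=1)
    res = pd.DataFrame({
        "probe": counts.index,
        "gene": [probe_to_gene(p) for p in counts.index],
        "baseMean": base_mean,
        "log2FoldChange": beta / _LN2,
        "lfcSE": se / _LN2,
        "pvalue": pvalue,
    }).set_index("probe")
    res["padj"] = adjust_bh(res["pvalue"].to_numpy())
    res["significant"] = (res["padj"] < alpha) & (res["log2FoldChange"].abs() > lfc_threshold)
    return res


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def peak_time(sig_counts: pd.Series) -> float:
    """Earliest time attaining the maximum significant-DEG count.

    Ties break toward the earlier time (interest lies in proximal events).
    """
    s = sig_counts.sort_index()
    return float(s.index[int(np.argmax(s.to_numpy()))])


def deg_time_series(counts: pd.DataFrame, metadata: pd.DataFrame, compound: str,
                    sf: pd.Series | None = None,
                    dispersions: pd.Series | None = None,
                    alpha: float = DEG_ALPHA, lfc_threshold: float = DEG_LFC):
    """Per-time-point DEG tables for one compound plus significant counts.

    Returns (tables, sig_counts, peak_time): tables maps time (h) to a DEG
    DataFrame, sig_counts is a Series of significant-probe counts per time,
    and peak_time is the time with the most significant probes (ties broken
    toward the earlier time).
    """
    treated_md, control_md = select_samples(metadata, compound)
    cols = list(treated_md["sample_id"]) + list(control_md["sample_id"])
    sub = counts[cols]
    if sf is None:
        sf = size_factors(sub)
    if dispersions is None:
        groups = [f"{c}:{t}" for c, t in zip(
            pd.concat([treated_md, control_md])["compound"],
            pd.concat([treated_md, control_md])["time_h"])]
        dispersions = estimate_dispersions(sub, sf, groups)

    times = sorted(treated_md["time_h"].unique())
    tables: dict[float, pd.DataFrame] = {}
    sig = {}
    for t in times:
        tr = treated_md.loc[treated_md["time_h"] == t, "sample_id"].tolist()
        ct = control_md.loc[control_md["time_h"] == t, "sample_id"].tolist()
        res = nb_wald_test(sub, tr, ct, sf, dispersions, alpha, lfc_threshold)
        tables[t] = res
        sig[t] = int(res["significant"].sum())
    sig_counts = pd.Series(sig).sort_index()
    return tables, sig_counts, peak_time(sig_counts)


def anova_dunnett(groups: dict[str, np.ndarray], control_label: str,
                  seed: int | None = 0):
    """One-way ANOVA plus Dunnett many-to-one adjusted p values.

    groups maps labels to replicate measurement arrays; the control group is
    compared against every other.  Returns (anova_p, {label: adjusted_p}).
    The Dunnett adjustment uses the equicorrelated multivariate-t distribution
    (numerically evaluated); degenerate all-zero-variance input returns p = 1
    when all means are equal and p = 0 otherwise.
    """
    if control_label not in groups:
        raise ValueError(f"control label {control_label!r} not in groups")
    labels = [k for k in groups if k != control_label]
    if not labels:
        raise ValueError("need at least one non-control group")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("need >= 2 replicates per group")
    ctrl = arrays[control_label]

    allvar = sum(float(np.var(a)) for a in arrays.values())
    if allvar == 0.0:
        means = {k: a.mean() for k, a in arrays.items()}
        same = all(np.isclose(means[k], means[control_label]) for k in labels)
        p = 1.0 if same else 0.0
        logger.warning("anova_dunnett: zero within-group variance (degenerate)")
        return p, {k: p for k in labels}

    anova_p = float(stats.f_oneway(*[arrays[k] for k in groups]).pvalue)
    res = stats.dunnett(*[arrays[k] for k in labels], control=ctrl,
                        rng=np.random.default_rng(seed))
    return anova_p, dict(zip(labels, np.clip(res.pvalue, 0.0, 1.0)))


def normalize_reporter(trace) -> np.ndarray:
    """Baseline-subtract a reporter fluorescence trace: out[i] = in[i] - in[0]."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    return trace - trace[0]


def pca_coordinates(counts: pd.DataFrame, sf: pd.Series | None = None,
                    n_components: int = 2) -> pd.DataFrame:
    """Sample PCA coordinates on centred log2 normalised counts (QC export)."""
    if sf is None:
        sf = size_factors(counts)
    x = np.log2(normalized_counts(counts, sf).to_numpy() + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    _, sv, vt = np.linalg.svd(x, full_matrices=False)
    coords = vt[:n_components].T * sv[:n_components]
    return pd.DataFrame(coords, index=counts.columns,
                        columns=[f"PC{i + 1}" for i in range(n_components)])
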