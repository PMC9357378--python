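"""Robust outlier removal and group-comparison statistics.

This layer provides the post-processing applied to every measurement table
in the pipeline: ROUT outlier flagging at a target false discovery rate,
ordinary one-/two-way ANOVA, Dunnett's many-to-one post-hoc against a
control group, Fisher's LSD unadjusted pairwise comparisons, and
Benjamini–Hochberg FDR control.

ROUT here is the constant-model case: a robust location is fitted by
iteratively reweighted least squares (Tukey biweight, median start), the
residual scale is the RSDR (68.27th percentile of absolute residuals with a
small-sample correction), and residual t-ratios are tested largest-first
under a step-up FDR schedule at level Q. The schedule is validated by its
empirical false-discovery behaviour, which is the property the Q level
promises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InsufficientDataError, InvalidParameterError

_TUKEY_C = 4.685  # 95% Gaussian efficiency for the biweight


@dataclass
class ROUTResult:
    """Outcome of ROUT outlier flagging on a 1D sample."""

    values: np.ndarray
    robust_center: float
    rsdr: float
    q: float
    outlier_flags: np.ndarray
    message: str | None = None

    @property
    def cleaned(self) -> np.ndarray:
        return self.values[~self.outlier_flags]

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_flags.sum())


@dataclass
class Comparison:
    """One treatment-vs-control (or pairwise) contrast."""

    group: str
    other: str
    estimate: float
    t: float
    p_unadjusted: float
    p_adjusted: float | None = None
    mc_standard_error: float | None = None


@dataclass
class GroupComparisonResult:
    """Omnibus ANOVA plus optional post-hoc contrasts."""

    group_names: list[str]
    group_n: list[int]
    group_means: list[float]
    group_sds: list[float]
    f_statistic: float
    p_anova: float
    df_between: int
    df_within: int
    ms_within: float
    method: str
    comparisons: list[Comparison] = field(default_factory=list)


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise InsufficientDataError("at least two groups are required")
    out: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float).ravel()
        if arr.size < 2:
            raise InsufficientDataError(f"group {name!r} has n={arr.size} < 2")
        out[str(name)] = arr
    return out


def robust_location(values: np.ndarray, max_iter: int = 100, tol: float = 1e-10) -> float:
    """Tukey-biweight location, initialized at the median.

    The scale used inside the reweighting is the normalized MAD, refreshed
    each iteration; an all-equal sample returns the common value.
    """
    x = np.asarray(values, dtype=float)
    mu = float(np.median(x))
    for _ in range(max_iter):
        resid = x - mu
        mad = np.median(np.abs(resid)) / 0.67448975
        if mad == 0:
            return mu
        u = resid / (_TUKEY_C * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return mu
        new_mu = float(np.sum(w * x) / np.sum(w))
        if abs(new_mu - mu) < tol * max(1.0, abs(mu)):
            return new_mu
        mu = new_mu
    return mu


def rsdr(residuals: np.ndarray) -> float:
    """Robust standard deviation of residuals.

    The 68.27th percentile of the absolute residuals (the Gaussian 1σ
    quantile) with the √(n/(n−1)) small-sample correction.
    """
    r = np.abs(np.asarray(residuals, dtype=float))
    n = r.size
    return float(np.percentile(r, 68.27) * np.sqrt(n / (n - 1)))


def rout_clean(values: Sequence[float], q: float = 0.01) -> ROUTResult:
    """Flag gross outliers in a 1D sample at target FDR ``q``.

    Residual t-ratios (|residual| / RSDR) are converted to two-sided
    p-values on n−1 df and tested from the most extreme inwards against the
    step-up schedule α_i = q·(n−i+1)/n, stopping at the first failure.
    ``q = 0`` disables flagging entirely.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if q == 0:
        return ROUTResult(x, float(np.median(x)), 0.0, 0.0, np.zeros(n, dtype=bool), "q=0: flagging disabled")
    if n < 3:
        raise InsufficientDataError(f"ROUT requires n >= 3, got n={n}")
    if not (0 < q < 0.5):
        raise InvalidParameterError("q must lie in (0, 0.5)")

    center = robust_location(x)
    resid = x - center
    scale = rsdr(resid)
    flags = np.zeros(n, dtype=bool)
    if scale == 0:
        return ROUTResult(x, center, 0.0, q, flags, "zero spread: no outliers flagged")

    t_ratio = np.abs(resid) / scale
    pvals = 2.0 * stats.t.sf(t_ratio, df=n - 1)
    order = np.argsort(pvals)  # most extreme (smallest p) first
    for i, idx in enumerate(order, start=1):
        alpha_i = q * (n - i + 1) / n
        if pvals[idx] < alpha_i:
            flags[idx] = True
        else:
            break
    return ROUTResult(x, center, scale, q, flags)


def oneway_anova(
    groups: Mapping[str, Sequence[float]], method: str = "oneway-anova"
) -> GroupComparisonResult:
    """Ordinary one-way ANOVA: F = MS_between / MS_within."""
    g = _check_groups(groups)
    names = list(g)
    ns = np.array([g[k].size for k in names])
    means = np.array([g[k].mean() for k in names])
    sds = np.array([g[k].std(ddof=1) for k in names])
    n_total = int(ns.sum())
    grand = float(np.concatenate([g[k] for k in names]).mean())

    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g[k] - g[k].mean()) ** 2) for k in names))
    df_between = len(names) - 1
    df_within = n_total - len(names)
    if df_within < 1:
        raise InsufficientDataError("error degrees of freedom must be >= 1")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = np.inf if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
    else:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df_between, df_within))
    return GroupComparisonResult(
        group_names=names,
        group_n=[int(v) for v in ns],
        group_means=[float(v) for v in means],
        group_sds=[float(v) for v in sds],
        f_statistic=float(f),
        p_anova=p,
        df_between=df_between,
        df_within=df_within,
        ms_within=float(ms_within),
        method=method,
    )


def _max_abs_t_draws(
    ns_treat: np.ndarray, n_control: int, df: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo sample of max_i |T_i| under the Dunnett null.

    Drawn exactly from the joint distribution: independent group-mean
    normals (variance 1/n) sharing the control mean, divided by a common
    chi²_df/df scale — this reproduces the Dunnett correlation structure
    for balanced and unbalanced designs alike.
    """
    k = ns_treat.size
    z_t = rng.standard_normal((n_draws, k)) / np.sqrt(ns_treat)
    z_c = rng.standard_normal(n_draws) / np.sqrt(n_control)
    s = rng.chisquare(df, size=n_draws) / df
    t = (z_t - z_c[:, None]) / np.sqrt(s[:, None] * (1.0 / ns_treat + 1.0 / n_control))
    return np.max(np.abs(t), axis=1)


def dunnett_posthoc(
    groups: Mapping[str, Sequence[float]],
    control: str,
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int | None = 0,
) -> GroupComparisonResult:
    """Dunnett's many-to-one comparison of every treatment against control.

    Statistics t_i = (x̄_i − x̄_c)/√(MS_within (1/n_i + 1/n_c)) are adjusted
    by the distribution of max_i |T_i| under the multivariate-t null with
    the Dunnett correlation structure, evaluated by seeded Monte-Carlo
    integration; the MC standard error of each adjusted p is reported.
    """
    g = _check_groups(groups)
    if control not in g:
        raise ConfigurationError(f"control group {control!r} not present")
    res = oneway_anova(g, method="oneway-anova+dunnett")
    treat_names = [k for k in g if k != control]
    ns_treat = np.array([g[k].size for k in treat_names], dtype=float)
    n_c = g[control].size
    df = res.df_within
    rng = np.random.default_rng(seed)
    max_t = _max_abs_t_draws(ns_treat, n_c, df, n_draws, rng)

    comparisons = []
    for name, n_i in zip(treat_names, ns_treat):
        est = float(g[name].mean() - g[control].mean())
        se = np.sqrt(res.ms_within * (1.0 / n_i + 1.0 / n_c))
        t_i = est / se if se > 0 else (np.inf if est != 0 else 0.0)
        p_unadj = float(2.0 * stats.t.sf(abs(t_i), df))
        p_adj = float(np.mean(max_t >= abs(t_i)))
        mc_se = float(np.sqrt(p_adj * (1 - p_adj) / n_draws))
        comparisons.append(
            Comparison(name, control, est, float(t_i), p_unadj, max(p_adj, 0.0), mc_se)
        )
    res.comparisons = comparisons
    res.method = "oneway-anova+dunnett"
    return res


def fishers_lsd(
    groups: Mapping[str, Sequence[float]], control: str | None = None
) -> GroupComparisonResult:
    """Fisher's least-significant-difference pairwise t tests.

    Pooled MS_within and its df from the omnibus ANOVA; p-values are
    deliberately unadjusted. With ``control`` given only the
    treatment-vs-control contrasts are produced.
    """
    g = _check_groups(groups)
    if control is not None and control not in g:
        raise ConfigurationError(f"control group {control!r} not present")
    res = oneway_anova(g, method="oneway-anova+lsd")
    names = list(g)
    pairs = (
        [(t, control) for t in names if t != control]
        if control is not None
        else [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    )
    for a, b in pairs:
        est = float(g[a].mean() - g[b].mean())
        se = np.sqrt(res.ms_within * (1.0 / g[a].size + 1.0 / g[b].size))
        t = est / se if se > 0 else (np.inf if est != 0 else 0.0)
        p = float(2.0 * stats.t.sf(abs(t), res.df_within))
        res.comparisons.append(Comparison(a, b, est, float(t), p))
    return res


def twoway_anova(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
) -> dict[str, dict[str, float]]:
    """Crossed fixed-effects two-way ANOVA without interaction.

    A minimal additive decomposition for balanced or mildly unbalanced
    designs (fit via OLS on effect-coded factors).
    """
    import statsmodels.api as sm
    import pandas as pd

    df = pd.DataFrame({"y": np.asarray(values, float), "a": list(factor_a), "b": list(factor_b)})
    from statsmodels.formula.api import ols

    model = ols("y ~ C(a) + C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {}
    for name, row in table.iterrows():
        if name == "Residual":
            continue
        factor = "a" if name == "C(a)" else "b"
        out[factor] = {"F": float(row["F"]), "p": float(row["PR(>F)"]), "df": float(row["df"])}
    return out


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR.

    Returns ``(flags, q_values)`` where ``flags = q_values <= q`` and the
    adjusted values are monotone in the usual step-up sense.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    _, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    flags = q_values <= q
    return flags, q_values
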