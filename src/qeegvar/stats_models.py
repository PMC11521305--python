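"""Per-laboratory fits and cross-laboratory variance decomposition.

Two models are fitted to each endpoint table.

Within laboratory, a one-way fixed-effects linear model

    Y_id = beta_0 + beta_d * TestGroup_d + eps_id,   eps_id ~ N(0, sigma_e^2)

gives group means and their contrasts (ordinary least squares; pooled
residual variance; t-based confidence limits and p-values), matching what
each site would report if it analysed its own data.

Across laboratories, a linear mixed model

    Y_idl = beta_0 + beta_d * TestGroup_d + b_l + d_dl + eps_idl

with b_l ~ N(0, sigma_b^2) (laboratory), d_dl ~ N(0, sigma_d^2)
(laboratory-by-group interaction) and eps ~ N(0, sigma_e^2) decomposes the
total variance into a laboratory share, an interaction share and a
residual (biological) share.  The between-laboratory variability is
sigma_b^2 + sigma_d^2.  Estimation is REML, profiled over the variance
ratios (sigma_b^2/sigma_e^2, sigma_d^2/sigma_e^2) with box constraints so
boundary optima (components estimated exactly zero) are reached cleanly.
Mixed-model contrasts use the Wald normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm, t as t_dist

from .errors import ConvergenceError, DesignError, InsufficientDataError, QeegError

__all__ = [
    "log10_endpoint",
    "ContrastResult",
    "PerLabFit",
    "fit_per_lab",
    "VarianceComponents",
    "fit_crosslab",
    "method_of_moments",
    "emm_contrast",
    "variance_table",
    "TukeySummary",
    "tukey_summary",
]


def log10_endpoint(values, labels=None) -> np.ndarray:
    """Elementwise log10 for strictly positive endpoint values.

    ``labels`` (parallel sequence, e.g. (lab, subject) pairs) is used to
    name offenders when a value is not positive.  Percent-change endpoints
    can be negative and must not be passed through this transform.
    """
    v = np.asarray(values, dtype=float)
    bad = ~(v > 0)
    if bad.any():
        idx = np.flatnonzero(bad)
        who = [labels[i] for i in idx] if labels is not None else idx.tolist()
        raise QeegError(f"log10 endpoint requires positive values; offending: {who}")
    return np.log10(v)


@dataclass
class ContrastResult:
    name: str
    estimate: float
    se: float
    df: float | None  # None -> Wald normal
    stat: float
    p: float
    ci_low: float
    ci_high: float


@dataclass
class PerLabFit:
    lab_id: str
    endpoint: str
    groups: list[str]
    n_per_group: dict[str, int]
    group_means: dict[str, tuple[float, float, float, float]]  # est, se, lo, hi
    contrasts: list[ContrastResult]
    sigma_e2: float
    df: int


def fit_per_lab(
    table: pd.DataFrame,
    lab_id: str,
    endpoint: str,
    contrasts: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> PerLabFit:
    """One-way OLS fit for a single laboratory with group contrasts.

    ``contrasts`` is a list of (a, b) pairs estimating mean(a) - mean(b);
    by default every later group is contrasted against every earlier one
    in order of appearance (so two groups give the single TG-WT or
    dose-vehicle difference).  SEs use the residual variance pooled over
    all groups, sigma_e^2 = RSS / (n - g); intervals and p-values come
    from the t distribution on n - g degrees of freedom.
    """
    sub = table[(table["lab_id"] == lab_id) & (table["endpoint"] == endpoint)]
    if sub.empty:
        raise InsufficientDataError(f"no rows for lab {lab_id}, endpoint {endpoint}")
    groups = list(dict.fromkeys(sub["group"]))
    by_group = {g: sub.loc[sub["group"] == g, "value"].to_numpy(float) for g in groups}
    for g, v in by_group.items():
        if len(v) < 2:
            raise InsufficientDataError(
                f"group {g!r} in lab {lab_id} has fewer than 2 subjects"
            )
    n = sum(len(v) for v in by_group.values())
    df = n - len(groups)
    rss = sum(float(((v - v.mean()) ** 2).sum()) for v in by_group.values())
    sigma_e2 = rss / df
    sig = math.sqrt(sigma_e2)
    tq = t_dist.ppf(1 - alpha / 2, df)

    group_means = {}
    for g, v in by_group.items():
        se = sig / math.sqrt(len(v))
        m = float(v.mean())
        group_means[g] = (m, se, m - tq * se, m + tq * se)

    if contrasts is None:
        contrasts = [(b, a) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    results = []
    for a, b in contrasts:
        est = group_means[a][0] - group_means[b][0]
        se = sig * math.sqrt(1 / len(by_group[a]) + 1 / len(by_group[b]))
        stat = est / se if se > 0 else 0.0
        p = 2 * t_dist.sf(abs(stat), df) if se > 0 else 1.0
        results.append(
            ContrastResult(
                name=f"{a} - {b}",
                estimate=est,
                se=se,
                df=df,
                stat=stat,
                p=float(p),
                ci_low=est - tq * se,
                ci_high=est + tq * se,
            )
        )
    return PerLabFit(
        lab_id=lab_id,
        endpoint=endpoint,
        groups=groups,
        n_per_group={g: len(v) for g, v in by_group.items()},
        group_means=group_means,
        contrasts=results,
        sigma_e2=sigma_e2,
        df=df,
    )


# ---------------------------------------------------------------------------
# Cross-laboratory mixed model


@dataclass
class VarianceComponents:
    """REML fit of the two-variance-component cross-laboratory model."""

    sigma_b2: float  # ContributorID (laboratory)
    sigma_d2: float  # TestgroupID:ContributorID (interaction)
    sigma_e2: float  # Residual (biological)
    beta: dict[str, float]
    beta_cov: np.ndarray
    groups: list[str]
    loglik: float
    n_obs: int
    n_labs: int
    boundary: dict[str, bool] = field(default_factory=dict)
    converged: bool = True

    @property
    def total(self) -> float:
        return self.sigma_b2 + self.sigma_d2 + self.sigma_e2

    @property
    def shares(self) -> dict[str, float]:
        """Percent of total variance per component."""
        tot = self.total
        if tot <= 0:
            return {"ContributorID": 0.0, "TestgroupID:ContributorID": 0.0, "Residual": 0.0}
        return {
            "ContributorID": 100.0 * self.sigma_b2 / tot,
            "TestgroupID:ContributorID": 100.0 * self.sigma_d2 / tot,
            "Residual": 100.0 * self.sigma_e2 / tot,
        }

    @property
    def between_lab(self) -> float:
        """Between-laboratory variability: sigma_b^2 + sigma_d^2."""
        return self.sigma_b2 + self.sigma_d2


def _design(sub: pd.DataFrame):
    y = sub["value"].to_numpy(float)
    labs = list(dict.fromkeys(sub["lab_id"]))
    groups = list(dict.fromkeys(sub["group"]))
    lab_idx = sub["lab_id"].map({l: i for i, l in enumerate(labs)}).to_numpy()
    grp_idx = sub["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    n = len(y)
    X = np.zeros((n, len(groups)))
    X[:, 0] = 1.0
    for j in range(1, len(groups)):
        X[grp_idx == j, j] = 1.0
    Zb = np.zeros((n, len(labs)))
    Zb[np.arange(n), lab_idx] = 1.0
    cell = lab_idx * len(groups) + grp_idx
    cells = np.unique(cell)
    Zd = np.zeros((n, len(cells)))
    Zd[np.arange(n), np.searchsorted(cells, cell)] = 1.0
    return y, X, Zb, Zd, labs, groups


def _reml_pieces(y, X, Z, gamma):
    """Woodbury evaluation of the profiled REML criterion.

    V = sigma_e^2 * W with W = I + Z diag(gamma per column) Z'.  Returns
    the criterion (-2 restricted log-likelihood profiled over sigma_e^2
    and beta, up to an additive constant) plus the pieces needed to
    reconstruct estimates.
    """
    n, p = X.shape
    g = np.asarray(gamma, dtype=float)
    sqg = np.sqrt(np.maximum(g, 0.0))
    Zs = Z * sqg  # n x q
    A = np.eye(Z.shape[1]) + Zs.T @ Zs
    cho = np.linalg.cholesky(A)
    logdetW = 2.0 * float(np.log(np.diag(cho)).sum())

    def winv(M):
        t = Zs.T @ M
        u = np.linalg.solve(cho.T, np.linalg.solve(cho, t))
        return M - Zs @ u

    Wy = winv(y)
    WX = winv(X)
    XtWX = X.T @ WX
    XtWy = X.T @ Wy
    sign, logdetXtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise ConvergenceError("X'W^-1X not positive definite")
    beta = np.linalg.solve(XtWX, XtWy)
    qform = float(y @ Wy - XtWy @ beta)
    qform = max(qform, 1e-300)
    crit = logdetW + logdetXtWX + (n - p) * math.log(qform)
    return crit, beta, XtWX, qform


def method_of_moments(table: pd.DataFrame, endpoint: str):
    """Expected-mean-squares (ANOVA) estimator for the balanced design.

    Closed-form method-of-moments estimates of (sigma_b^2, sigma_d^2,
    sigma_e^2) from the lab, lab-by-group and within-cell mean squares.
    Estimates can be negative (interior REML optima coincide with this
    estimator on balanced data only when all components are positive).
    For unbalanced data, cell sizes are replaced by their harmonic mean
    and the result is approximate; the package uses it only as an
    optimiser start and as a test oracle on balanced data.
    """
    sub = table[table["endpoint"] == endpoint]
    piv = sub.groupby(["lab_id", "group"])["value"]
    cell_means = piv.mean().unstack()
    cell_n = piv.count().unstack()
    L, D = cell_means.shape
    if cell_means.isna().any().any():
        raise DesignError("method of moments requires every lab x group cell filled")
    n_h = len(cell_n.values.ravel()) / np.sum(1.0 / cell_n.values.ravel())
    m = cell_means.to_numpy()
    grand = m.mean()
    lab_means = m.mean(axis=1)
    grp_means = m.mean(axis=0)
    ss_lab = D * n_h * ((lab_means - grand) ** 2).sum()
    resid = m - lab_means[:, None] - grp_means[None, :] + grand
    ss_int = n_h * (resid**2).sum()
    ssw = float(
        sub.groupby(["lab_id", "group"])["value"]
        .apply(lambda v: ((v - v.mean()) ** 2).sum())
        .sum()
    )
    df_w = len(sub) - L * D
    mse = ssw / df_w if df_w > 0 else 0.0
    ms_lab = ss_lab / (L - 1)
    ms_int = ss_int / ((L - 1) * (D - 1)) if D > 1 else mse
    sigma_d2 = (ms_int - mse) / n_h
    sigma_b2 = (ms_lab - ms_int) / (D * n_h)
    return float(sigma_b2), float(sigma_d2), float(mse)


def fit_crosslab(
    table: pd.DataFrame,
    endpoint: str,
    tol: float = 1e-10,
) -> VarianceComponents:
    """REML variance decomposition of one endpoint across laboratories.

    Profiles the restricted likelihood over the two variance ratios
    (laboratory and interaction, each relative to the residual) with
    non-negativity box constraints, deterministic multi-start (method of
    moments, the origin, and equal ratios), and tolerance ``tol`` on the
    criterion.  Components estimated at the zero boundary are flagged.
    """
    sub = table[table["endpoint"] == endpoint]
    if sub.empty:
        raise InsufficientDataError(f"no rows for endpoint {endpoint}")
    y, X, Zb, Zd, labs, groups = _design(sub)
    if len(labs) < 2:
        raise DesignError("cross-laboratory model needs at least 2 laboratories")
    counts = sub.groupby(["lab_id", "group"]).size().unstack()
    if counts.isna().any().any():
        raise DesignError("every laboratory must contain every group")

    Z = np.hstack([Zb, Zd])
    nb, nd = Zb.shape[1], Zd.shape[1]

    def expand(gam2):
        return np.concatenate([np.full(nb, gam2[0]), np.full(nd, gam2[1])])

    def crit_fn(gam2):
        gam2 = np.maximum(gam2, 0.0)
        return _reml_pieces(y, X, Z, expand(gam2))[0]

    starts = [np.array([0.0, 0.0]), np.array([1.0, 1.0])]
    try:
        b2, d2, e2 = method_of_moments(table, endpoint)
        if e2 > 0:
            starts.insert(0, np.array([max(b2, 0.0) / e2, max(d2, 0.0) / e2]))
    except (DesignError, ZeroDivisionError):
        pass

    best = None
    for x0 in starts:
        res = optimize.minimize(
            crit_fn,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, 1e8), (0.0, 1e8)],
            options={"ftol": tol, "gtol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise ConvergenceError("REML optimisation failed")

    gam = np.maximum(best.x, 0.0)
    gam[gam < 1e-10] = 0.0  # snap numerically-zero ratios to the boundary
    crit, beta, XtWX, qform = _reml_pieces(y, X, Z, expand(gam))
    n, p = X.shape
    sigma_e2 = qform / (n - p)
    sigma_b2 = gam[0] * sigma_e2
    sigma_d2 = gam[1] * sigma_e2
    beta_cov = sigma_e2 * np.linalg.inv(XtWX)
    # -2 restricted log-likelihood at the optimum (full constant included)
    logdetW_part = crit - (n - p) * math.log(qform)
    minus2ll = (
        (n - p) * math.log(2 * math.pi * sigma_e2)
        + logdetW_part
        + (n - p)
    )
    names = ["(Intercept)"] + [f"{g} - {groups[0]}" for g in groups[1:]]
    return VarianceComponents(
        sigma_b2=float(sigma_b2),
        sigma_d2=float(sigma_d2),
        sigma_e2=float(sigma_e2),
        beta=dict(zip(names, beta.tolist())),
        beta_cov=beta_cov,
        groups=groups,
        loglik=-0.5 * minus2ll,
        n_obs=n,
        n_labs=len(labs),
        boundary={
            "ContributorID": gam[0] == 0.0,
            "TestgroupID:ContributorID": gam[1] == 0.0,
        },
        converged=bool(best.success),
    )


def emm_contrast(
    fit: VarianceComponents,
    pair: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> ContrastResult:
    """Marginal group contrast from the mixed-model fit.

    Estimates mean(a) - mean(b) for ``pair`` (default: second group minus
    the reference) with the model-based SE at the REML optimum and a Wald
    normal interval and p-value.
    """
    groups = fit.groups
    if pair is None:
        pair = (groups[1], groups[0])
    a, b = pair
    coef = np.zeros(len(groups))

    def loading(g):
        v = np.zeros(len(groups))
        v[0] = 1.0
        if g != groups[0]:
            v[groups.index(g)] = 1.0
        return v

    coef = loading(a) - loading(b)
    beta_vec = np.array(list(fit.beta.values()))
    est = float(coef @ beta_vec)
    se = float(np.sqrt(coef @ fit.beta_cov @ coef))
    z = est / se if se > 0 else 0.0
    q = norm.ppf(1 - alpha / 2)
    return ContrastResult(
        name=f"{a} - {b}",
        estimate=est,
        se=se,
        df=None,
        stat=z,
        p=float(2 * norm.sf(abs(z))),
        ci_low=est - q * se,
        ci_high=est + q * se,
    )


def variance_table(fits: dict[str, VarianceComponents | tuple]) -> pd.DataFrame:
    """Variance-components table: rows ContributorID / interaction /
    Residual / Total, one column per condition, cells "estimate (share%)".

    Estimates print with 4 decimals and shares with 2; the Total row is
    the exact component sum.  Values may be given as fitted
    :class:`VarianceComponents` or as raw (sigma_b2, sigma_d2, sigma_e2)
    triples (e.g. components transcribed from a published table).
    """
    rows = ["ContributorID", "TestgroupID:ContributorID", "Residual", "Total"]
    out = {}
    for cond, fit in fits.items():
        if isinstance(fit, VarianceComponents):
            comps = (fit.sigma_b2, fit.sigma_d2, fit.sigma_e2)
        else:
            comps = tuple(float(v) for v in fit)
        total = sum(comps)
        shares = [100.0 * c / total if total > 0 else 0.0 for c in comps]
        cells = [f"{c:.4f} ({s:.2f}%)" for c, s in zip(comps, shares)]
        cells.append(f"{total:.4f} ({100.0 if total > 0 else 0.0:.2f}%)")
        out[cond] = cells
    return pd.DataFrame(out, index=rows).rename_axis("Effect")


# ---------------------------------------------------------------------------
# Boxplot summaries


@dataclass
class TukeySummary:
    q1: float
    median: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def tukey_summary(values) -> TukeySummary:
    """Five-number boxplot summary with 1.5*IQR whiskers.

    Quartiles use linear interpolation; the whiskers are the most extreme
    data values not beyond Q3 + 1.5*IQR / Q1 - 1.5*IQR; points outside are
    outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("tukey_summary needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    hi_fence = q3 + 1.5 * iqr
    lo_fence = q1 - 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return TukeySummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]),
    )
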