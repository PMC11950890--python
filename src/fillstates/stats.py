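"""Marker-comparison statistics.

Nonparametric staging tests (Kruskal-Wallis with post hoc Mann-Whitney),
paired ROC comparison via the DeLong structural-components estimator,
partial Spearman correlations with covariate adjustment, and multivariate
linear models of cognitive performance with a reflect-and-square-root
transform for left-skewed scores.

Standard procedures are delegated to scipy/statsmodels; the DeLong test
and the partial Spearman construction are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.multivariate.manova import MANOVA
import statsmodels.api as sm


class DegenerateDesignError(ValueError):
    """A test's design is degenerate (single group, rank deficiency, ...)."""


# ---------------------------------------------------------------------------
# staging tests


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Kruskal-Wallis H across groups defined by ``labels``.

    Midranks with tie correction; p from chi-square with k-1 df.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise DegenerateDesignError("Kruskal-Wallis needs >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise DegenerateDesignError("empty group")
    if all(np.array_equal(np.sort(g), np.sort(groups[0])) for g in groups[1:]):
        # identical samples: H = 0 by construction, scipy raises on all-tied data
        if np.ptp(values) == 0:
            return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(
    a, b, alternative: str = "two-sided", exact_max_n: int = 16
) -> tuple[float, float]:
    """Mann-Whitney U of ``a`` vs ``b`` (U reported for sample ``a``).

    Exact enumeration when the combined sample is small (<= ``exact_max_n``)
    and tie-free; otherwise the normal approximation with tie-corrected
    variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size + b.size <= exact_max_n and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni(alpha: float, m: int, display_decimals: int = 3) -> float:
    """Bonferroni-corrected alpha = alpha/m, rounded for display (.05/3 -> .017)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return round(alpha / m, display_decimals)


# ---------------------------------------------------------------------------
# ROC / DeLong


def roc_auc(scores, labels, positive_direction: str = "greater") -> float:
    """AUC via the rank (Mann-Whitney) formulation; ties count 0.5.

    ``positive_direction='greater'`` means higher scores indicate the
    positive class; ``'less'`` flips the score sign first.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if positive_direction == "less":
        scores = -scores
    elif positive_direction != "greater":
        raise ValueError("positive_direction must be 'greater' or 'less'")
    ranks = sps.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x)


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong V10 (per positive) and V01 (per negative) components and AUC."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


@dataclass
class ROCComparison:
    """Paired comparison of two correlated AUCs (same subjects)."""

    auc_a: float
    auc_b: float
    delong_z: float
    p_value: float
    n_pos: int
    n_neg: int
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels, alternative: str = "two-sided") -> ROCComparison:
    """DeLong test for two correlated AUCs measured on the same subjects.

    Estimates the covariance of the two AUCs from the structural components
    of the underlying U-statistics; z = (AUC_a - AUC_b) / SE(diff).
    A zero-variance difference (e.g. identical rankings) sets the
    ``degenerate`` flag with p = 1 when the AUCs agree.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    auc_a, v10_a, v01_a = _structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _structural_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var_diff = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    var_diff = max(float(var_diff), 0.0)
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        return ROCComparison(float(auc_a), float(auc_b), float(z), p, m, n, degenerate=True)
    z = diff / np.sqrt(var_diff)
    if alternative == "two-sided":
        p = 2 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        p = sps.norm.sf(z)
    elif alternative == "less":
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return ROCComparison(float(auc_a), float(auc_b), float(z), float(p), m, n)


# ---------------------------------------------------------------------------
# partial Spearman


@dataclass
class PartialCorrelation:
    rho: float
    p_value: float
    n: int
    covariate_names: list[str] = field(default_factory=list)


def partial_spearman(x, y, covariates=None, covariate_names=None) -> PartialCorrelation:
    """Partial Spearman correlation of x and y given covariates.

    Realized as the partial Pearson correlation of midranks: all variables
    are rank-transformed, x and y ranks are residualized on the ranked
    covariates (plus intercept) by least squares, and the Pearson
    correlation of the residuals is returned. p from a t distribution with
    n - k - 2 df (k covariates). With no covariates this reduces exactly
    to the plain Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y lengths differ")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDesignError("constant x or y")
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n and cov.shape[1] == n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate length mismatch")
    k = cov.shape[1]
    if n <= k + 2:
        raise DegenerateDesignError(f"n={n} too small for {k} covariates")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    design = np.column_stack([np.ones(n)] + [sps.rankdata(cov[:, j]) for j in range(k)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDesignError("rank-deficient covariates")
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    rho = float(np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey)))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - k - 2
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df))
    names = list(covariate_names) if covariate_names else [f"c{j}" for j in range(k)]
    return PartialCorrelation(rho, p, n, names)


def reflect_sqrt_transform(scores) -> np.ndarray:
    """t(x) = sqrt((max(x) + 1) - x): strictly decreasing, so downstream
    association signs invert (a negative raw association yields a positive
    coefficient on the transformed scale)."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return np.sqrt(scores.max() + 1.0 - scores)


# ---------------------------------------------------------------------------
# regression models


@dataclass
class RegressionSpec:
    """Design for one cognition model: dependent score block and predictors."""

    dependents: list[str]
    terms: list[str]  # predictor column names, intercept added automatically


@dataclass
class RegressionResult:
    spec: RegressionSpec
    n: int
    multivariate: pd.DataFrame  # per-term Wilks' lambda, F, df, p
    univariate: pd.DataFrame  # per (dependent, term): beta, CI, t, p
    residual_sd: dict


def fit_regression(spec: RegressionSpec, data: pd.DataFrame) -> RegressionResult:
    """Multivariate linear model of a block of cognitive scores.

    Per-term multivariate significance uses Wilks' lambda with Rao's F
    approximation (via statsmodels MANOVA); per-score univariate OLS
    supplies coefficients with 95% CIs. Complete cases only.
    """
    cols = spec.dependents + spec.terms
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    d = data[cols].dropna()
    n = len(d)
    Y = d[spec.dependents].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n)] + [d[t].to_numpy(dtype=float) for t in spec.terms])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear offenders by greedy QR-style elimination
        bad = []
        keep = [0]
        for j in range(1, X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append((["intercept"] + spec.terms)[j])
        raise DegenerateDesignError(f"design matrix rank deficient; collinear terms: {bad}")

    term_names = ["intercept"] + spec.terms
    rows = []
    if Y.shape[1] > 1:
        mv = MANOVA(Y, X)
        hyps = [(name, np.eye(X.shape[1])[[j]]) for j, name in enumerate(term_names)]
        res = mv.mv_test(hyps)
        for name in term_names:
            w = res.results[name]["stat"].loc["Wilks' lambda"]
            rows.append(
                {
                    "term": name,
                    "wilks_lambda": float(w["Value"]),
                    "F": float(w["F Value"]),
                    "df_num": float(w["Num DF"]),
                    "df_den": float(w["Den DF"]),
                    "p": float(w["Pr > F"]),
                }
            )
    else:
        # single response: Wilks' F reduces exactly to the univariate
        # partial F (t^2) for each term
        fit0 = sm.OLS(Y[:, 0], X).fit()
        df_den = n - X.shape[1]
        for j, name in enumerate(term_names):
            f_val = float(fit0.tvalues[j] ** 2)
            rows.append(
                {
                    "term": name,
                    "wilks_lambda": df_den / (df_den + f_val),
                    "F": f_val,
                    "df_num": 1.0,
                    "df_den": float(df_den),
                    "p": float(fit0.pvalues[j]),
                }
            )
    multivariate = pd.DataFrame(rows).set_index("term")

    uni_rows = []
    resid_sd = {}
    for dep in spec.dependents:
        fit = sm.OLS(d[dep].to_numpy(dtype=float), X).fit()
        ci = fit.conf_int(alpha=0.05)
        for j, name in enumerate(term_names):
            uni_rows.append(
                {
                    "dependent": dep,
                    "term": name,
                    "beta": float(fit.params[j]),
                    "ci_low": float(ci[j, 0]),
                    "ci_high": float(ci[j, 1]),
                    "t": float(fit.tvalues[j]),
                    "p": float(fit.pvalues[j]),
                }
            )
        resid_sd[dep] = float(np.sqrt(fit.mse_resid))
    univariate = pd.DataFrame(uni_rows)
    return RegressionResult(spec, n, multivariate, univariate, resid_sd)


def significance_tiers(p: float, m: int = 3, alpha: float = 0.05) -> dict:
    """The three reporting tiers: nominal alpha, Bonferroni-corrected, .001."""
    return {
        "alpha_05": bool(p < alpha),
        "alpha_bonferroni": bool(p < bonferroni(alpha, m)),
        "alpha_001": bool(p < 0.001),
    }
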