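"""Effect sizes and inferential machinery for the repletion audit.

Group comparisons use the pooled-variance two-sample Student's t and
Cohen's d (standardized mean difference; ~0.2 small, ~0.5 moderate, ~0.8
large).  Repletion effectiveness compares pre (index) with post (follow-up)
serum levels; the decision/effect regression is ordinary least squares with
the conventional summary-table layout (coefficients, SEs, significance
stars at 0.1/0.05/0.01, R^2, adjusted R^2, residual SE and the overall F
with its (k, n-k-1) degrees of freedom); threshold heterogeneity across ICU
units or medication groups is a one-way fixed-effects ANOVA.

OLS fitting is delegated to statsmodels and the ANOVA to scipy; the
surrounding contracts (rank-deficiency diagnosis, small-group exclusion,
star thresholds, paired/unpaired d) are the package's own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .errors import DataError


@dataclass(frozen=True)
class GroupStats:
    """Sufficient statistics of one group: n, mean, sample SD (n-1)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError("GroupStats requires n >= 1")
        if self.sd < 0:
            raise DataError("GroupStats requires sd >= 0")

    @classmethod
    def from_values(cls, values) -> "GroupStats":
        values = np.asarray(values, dtype=float)
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        return cls(n=len(values), mean=float(np.mean(values)), sd=sd)


@dataclass(frozen=True)
class EffectResult:
    """Two-group comparison: pooled t, two-sided p, Cohen's d."""

    t_statistic: float
    p_value: float
    d_cohen: float
    df: float
    n_a: int = 0
    n_b: int = 0
    degenerate: bool = False


def _as_stats(x) -> GroupStats:
    return x if isinstance(x, GroupStats) else GroupStats.from_values(x)


def pooled_sd(a: GroupStats, b: GroupStats) -> float:
    num = (a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2
    den = a.n + b.n - 2
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def cohens_d(a, b) -> float:
    """Cohen's d: (mean_a - mean_b) / pooled SD.

    Degenerate pooled SD (both groups constant) yields 0 for equal means
    and a signed infinity sentinel otherwise.  Scale- and shift-invariant.
    """
    a, b = _as_stats(a), _as_stats(b)
    if a.n + b.n < 3:
        raise DataError("cohens_d requires at least 3 observations in total")
    sp = pooled_sd(a, b)
    diff = a.mean - b.mean
    if sp == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
    return float(diff / sp)


def students_t(a, b) -> EffectResult:
    """Pooled-variance two-sample t with two-sided p and Cohen's d.

    ``df = n_a + n_b - 2``.  Zero pooled variance is flagged degenerate
    (t = 0, p = 1 for equal means; infinite t, p = 0 otherwise).
    Antisymmetric: swapping the groups negates t and d, preserves p.
    """
    a, b = _as_stats(a), _as_stats(b)
    if a.n < 2 or b.n < 2:
        raise DataError("students_t requires n >= 2 in each group")
    df = a.n + b.n - 2
    sp = pooled_sd(a, b)
    diff = a.mean - b.mean
    if sp == 0.0:
        t = 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
        p = 1.0 if diff == 0.0 else 0.0
        return EffectResult(t, p, cohens_d(a, b), df, a.n, b.n, degenerate=True)
    t = diff / (sp * np.sqrt(1.0 / a.n + 1.0 / b.n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return EffectResult(float(t), p, cohens_d(a, b), df, a.n, b.n)


def pre_post_effect(episodes: pd.DataFrame, paired: bool = False) -> pd.DataFrame:
    """Repletion effectiveness per electrolyte: pre vs post serum levels.

    Uses repletion episodes that carry both an index value and a follow-up
    value.  The default is the unpaired pooled-SD comparison of the two
    distributions; ``paired=True`` computes t and d on the within-episode
    differences instead (d = mean(post - pre) / SD(post - pre)).  The sign
    convention is post minus pre, so a positive d means levels rose.
    Electrolytes with fewer than two complete episodes are flagged
    undefined rather than dropped.
    """
    rows = []
    complete = episodes.loc[
        episodes["order_time"].notna()
        & episodes["index_value"].notna()
        & episodes["followup_value"].notna()
    ]
    for elec in sorted(episodes["electrolyte"].unique()):
        sub = complete.loc[complete["electrolyte"] == elec]
        pre = sub["index_value"].to_numpy(dtype=float)
        post = sub["followup_value"].to_numpy(dtype=float)
        if len(pre) < 2:
            rows.append(
                {
                    "electrolyte": elec,
                    "n": len(pre),
                    "mean_pre": np.nan,
                    "mean_post": np.nan,
                    "t": np.nan,
                    "p": np.nan,
                    "d_cohen": np.nan,
                    "defined": False,
                }
            )
            continue
        if paired:
            diff = post - pre
            t, p = sps.ttest_rel(post, pre)
            sd = float(np.std(diff, ddof=1))
            d = 0.0 if sd == 0.0 and diff.mean() == 0.0 else float(diff.mean() / sd) if sd else np.inf
        else:
            res = students_t(post, pre)
            t, p, d = res.t_statistic, res.p_value, res.d_cohen
        rows.append(
            {
                "electrolyte": elec,
                "n": len(pre),
                "mean_pre": float(pre.mean()),
                "mean_post": float(post.mean()),
                "t": float(t),
                "p": float(p),
                "d_cohen": float(d),
                "defined": True,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionFit:
    """OLS summary in the audit's table layout."""

    coefficients: pd.DataFrame  # index: predictor (+ const); columns: coef, se, t, p, stars
    n_observations: int
    r_squared: float
    adjusted_r_squared: float
    residual_std_error: float
    residual_df: int
    f_statistic: float
    f_df: tuple[int, int] = (0, 0)
    f_p_value: float = np.nan
    dropped_predictors: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.coefficients.copy()
        out.index.name = "predictor"
        return out.reset_index()


def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def decision_regression(
    features: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    stepwise: str | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> RegressionFit:
    """OLS of the repletion outcome on clinical covariates.

    ``outcome`` is typically the post-repletion serum level (with the
    same-electrolyte pre value among the predictors) or a 0/1 replace
    decision fitted as a linear probability model.  Complete cases only.
    A rank-deficient design is a hard error naming the collinear columns.

    ``stepwise`` optionally runs a non-canonical forward-addition
    (``"add"``) or backward-subtraction (``"subtract"``) p-value screening
    before the final fit; the default fits all predictors at once.
    """
    cols = [outcome] + list(predictors)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise DataError(f"feature table lacks column(s): {', '.join(missing)}")
    data = features[cols].dropna()
    n, k = len(data), len(predictors)
    if n <= k + 1:
        raise DataError(f"need more than k+1={k + 1} complete observations, have {n}")

    X = data[list(predictors)].to_numpy(dtype=float)
    keep = list(predictors)
    const_like = [p for p, s in zip(keep, X.std(axis=0)) if s == 0.0]
    if const_like:
        raise DataError(f"zero-variance predictor(s): {', '.join(const_like)}")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = _name_collinear(design, ["const"] + keep)
        raise DataError(f"rank-deficient design; collinear column(s): {', '.join(collinear)}")

    if stepwise in ("add", "subtract"):
        keep = _stepwise_screen(data, outcome, keep, stepwise, alpha_enter, alpha_remove)
    elif stepwise is not None:
        raise DataError(f"unknown stepwise mode {stepwise!r}")

    y = data[outcome].to_numpy(dtype=float)
    Xk = sm.add_constant(data[keep].to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant outcome: 0/0 R^2
        fit = sm.OLS(y, Xk).fit()
        r2 = float(fit.rsquared)  # lazy property; keep inside the suppression
        r2_adj = float(fit.rsquared_adj)
    if y.std() == 0.0:  # constant outcome: define R^2 as 0, not 0/0
        r2, r2_adj = 0.0, 0.0

    names = ["const"] + keep
    coef = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        },
        index=names,
    )
    coef["stars"] = [_stars(p) for p in coef["p"]]
    return RegressionFit(
        coefficients=coef,
        n_observations=n,
        r_squared=r2,
        adjusted_r_squared=r2_adj,
        residual_std_error=float(np.sqrt(fit.mse_resid)),
        residual_df=int(fit.df_resid),
        f_statistic=float(fit.fvalue) if len(keep) else np.nan,
        f_df=(int(fit.df_model), int(fit.df_resid)),
        f_p_value=float(fit.f_pvalue) if len(keep) else np.nan,
        dropped_predictors=[p for p in predictors if p not in keep],
    )


def _name_collinear(design: np.ndarray, names: list[str]) -> list[str]:
    """Identify columns that are linear combinations of earlier ones (QR)."""
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    return [names[j] for j in range(design.shape[1]) if diag[j] <= tol]


def _stepwise_screen(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    mode: str,
    alpha_enter: float,
    alpha_remove: float,
) -> list[str]:
    """Forward-addition / backward-subtraction p-value screening.

    A non-canonical convenience: variables enter (or leave) one at a time
    by the p-value of their coefficient.  Exposed for parity with
    stepwise-style variable screening, not recommended for inference.
    """
    y = data[outcome].to_numpy(dtype=float)

    def _pvals(sel: list[str]) -> pd.Series:
        X = sm.add_constant(data[sel].to_numpy(dtype=float), has_constant="add")
        fit = sm.OLS(y, X).fit()
        return pd.Series(fit.pvalues[1:], index=sel)

    if mode == "add":
        selected: list[str] = []
        remaining = list(predictors)
        improved = True
        while improved and remaining:
            improved = False
            best, best_p = None, alpha_enter
            for cand in remaining:
                p = _pvals(selected + [cand])[cand]
                if p < best_p:
                    best, best_p = cand, p
            if best is not None:
                selected.append(best)
                remaining.remove(best)
                improved = True
        return selected or list(predictors)
    selected = list(predictors)
    while len(selected) > 1:
        p = _pvals(selected)
        worst = p.idxmax()
        if p[worst] <= alpha_remove:
            break
        selected.remove(worst)
    return selected


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_sizes: dict = field(default_factory=dict)
    excluded_groups: tuple = ()


def threshold_anova(values, groups) -> AnovaResult:
    """One-way fixed-effects ANOVA of pre-repletion values across groups.

    ``groups`` labels each value with its ICU unit (or medication-exposure
    group).  Groups with fewer than two observations are excluded with a
    warning and the degrees of freedom adjusted; at least two usable groups
    are required.  df = (groups - 1, total - groups).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise DataError("values and groups must align")
    samples: dict = {}
    excluded = []
    for g in pd.unique(groups):
        sample = values[groups == g]
        if len(sample) < 2:
            excluded.append(g)
        else:
            samples[g] = sample
    if excluded:
        warnings.warn(
            f"excluding group(s) with n < 2 from ANOVA: {excluded}", stacklevel=2
        )
    if len(samples) < 2:
        raise DataError("threshold_anova requires at least two groups with n >= 2")
    arrays = list(samples.values())
    if all(np.allclose(a, arrays[0].mean()) for a in arrays) and all(a.std() == 0 for a in arrays):
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    return AnovaResult(
        f_statistic=float(f),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        p_value=float(p),
        group_sizes={g: len(a) for g, a in samples.items()},
        excluded_groups=tuple(excluded),
    )
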