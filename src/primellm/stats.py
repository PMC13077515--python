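"""Statistical comparison suite for benchmark accuracies and PrIME scores.

Question-level accuracy is compared across models with a one-way
repeated-measures ANOVA (model within-subjects, question as the repeated
factor) followed by Holm-corrected paired t tests.  PrIME scores — defined
per replicate, not per question — are compared with a between-subjects
one-way ANOVA and Tukey HSD contrasts.  Planned two-group contrasts
(e.g. reasoning vs non-reasoning models) report t tests (Welch or pooled)
with Cohen d, Hedges g and its normal-approximation CI, and the
common-language effect size.  Question-level regressions use a linear mixed
model with a random intercept per question; model-level regressions use OLS.

Standard machinery is delegated to scipy / statsmodels; results are wrapped
in small typed containers with a uniform surface.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ValidationError

logger = logging.getLogger(__name__)

#: Smallest p-value ever reported; below this, results mean "beyond
#: representable precision", never an exact zero.
P_FLOOR = 1e-300


def _floor_p(p: float) -> float:
    if np.isnan(p):
        return p
    return max(float(p), P_FLOOR)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    design: str  # "within" | "between"
    ss: Mapping[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"{self.design}-subjects one-way ANOVA: "
            f"F({self.df_num}, {self.df_den}) = {self.F:.4g}, p = {self.p:.3g}"
        )


@dataclass(frozen=True)
class PairwiseTable:
    """All-pairs post hoc contrasts with familywise-adjusted p-values."""

    frame: pd.DataFrame  # group_a, group_b, mean_difference, ci_low, ci_high, p_raw, p_adjusted
    method: str  # "holm_paired_t" | "tukey_hsd"

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variance_mode: str  # "welch" | "pooled"


@dataclass(frozen=True)
class EffectSizes:
    """Standardized two-group effect sizes.

    d: Cohen d with the pooled SD; g: Hedges small-sample-corrected d,
    g = J*d with J = 1 - 3/(4N - 9); g_ci: normal-approximation 95% CI;
    cles: common-language effect size, P(a > b) with ties counted half.
    """

    d: float
    g: float
    g_ci: tuple
    cles: float


@dataclass(frozen=True)
class RegressionResult:
    """Coefficient table plus model-specific extras.

    coefficients maps term -> (estimate, ci_low, ci_high, p).
    random_intercept_variance is set for mixed models, r_squared for OLS.
    """

    coefficients: Mapping[str, tuple]
    random_intercept_variance: float | None = None
    r_squared: float | None = None
    singular: bool = False

    def beta(self, term: str) -> float:
        return self.coefficients[term][0]


# --------------------------------------------------------------------------
# multiple testing


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in the original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError(f"p-values must lie in [0, 1], got {list(p)}")
    return list(multipletests(p, method="holm")[1])


# --------------------------------------------------------------------------
# ANOVA


def _as_wide(values: pd.DataFrame) -> pd.DataFrame:
    if values.isna().any().any():
        missing = values.isna().stack()
        cells = list(missing[missing].index[:5])
        raise AnalysisError(f"missing cells in repeated-measures table: {cells}")
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise AnalysisError(
            f"need >= 2 subjects and >= 2 conditions, got {values.shape}"
        )
    return values.astype(float)


def rm_anova(values: pd.DataFrame) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subject x condition table.

    Classical univariate decomposition (no sphericity correction):
    SS_total = SS_condition + SS_subject + SS_error,
    F = MS_condition / MS_error with df (k-1, (k-1)(n-1)).
    Constant data yields an undefined (NaN) F.
    """
    wide = _as_wide(values)
    x = wide.to_numpy()
    n, k = x.shape
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_cond = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df_den
    if ms_err <= 0:
        f_stat = math.nan if ss_cond == 0 else math.inf
        p = math.nan if ss_cond == 0 else P_FLOOR
    else:
        f_stat = (ss_cond / df_num) / ms_err
        p = _floor_p(sps.f.sf(f_stat, df_num, df_den))
    return AnovaResult(
        F=f_stat,
        df_num=df_num,
        df_den=df_den,
        p=p,
        design="within",
        ss={"condition": ss_cond, "subject": ss_subj, "error": ss_err, "total": ss_total},
    )


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way between-subjects ANOVA; df = (k-1, N-k)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise AnalysisError("need at least 2 groups")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise AnalysisError(f"group {i} has fewer than 2 values")
    k = len(arrs)
    n_total = sum(g.size for g in arrs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = sps.f_oneway(*arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in arrs))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrs))
    return AnovaResult(
        F=float(f_stat),
        df_num=k - 1,
        df_den=n_total - k,
        p=_floor_p(float(p)),
        design="between",
        ss={"between": ss_between, "within": ss_within, "total": ss_between + ss_within},
    )


# --------------------------------------------------------------------------
# post hoc pairwise procedures


def pairwise_paired_t(values: pd.DataFrame, alpha: float = 0.05) -> PairwiseTable:
    """All k(k-1)/2 paired t tests between conditions, Holm-adjusted.

    A zero-variance difference vector is degenerate: identical columns get
    p = 1 exactly; a constant non-zero shift gets infinite t and an
    undefined (NaN) p, logged.
    """
    wide = _as_wide(values)
    n = wide.shape[0]
    tcrit = sps.t.ppf(1 - alpha / 2, n - 1)
    rows = []
    for a, b in itertools.combinations(wide.columns, 2):
        diff = wide[a].to_numpy() - wide[b].to_numpy()
        md = float(diff.mean())
        sd = float(diff.std(ddof=1))
        if sd == 0.0:
            if md == 0.0:
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = math.copysign(math.inf, md), math.nan
                logger.warning(
                    "pairwise_paired_t: constant non-zero difference %s vs %s; p undefined",
                    a, b,
                )
            ci = (md, md)
        else:
            t_stat, p = sps.ttest_rel(wide[a], wide[b])
            p = _floor_p(float(p))
            half = tcrit * sd / math.sqrt(n)
            ci = (md - half, md + half)
        rows.append((a, b, md, ci[0], ci[1], float(t_stat), p))
    frame = pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "mean_difference", "ci_low", "ci_high", "t", "p_raw"],
    )
    adjusted = np.full(len(frame), math.nan)
    ok = ~frame["p_raw"].isna()
    if ok.any():
        adjusted[ok.to_numpy()] = holm_adjust(frame.loc[ok, "p_raw"].tolist())
    frame["p_adjusted"] = adjusted
    return PairwiseTable(frame=frame, method="holm_paired_t")


def tukey_hsd(groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None,
              alpha: float = 0.05) -> PairwiseTable:
    """Tukey HSD all-pairs contrasts with simultaneous CIs.

    p_raw is the unadjusted pooled-t p-value for the same contrast (the
    studentized-range statistic divided by sqrt(2)); p_adjusted is the Tukey
    familywise p from the studentized range distribution.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    oneway_anova(arrs)  # validation side effect
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    res = sps.tukey_hsd(*arrs)
    ci = res.confidence_interval(1 - alpha)
    n_total = sum(g.size for g in arrs)
    df_err = n_total - len(arrs)
    mse = sum(((g - g.mean()) ** 2).sum() for g in arrs) / df_err
    rows = []
    for i, j in itertools.combinations(range(len(arrs)), 2):
        md = float(res.statistic[i, j])
        se = math.sqrt(mse * (1 / arrs[i].size + 1 / arrs[j].size))
        if se == 0.0:
            p_raw = 1.0 if md == 0.0 else math.nan
        else:
            p_raw = _floor_p(2 * sps.t.sf(abs(md) / se, df_err))
        p_adj = _floor_p(float(res.pvalue[i, j]))
        rows.append(
            (labels[i], labels[j], md, float(ci.low[i, j]), float(ci.high[i, j]),
             p_raw, max(p_adj, p_raw if not math.isnan(p_raw) else p_adj))
        )
    frame = pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "mean_difference", "ci_low", "ci_high",
                 "p_raw", "p_adjusted"],
    )
    return PairwiseTable(frame=frame, method="tukey_hsd")


# --------------------------------------------------------------------------
# two-group contrasts and effect sizes


def hedges_j(n_total: int) -> float:
    """Small-sample correction factor J = 1 - 3/(4N - 9)."""
    return 1.0 - 3.0 / (4.0 * n_total - 9.0)


def hedges_g_ci(g: float, n1: int, n2: int, z: float = 1.959963984540054) -> tuple:
    """Normal-approximation 95% CI for Hedges g:
    g +/- z * sqrt((n1+n2)/(n1*n2) + g**2 / (2*(n1+n2)))."""
    n = n1 + n2
    se = math.sqrt(n / (n1 * n2) + g * g / (2 * n))
    return (g - z * se, g + z * se)


def cles(a: Sequence[float], b: Sequence[float]) -> float:
    """Common-language effect size: P(x > y) for x from a, y from b, ties
    counted one half.  cles(a, a) = 0.5; cles(a, b) + cles(b, a) = 1."""
    x = np.asarray(a, dtype=float)[:, None]
    y = np.asarray(b, dtype=float)[None, :]
    return float(((x > y).sum() + 0.5 * (x == y).sum()) / (x.size * y.size))


def two_sample(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variance_mode: str = "welch",
) -> tuple[TTestResult, EffectSizes]:
    """Two-sided two-sample t test plus standardized effect sizes.

    variance_mode "welch" uses the Welch-Satterthwaite df; "pooled" the
    classical n1+n2-2.  Effect sizes always use the pooled SD for d, Hedges
    J for g, and the pair-count CLES.
    """
    if variance_mode not in ("welch", "pooled"):
        raise ValueError(f"variance_mode must be 'welch' or 'pooled', got {variance_mode!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs >= 2 values")
    n1, n2 = a.size, b.size
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    md = a.mean() - b.mean()

    if sp2 == 0.0:
        t_stat = 0.0 if md == 0.0 else math.copysign(math.inf, md)
        p = 1.0 if md == 0.0 else P_FLOOR
        df = float(n1 + n2 - 2)
        d = 0.0 if md == 0.0 else math.copysign(math.inf, md)
    else:
        equal_var = variance_mode == "pooled"
        t_stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(t_stat), _floor_p(float(p))
        if equal_var:
            df = float(n1 + n2 - 2)
        else:
            num = (v1 / n1 + v2 / n2) ** 2
            den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            df = float(num / den)
        d = float(md / math.sqrt(sp2))

    j = hedges_j(n1 + n2)
    g = j * d
    g_ci = hedges_g_ci(g, n1, n2) if math.isfinite(g) else (math.nan, math.nan)
    return (
        TTestResult(t=t_stat, df=df, p=p, variance_mode=variance_mode),
        EffectSizes(d=d, g=g, g_ci=g_ci, cles=cles(a, b)),
    )


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p via the
    t approximation.  Constant input yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise AnalysisError("need paired sequences of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rho, p = sps.spearmanr(x, y)
    return float(rho), _floor_p(float(p))


# --------------------------------------------------------------------------
# regression


def _coef_table(params, conf, pvals) -> dict[str, tuple]:
    out = {}
    for term in params.index:
        out[term] = (
            float(params[term]),
            float(conf.loc[term, 0]),
            float(conf.loc[term, 1]),
            _floor_p(float(pvals[term])),
        )
    return out


def mixed_linear(
    question_level: pd.DataFrame,
    response: str = "accuracy",
    group: str = "question_id",
    domain_reference: str = "DT",
    fixed_effects: Sequence[str] = ("domain", "age_group", "sex", "reasoning"),
) -> RegressionResult:
    """Linear mixed model for question-level accuracy with a random
    intercept per question.

    Fixed effects default to question type (treatment-coded against the
    diagnostic-testing reference), age group, sex and the reasoning flag;
    factors with a single observed level are dropped from the formula.
    A singular fit (random-intercept variance estimated at the boundary or
    non-convergence) is flagged on the result, not fatal.
    """
    df = question_level.copy()
    if ((df[response] < 0) | (df[response] > 1)).any():
        raise ValidationError(f"{response} values must lie in [0, 1]")

    terms = []
    for col in fixed_effects:
        if col not in df.columns:
            continue
        if df[col].nunique() < 2:
            continue  # constant factor: not estimable
        if col == "domain":
            terms.append(f"C(domain, Treatment({domain_reference!r}))")
        elif df[col].dtype == bool or set(df[col].unique()) <= {0, 1, True, False}:
            df[col] = df[col].astype(int)
            terms.append(col)
        else:
            terms.append(f"C({col})")

    if df[response].nunique() == 1:
        # degenerate: the exact ML solution is the constant fit
        const = float(df[response].iloc[0])
        coefs = {"Intercept": (const, const, const, math.nan)}
        return RegressionResult(coefficients=coefs, random_intercept_variance=0.0,
                                singular=True)

    formula = f"{response} ~ " + (" + ".join(terms) if terms else "1")
    model = smf.mixedlm(formula, df, groups=df[group])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
        var_re = float(fit.cov_re.iloc[0, 0])
        singular = bool(not fit.converged or var_re < 1e-10)
        params = fit.params.drop(
            labels=[i for i in fit.params.index if "Var" in i or i == "Group Var"],
            errors="ignore",
        )
        conf = fit.conf_int().loc[params.index]
        coefs = _coef_table(params, conf, fit.pvalues)
    except np.linalg.LinAlgError:
        # degenerate random-effects structure (e.g. tiny designs): fall back
        # to the fixed-effects OLS solution and flag the fit as singular
        logger.warning("mixed_linear: singular mixed fit; reporting OLS fixed effects")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.ols(formula, df).fit()
        var_re = 0.0
        singular = True
        coefs = _coef_table(fit.params, fit.conf_int(), fit.pvalues)
    return RegressionResult(
        coefficients=coefs, random_intercept_variance=var_re, singular=singular
    )


def ols_model(
    model_level: pd.DataFrame,
    response: str = "prime_score",
    predictors: Sequence[str] = ("reasoning",),
) -> RegressionResult:
    """Ordinary least-squares fit with 95% CIs, p-values and R^2.

    Raises :class:`AnalysisError` naming the collinear terms when the design
    matrix is rank-deficient.
    """
    df = model_level.copy()
    terms = []
    for col in predictors:
        if df[col].dtype == bool or set(pd.unique(df[col])) <= {0, 1, True, False}:
            df[col] = df[col].astype(int)
            terms.append(col)
        elif pd.api.types.is_numeric_dtype(df[col]):
            terms.append(col)
        else:
            terms.append(f"C({col})")
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, df)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # walk columns to name the dependent ones
        bad = []
        for i in range(1, model.exog.shape[1]):
            if np.linalg.matrix_rank(model.exog[:, : i + 1]) == np.linalg.matrix_rank(
                model.exog[:, :i]
            ):
                bad.append(model.exog_names[i])
        raise AnalysisError(f"rank-deficient design; collinear term(s): {bad}")
    fit = model.fit()
    coefs = _coef_table(fit.params, fit.conf_int(), fit.pvalues)
    return RegressionResult(coefficients=coefs, r_squared=float(fit.rsquared))
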