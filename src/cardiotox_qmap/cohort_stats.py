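"""Cohort-level statistics: group comparisons, regression, power.

The comparison layer mirrors common small-animal study practice: a
Shapiro-Wilk normality gate routes each variable to a parametric path
(t-test / one-way ANOVA) or a nonparametric path (Mann-Whitney /
Kruskal-Wallis), with Bonferroni-corrected pairwise post-hoc tests.  The
regression layer provides univariable OLS (reporting Pearson R), multiple
linear regression with per-predictor variance inflation factors (VIF) and
adjusted R-squared, and a model-reduction step that drops the predictor
with the weakest univariable correlation.  Sample sizing inverts the exact
noncentral-t power function of the two-sided two-sample t-test.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InputError, MulticollinearityError

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "PowerSpec",
    "normality_gate",
    "compare_groups",
    "univariable",
    "multiple_regression",
    "reduce_model",
    "sample_size_two_sample_t",
    "adjusted_r2",
    "format_p",
]

log = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "subject",
    "group",
    "hct",
    "HR",
    "LVEDV",
    "LVESV",
    "LVSV",
    "CO",
    "LVmass",
    "LVEF",
    "native_t1",
    "t2",
    "ecv",
    "partition_coefficient",
    "vacuolar_pct",
    "fibrosis_pct",
    "inflammation_score",
    "edema_score",
]


@dataclass
class GroupComparison:
    test_used: str  # "t" | "mannwhitney" | "anova" | "kruskal-wallis"
    statistic: float
    p_raw: float
    p_adjusted: float
    pair: tuple = ()

    def __post_init__(self) -> None:
        assert self.p_adjusted >= self.p_raw - 1e-15


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    vif: dict
    r2: float
    adj_r2: float
    n: int
    n_predictors: int

    def __post_init__(self) -> None:
        expected = adjusted_r2(self.r2, self.n, self.n_predictors)
        assert abs(self.adj_r2 - expected) < 1e-10
        assert all(v >= 1.0 - 1e-9 for v in self.vif.values())


@dataclass
class PowerSpec:
    """Design inputs for a two-sided two-sample t-test sample size."""

    effect: float | None = None  # standardized difference d
    mean_difference: float | None = None
    sd: float | None = None
    alpha: float = 0.05
    power: float = 0.80
    dropout_fraction: float = 0.0

    def standardized_effect(self) -> float:
        if self.effect is not None:
            d = self.effect
        elif self.mean_difference is not None and self.sd:
            d = self.mean_difference / self.sd
        else:
            raise InputError("provide effect or (mean_difference, sd)")
        if d <= 0:
            raise InputError("effect size must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise InputError("alpha and power must be in (0, 1)")
        return d


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """``1 - (1 - R^2)(n - 1)/(n - p - 1)``."""
    if n - p - 1 <= 0:
        raise InputError("need n > p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def format_p(p: float) -> str:
    """Render a p-value the way clinical tables print it."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def normality_gate(groups: list, alpha: float = 0.05) -> str:
    """Route to 'parametric' or 'nonparametric' via per-group Shapiro-Wilk.

    Any group rejecting normality at ``alpha`` — or any degenerate
    (constant) group, for which the test is undefined — selects the
    nonparametric path.
    """
    if not groups:
        raise InputError("no groups")
    for g in groups:
        arr = np.asarray(g, dtype=float)
        if arr.size < 3:
            raise InputError("Shapiro-Wilk needs n >= 3 per group")
        if np.ptp(arr) == 0:
            log.info("degenerate (constant) sample; routing to nonparametric path")
            return "nonparametric"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(arr).pvalue < alpha:
                return "nonparametric"
    return "parametric"


def _two_sample(x, y, parametric: bool, equal_var: bool = False):
    if parametric:
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        return "t", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return "mannwhitney", float(res.statistic), float(res.pvalue)


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    groups: list | None = None,
    group_col: str = "group",
    alpha: float = 0.05,
    equal_var: bool = False,
    force: str | None = None,
) -> list[GroupComparison]:
    """Omnibus plus Bonferroni-corrected pairwise comparisons of one variable.

    Two groups use a t-test (Welch by default) or Mann-Whitney; more use
    one-way ANOVA or Kruskal-Wallis followed by pairwise post-hoc tests
    with the Bonferroni multiplier equal to the number of pairs tested.
    ``force`` overrides the Shapiro-Wilk gate ("parametric"/"nonparametric").
    """
    sub = table[[group_col, variable]].dropna()
    if groups is None:
        groups = sorted(sub[group_col].unique())
    samples = {g: sub.loc[sub[group_col] == g, variable].to_numpy(float) for g in groups}
    if len(samples) < 2 or any(s.size < 2 for s in samples.values()):
        raise InputError("need >=2 groups with >=2 subjects each")
    route = force or normality_gate(list(samples.values()), alpha=alpha)
    parametric = route == "parametric"

    out: list[GroupComparison] = []
    vals = [samples[g] for g in groups]
    if len(groups) == 2:
        name, statistic, p = _two_sample(vals[0], vals[1], parametric, equal_var)
        out.append(GroupComparison(name, statistic, p, min(1.0, p), tuple(groups)))
        return out

    if parametric:
        res = stats.f_oneway(*vals)
        out.append(GroupComparison("anova", float(res.statistic), float(res.pvalue), float(res.pvalue)))
    else:
        res = stats.kruskal(*vals)
        out.append(
            GroupComparison("kruskal-wallis", float(res.statistic), float(res.pvalue), float(res.pvalue))
        )
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    for a, b in pairs:
        name, statistic, p = _two_sample(samples[a], samples[b], parametric, equal_var)
        out.append(GroupComparison(name, statistic, p, min(1.0, p * m), (a, b)))
    return out


def univariable(table: pd.DataFrame, x: str, y: str) -> dict:
    """Simple OLS of y on x; reports Pearson R, two-sided p, slope, intercept."""
    sub = table[[x, y]].dropna()
    if len(sub) < 3:
        raise InputError("need >=3 complete pairs")
    xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
    if np.ptp(xv) == 0:
        raise InputError(f"zero-variance predictor: {x}")
    res = stats.linregress(xv, yv)
    return {
        "R": float(res.rvalue),
        "p": float(res.pvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n": int(len(sub)),
    }


def multiple_regression(table: pd.DataFrame, y: str, predictors: list[str]) -> RegressionResult:
    """OLS of y on several predictors with VIF diagnostics.

    VIF_j = 1/(1 - R^2_j) where R^2_j comes from regressing predictor j on
    the remaining predictors.  A rank-deficient design raises an explicit
    multicollinearity error rather than silently pseudo-inverting.
    """
    if not predictors:
        raise InputError("no predictors")
    sub = table[[y] + list(predictors)].dropna()
    n, p = len(sub), len(predictors)
    if n <= p + 1:
        raise InputError("need n > p + 1 observations")
    X = sm.add_constant(sub[list(predictors)].to_numpy(float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise MulticollinearityError("design matrix is rank deficient")
    fit = sm.OLS(sub[y].to_numpy(float), X).fit()

    vif: dict[str, float] = {}
    for j, name in enumerate(predictors):
        if p == 1:
            vif[name] = 1.0
            continue
        others = [q for q in predictors if q != name]
        Xa = sm.add_constant(sub[others].to_numpy(float), has_constant="add")
        r2_j = sm.OLS(sub[name].to_numpy(float), Xa).fit().rsquared
        vif[name] = 1.0 / (1.0 - r2_j) if r2_j < 1 else math.inf

    names = ["const"] + list(predictors)
    return RegressionResult(
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        vif=vif,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=n,
        n_predictors=p,
    )


def reduce_model(
    table: pd.DataFrame,
    y: str,
    predictors: list[str],
    univariable_r: dict,
) -> tuple[RegressionResult, str]:
    """Refit after dropping the predictor with the weakest univariable |R|.

    Ties drop the later-listed predictor (deterministic, logged).  Returns
    the reduced fit and the name of the dropped predictor.
    """
    if len(predictors) < 2:
        raise InputError("nothing to drop: need >=2 predictors")
    missing = [p for p in predictors if p not in univariable_r]
    if missing:
        raise InputError(f"missing univariable R for {missing}")
    low = min(abs(univariable_r[p]) for p in predictors)
    candidates = [p for p in predictors if abs(univariable_r[p]) == low]
    dropped = candidates[-1]
    if len(candidates) > 1:
        log.info("tie in |R|=%.3g; dropping later-listed predictor %r", low, dropped)
    kept = [p for p in predictors if p != dropped]
    return multiple_regression(table, y, kept), dropped


def _t_test_power(d: float, n: int, alpha: float) -> float:
    """Exact power of the two-sided two-sample t-test (pooled, equal n)."""
    df = 2 * n - 2
    nc = d * math.sqrt(n / 2.0)
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def sample_size_two_sample_t(spec: PowerSpec, n_groups: int = 2, n_max: int = 100000) -> dict:
    """Smallest per-group n achieving the target power, plus enrollment.

    Enrollment inflates n by the dropout fraction (ceiling), the classical
    design step that turned 7 evaluable into 8 enrolled per group here.
    """
    d = spec.standardized_effect()
    n = 2
    while n <= n_max and _t_test_power(d, n, spec.alpha) < spec.power:
        n += 1
    if n > n_max:
        raise InputError("no attainable n below n_max for this effect size")
    if not 0 <= spec.dropout_fraction < 1:
        raise InputError("dropout fraction must be in [0, 1)")
    enrolled = math.ceil(n / (1.0 - spec.dropout_fraction))
    return {
        "n_per_group": n,
        "achieved_power": _t_test_power(d, n, spec.alpha),
        "enrolled_per_group": enrolled,
        "enrolled_total": enrolled * n_groups,
    }
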