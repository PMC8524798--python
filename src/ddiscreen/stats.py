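"""Statistical layer: paired prevalence tests, trend test, group
comparisons, univariate screening and multivariable logistic models.

The analysis sequence mirrors standard pharmacoepidemiology practice for a
longitudinal prevalence study: McNemar's test compares paired DDI status
between admission and discharge; a Cochran-Armitage chi-squared test for
trend assesses the post-discharge trajectory; Mann-Whitney / Kruskal-Wallis
and chi-squared / Fisher tests compare groups descriptively; candidate risk
factors pass a univariate logistic screen at P < .15 before entering a
multivariable logistic model reported as odds ratios with Wald 95% CIs,
model AIC and the C-statistic.  No multiple-testing correction is applied;
p-values are reported as-is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "PairedBinary2x2",
    "TrendSeries",
    "RegressionResult",
    "mcnemar_test",
    "chi2_trend_test",
    "compare_groups",
    "univariate_screen",
    "check_collinearity",
    "fit_multivariable",
    "build_design_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedBinary2x2:
    """Paired binary status counts: n11 = positive at both assessments,
    n10 = positive at the first only, n01 at the second only, n00 at neither."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class TrendSeries:
    """Ordered (timepoint, n_with, n_total) triples for the trend test."""

    points: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("trend needs at least 2 timepoints")
        for tp, x, n in self.points:
            if not (0 <= x <= n):
                raise ValueError(f"{tp}: need 0 <= n_with <= n_total")


@dataclass
class RegressionResult:
    """Odds ratios, Wald CIs and model-level fit summaries."""

    table: pd.DataFrame  # variable, level, coef, or, ci_low, ci_high, p
    aic: float
    c_statistic: float
    c_ci: tuple[float, float] | None
    n: int
    converged: bool = True


def mcnemar_test(t: PairedBinary2x2, method: str = "auto") -> tuple[float, float]:
    """McNemar's test on the discordant pairs of a paired 2x2 table.

    method='auto' uses the exact binomial test when fewer than 25 discordant
    pairs are available and the continuity-corrected chi-square otherwise;
    'exact' and 'chi2' force a variant.  The returned statistic is the
    (uncorrected) chi-square on discordant counts when the exact method is
    used, so a symmetric table reports statistic 0, p = 1 under any method.
    With no discordant pairs at all the test is degenerate: p = 1 (warned).
    """
    if method not in ("auto", "exact", "chi2"):
        raise ValueError(f"unknown method {method!r}")
    d = t.n10 + t.n01
    if d == 0:
        warnings.warn("McNemar: no discordant pairs; p = 1", stacklevel=2)
        return 0.0, 1.0
    if method == "auto":
        method = "exact" if d < 25 else "chi2"
    table = [[t.n11, t.n10], [t.n01, t.n00]]
    if method == "exact":
        res = _sm_mcnemar(table, exact=True)
        stat = (t.n10 - t.n01) ** 2 / d
        return float(stat), float(res.pvalue)
    res = _sm_mcnemar(table, exact=False, correction=True)
    return float(res.statistic), float(res.pvalue)


def chi2_trend_test(
    s: TrendSeries, scores: list[float] | None = None
) -> tuple[float, float]:
    """Cochran-Armitage chi-squared test for trend in proportions (1 df).

    Scores default to equally spaced integers over the ordered timepoints;
    calendar-time scores may be supplied instead.  Degenerate series (all
    successes or none) return statistic 0, p = 1.
    """
    pts = [(tp, x, n) for tp, x, n in s.points if n > 0]
    if len(pts) < 2:
        raise ValueError("trend needs >=2 timepoints with n_total > 0")
    x = np.array([p[1] for p in pts], dtype=float)
    n = np.array([p[2] for p in pts], dtype=float)
    if scores is None:
        sc = np.arange(len(pts), dtype=float)
    else:
        if len(scores) != len(s.points):
            raise ValueError("scores must match the number of timepoints")
        sc = np.array(
            [scores[i] for i, (tp, _, nn) in enumerate(s.points) if nn > 0],
            dtype=float,
        )
    N, X = n.sum(), x.sum()
    pbar = X / N
    if pbar in (0.0, 1.0):
        return 0.0, 1.0
    t_stat = float(np.sum(sc * (x - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * sc**2) - np.sum(n * sc) ** 2 / N)
    if var <= 0:
        return 0.0, 1.0
    chi2 = t_stat**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def compare_groups(values, groups, kind: str = "auto") -> float:
    """Dispatching two-sided group comparison; returns the p-value.

    Continuous data: Mann-Whitney U for two groups, Kruskal-Wallis beyond.
    Categorical data: Pearson chi-square, switching to Fisher's exact test
    for 2x2 tables whenever an expected cell is 5 or smaller.
    """
    values = pd.Series(values).reset_index(drop=True)
    groups = pd.Series(groups).reset_index(drop=True)
    levels = sorted(groups.dropna().unique(), key=str)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if kind == "auto":
        kind = "continuous" if pd.api.types.is_numeric_dtype(values) and values.nunique() > 6 else "categorical"
    if kind == "continuous":
        samples = [values[groups == g].dropna().to_numpy() for g in levels]
        if len(levels) == 2:
            return float(sps.mannwhitneyu(samples[0], samples[1],
                                          alternative="two-sided").pvalue)
        return float(sps.kruskal(*samples).pvalue)
    table = pd.crosstab(values, groups).to_numpy()
    expected = sps.contingency.expected_freq(table)
    if table.shape == (2, 2) and (expected <= 5).any():
        return float(sps.fisher_exact(table)[1])
    return float(sps.chi2_contingency(table, correction=False)[1])


# --- design matrices -------------------------------------------------------

#: Dummy-coding reference levels for the cohort's multi-level covariates.
DEFAULT_REFERENCES = {
    "age_group": "70-79",
    "sex": "female",
    "site": "Bern",
    "arm": "intervention",
    "admission_type": "elective",
    "admission_reason": "surgical",
}


def build_design_matrix(
    covariates: pd.DataFrame,
    references: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a covariate table into a numeric design matrix.

    Numeric and boolean columns pass through; multi-level columns are
    dummy-coded against a reference level (from *references*, defaulting to
    the alphabetically first level).  Returns the matrix together with a map
    of design columns to (variable, level) labels.
    """
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    cols, meta = {}, []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_bool_dtype(col):
            cols[name] = col.astype(float)
            meta.append({"column": name, "variable": name, "level": ""})
        elif pd.api.types.is_numeric_dtype(col):
            cols[name] = col.astype(float)
            meta.append({"column": name, "variable": name, "level": ""})
        else:
            levels = sorted(col.astype(str).unique())
            ref = refs.get(name, levels[0])
            if ref not in levels:
                ref = levels[0]
            for lv in levels:
                if lv == ref:
                    continue
                dummy = f"{name}[{lv}]"
                cols[dummy] = (col.astype(str) == lv).astype(float)
                meta.append({"column": dummy, "variable": name, "level": lv})
    return pd.DataFrame(cols, index=covariates.index), pd.DataFrame(meta)


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(disp=False, maxiter=100)


def univariate_screen(
    covariates: pd.DataFrame,
    outcome,
    alpha: float = 0.15,
    references: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Single-covariate logistic screen; keep variables with P < alpha.

    Multi-level variables are tested jointly with a likelihood-ratio test.
    Single-level (constant) covariates are skipped with a warning.  Returns a
    DataFrame (variable, p_value, selected, note).
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is degenerate (single level)")
    rows = []
    for name in covariates.columns:
        col = covariates[[name]]
        if col[name].nunique(dropna=True) < 2:
            warnings.warn(f"covariate {name!r} has a single level; skipped",
                          stacklevel=2)
            rows.append({"variable": name, "p_value": np.nan,
                         "selected": False, "note": "skipped: single level"})
            continue
        X, _ = build_design_matrix(col, references)
        try:
            fit = _fit_logit(X, y)
            null = _fit_logit(pd.DataFrame(index=X.index), y)
            lr = 2 * (fit.llf - null.llf)
            p = float(sps.chi2.sf(lr, df=X.shape[1]))
        except Exception as exc:  # separation, non-convergence
            warnings.warn(f"covariate {name!r}: fit failed ({exc}); skipped",
                          stacklevel=2)
            rows.append({"variable": name, "p_value": np.nan,
                         "selected": False, "note": f"skipped: {exc}"})
            continue
        rows.append({"variable": name, "p_value": p,
                     "selected": bool(p < alpha), "note": ""})
    return pd.DataFrame(rows)


def check_collinearity(
    covariates: pd.DataFrame, threshold: float = 0.7
) -> pd.DataFrame:
    """Flag covariate pairs with |correlation| above *threshold*.

    Pearson's r between quantitative variables; the Phi coefficient (Pearson
    on 0/1 indicators) between binary variables; point-biserial for mixed
    pairs.  Resolution of flagged pairs is a clinical judgement and is left
    to the analyst.
    """
    X, meta = build_design_matrix(covariates)
    names = list(X.columns)
    rows = []
    arr = X.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    is_binary = [set(np.unique(arr[:, i])) <= {0.0, 1.0} for i in range(arr.shape[1])]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = corr[i, j]
            if np.isnan(r) or abs(r) < threshold:
                continue
            kind = ("phi" if is_binary[i] and is_binary[j]
                    else "pearson" if not is_binary[i] and not is_binary[j]
                    else "point_biserial")
            rows.append({"var1": names[i], "var2": names[j],
                         "coefficient": float(r), "kind": kind})
    return pd.DataFrame(rows, columns=["var1", "var2", "coefficient", "kind"])


def _auc(y: np.ndarray, score: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity."""
    pos = score[y == 1]
    neg = score[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return np.nan
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


class SeparationError(RuntimeError):
    """Perfect separation: some covariate predicts the outcome exactly."""


def fit_multivariable(
    covariates: pd.DataFrame,
    outcome,
    references: dict[str, str] | None = None,
    c_ci: str | None = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> RegressionResult:
    """Maximum-likelihood multivariable logistic regression.

    Reports per-level odds ratios with Wald 95% CIs and p-values, model AIC
    and the C-statistic (AUC of the fitted probabilities), with a seeded
    bootstrap CI (*c_ci*='bootstrap', default 2000 replicates) or none.
    Fewer than 10 events per fitted parameter triggers a warning; perfect
    separation raises :class:`SeparationError` naming the offending
    covariate where it can be identified.
    """
    y = np.asarray(outcome, dtype=float)
    X, meta = build_design_matrix(covariates, references)
    n_events = int(min(y.sum(), (1 - y).sum()))
    if X.shape[1] > 0 and n_events / X.shape[1] < 10:
        warnings.warn(
            f"only {n_events} events for {X.shape[1]} parameters "
            "(<10 events per variable)", stacklevel=2)
    try:
        fit = _fit_logit(X, y)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", True) or np.any(np.abs(fit.params) > 15):
        offenders = [c for c, b in zip(fit.params.index, fit.params) if abs(b) > 15]
        if offenders:
            raise SeparationError(
                f"perfect or quasi-perfect separation; diverging coefficient(s): {offenders}"
            )
        raise RuntimeError(f"logistic fit did not converge: {fit.mle_retvals}")

    ci = fit.conf_int()
    rows = []
    for _, m in meta.iterrows():
        c = m["column"]
        rows.append(
            {
                "variable": m["variable"],
                "level": m["level"],
                "coef": float(fit.params[c]),
                "or": float(np.exp(fit.params[c])),
                "ci_low": float(np.exp(ci.loc[c, 0])),
                "ci_high": float(np.exp(ci.loc[c, 1])),
                "p": float(fit.pvalues[c]),
            }
        )
    table = pd.DataFrame(rows)

    score = np.asarray(fit.predict())
    c_stat = _auc(y, score)
    c_interval = None
    if c_ci == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = np.arange(len(y))
        boots = []
        for _ in range(n_boot):
            b = rng.choice(idx, size=len(idx), replace=True)
            a = _auc(y[b], score[b])
            if not np.isnan(a):
                boots.append(a)
        c_interval = (float(np.quantile(boots, 0.025)),
                      float(np.quantile(boots, 0.975)))
    return RegressionResult(
        table=table,
        aic=float(fit.aic),
        c_statistic=c_stat,
        c_ci=c_interval,
        n=int(len(y)),
        converged=bool(fit.mle_retvals.get("converged", True)),
    )
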