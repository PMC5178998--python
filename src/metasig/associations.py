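"""The evaluation battery around the signature.

ANOVA contrasts of expression by sample status, univariate and multivariate
logistic regression for treatment response (pCR), Kaplan-Meier / log-rank /
Cox proportional-hazards survival analysis, and lymphocyte-infiltration
correlations.  Standard fits go through statsmodels (logistic), lifelines
(Kaplan-Meier, log-rank, Cox with Efron ties) and scipy (ANOVA, Pearson);
this module owns the cohort assembly, reference-level conventions,
complete-case handling, separation detection and the p < 0.10 univariate
inclusion rule for the multivariate models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .containers import MetageneMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "anova_by_status",
    "fit_logistic",
    "build_multivariate",
    "km_logrank",
    "fit_cox",
    "til_correlation",
    "results_table",
]

#: Coefficients beyond this magnitude on the logit/log-hazard scale are
#: treated as evidence of separation / monotone likelihood.
SEPARATION_COEF = 15.0

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class AssociationResult:
    """One fitted term: effect estimate with Wald 95% CI and p-value.

    ``estimate`` is an odds ratio (logistic), hazard ratio (cox), F
    statistic (anova) or correlation coefficient (pearson).  ``covariate``
    groups the levels of a categorical covariate; ``term`` names the
    non-reference level.  Non-estimable terms (separation, monotone
    likelihood) carry NaN estimates and ``estimable=False``.
    """

    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    model: str
    covariate: str = ""
    estimable: bool = True
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not self.covariate:
            self.covariate = self.term


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten results to the (term, n, estimate, ci, p, model) table layout."""
    return pd.DataFrame(
        [
            {
                "covariate": r.covariate,
                "term": r.term,
                "n": r.n,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "model": r.model,
                "estimable": r.estimable,
            }
            for r in results
        ]
    )


def anova_by_status(values, status, term: str = "status") -> AssociationResult:
    """One-way ANOVA of a continuous variable across status groups.

    Groups with all-equal values in every group (zero within-group
    variance) are degenerate: p is reported as 0 when group means differ
    and 1 when they coincide.
    """
    df = pd.DataFrame({"v": np.asarray(values, dtype=float), "g": list(status)}).dropna()
    groups = [sub["v"].to_numpy() for _, sub in df.groupby("g", sort=True)]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    for (name, sub) in df.groupby("g", sort=True):
        if len(sub) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 observations")
    means = {name: float(sub["v"].mean()) for name, sub in df.groupby("g", sort=True)}
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within == 0:
        distinct = len({round(m, 12) for m in means.values()}) > 1
        f, p = (np.inf, 0.0) if distinct else (np.nan, 1.0)
    else:
        f, p = stats.f_oneway(*groups)
    return AssociationResult(
        term=term,
        estimate=float(f),
        ci_low=np.nan,
        ci_high=np.nan,
        p=float(p),
        n=len(df),
        model="anova",
        extra={"group_means": means},
    )


def _design_from_table(design: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Expand covariates into 0/1 indicator columns against reference levels.

    The reference level of a categorical covariate is its first listed
    level (first occurrence order in the column); numeric columns pass
    through unchanged.
    """
    cols: dict[str, np.ndarray] = {}
    terms: list[tuple[str, str]] = []  # (covariate, term/column name)
    for name in design.columns:
        col = design[name]
        if pd.api.types.is_numeric_dtype(col) and col.dropna().nunique() > 2:
            cols[name] = col.to_numpy(dtype=float)
            terms.append((name, name))
            continue
        levels = [lv for lv in pd.unique(col.dropna())]
        if pd.api.types.is_numeric_dtype(col):
            levels = sorted(levels)
        if len(levels) < 2:
            raise ValidationError(f"covariate {name!r} has a single level")
        for lv in levels[1:]:
            tname = f"{name}={lv}"
            cols[tname] = (col == lv).astype(float).where(col.notna()).to_numpy()
            terms.append((name, tname))
    X = pd.DataFrame(cols, index=design.index)
    return X, terms


def fit_logistic(outcome, design: pd.DataFrame) -> list[AssociationResult]:
    """Maximum-likelihood logistic regression; one result per non-reference level.

    Complete-case rows only; odds ratios with Wald 95% CIs and p-values.
    Separated terms (|coefficient| > 15 on the logit scale, the signature
    of a level with no events) are reported as non-estimable.
    """
    import statsmodels.api as sm

    y = pd.Series(np.asarray(outcome, dtype=float), index=design.index)
    X, terms = _design_from_table(design)
    data = pd.concat([y.rename("_y"), X], axis=1).dropna()
    if data["_y"].nunique() < 2:
        raise ValidationError("outcome must have both classes")
    Xc = sm.add_constant(data.drop(columns="_y"), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(data["_y"], Xc).fit(disp=0, maxiter=200)
        except Exception:  # perfect separation raises in some statsmodels paths
            fit = sm.Logit(data["_y"], Xc).fit(
                disp=0, maxiter=500, method="bfgs", gtol=1e-6
            )
    results = []
    for covariate, tname in terms:
        coef = float(fit.params[tname])
        se = float(fit.bse[tname])
        estimable = abs(coef) <= SEPARATION_COEF and np.isfinite(se)
        if not estimable:
            logger.warning("term %s non-estimable (separation)", tname)
            results.append(
                AssociationResult(
                    term=tname,
                    estimate=np.nan,
                    ci_low=np.nan,
                    ci_high=np.nan,
                    p=np.nan,
                    n=len(data),
                    model="logistic",
                    covariate=covariate,
                    estimable=False,
                )
            )
            continue
        results.append(
            AssociationResult(
                term=tname,
                estimate=float(np.exp(coef)),
                ci_low=float(np.exp(coef - Z975 * se)),
                ci_high=float(np.exp(coef + Z975 * se)),
                p=float(fit.pvalues[tname]),
                n=len(data),
                model="logistic",
                covariate=covariate,
            )
        )
    return results


def univariate_screen(
    outcome_fitter, design: pd.DataFrame
) -> dict[str, list[AssociationResult]]:
    """Fit each covariate alone; returns covariate -> its term results."""
    out: dict[str, list[AssociationResult]] = {}
    for name in design.columns:
        try:
            out[name] = outcome_fitter(design[[name]])
        except ValidationError as exc:
            logger.warning("univariate fit for %s failed: %s", name, exc)
            out[name] = []
    return out


def build_multivariate(
    univariate: dict[str, list[AssociationResult]] | list[AssociationResult],
    inclusion_p: float = 0.10,
) -> list[str]:
    """Covariates with any estimable univariate p strictly below the threshold.

    Input order is preserved; covariates whose every level is
    non-estimable are excluded.
    """
    if isinstance(univariate, list):
        grouped: dict[str, list[AssociationResult]] = {}
        for r in univariate:
            grouped.setdefault(r.covariate, []).append(r)
        univariate = grouped
    selected = []
    for covariate, results in univariate.items():
        ps = [r.p for r in results if r.estimable and np.isfinite(r.p)]
        if ps and min(ps) < inclusion_p:
            selected.append(covariate)
    return selected


def km_logrank(time, event, group) -> tuple[dict[str, pd.DataFrame], AssociationResult]:
    """Kaplan-Meier curves per group plus the log-rank comparison.

    Curves carry Greenwood 95% bands.  With zero events overall the
    curves are still returned and the test is reported as undefined
    (NaN statistic and p).
    """
    df = pd.DataFrame(
        {"t": np.asarray(time, float), "e": np.asarray(event, float), "g": list(group)}
    ).dropna()
    if df.empty or (df["g"].nunique() < 1):
        raise ValidationError("no usable observations")
    curves: dict[str, pd.DataFrame] = {}
    for name, sub in df.groupby("g", sort=True):
        km = KaplanMeierFitter()
        km.fit(sub["t"], sub["e"], label=str(name))
        curve = km.survival_function_.copy()
        curve.columns = ["survival"]
        ci = km.confidence_interval_
        curve["ci_low"] = ci.iloc[:, 0].to_numpy()
        curve["ci_high"] = ci.iloc[:, 1].to_numpy()
        curves[str(name)] = curve
    if df["e"].sum() == 0 or df["g"].nunique() < 2:
        test = AssociationResult(
            term="logrank",
            estimate=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            p=np.nan,
            n=len(df),
            model="logrank",
            estimable=False,
        )
        return curves, test
    lr = multivariate_logrank_test(df["t"], df["g"], df["e"])
    test = AssociationResult(
        term="logrank",
        estimate=float(lr.test_statistic),
        ci_low=np.nan,
        ci_high=np.nan,
        p=float(lr.p_value),
        n=len(df),
        model="logrank",
    )
    return curves, test


def fit_cox(time, event, design: pd.DataFrame) -> list[AssociationResult]:
    """Cox proportional-hazards fit (Efron ties); one result per term.

    Complete-case rows; hazard ratios with Wald 95% CIs.  Monotone
    likelihood (e.g. a level with no events) is reported as a
    non-estimable term.
    """
    X, terms = _design_from_table(design)
    df = pd.concat(
        [
            pd.Series(np.asarray(time, float), index=design.index, name="_t"),
            pd.Series(np.asarray(event, float), index=design.index, name="_e"),
            X,
        ],
        axis=1,
    ).dropna()
    if df["_e"].sum() < 1:
        raise ValidationError("need at least one event")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="_t", event_col="_e")
            summary = cph.summary
        except Exception as exc:
            logger.warning("Cox fit failed (%s); reporting terms as non-estimable", exc)
            return [
                AssociationResult(
                    term=t,
                    estimate=np.nan,
                    ci_low=np.nan,
                    ci_high=np.nan,
                    p=np.nan,
                    n=len(df),
                    model="cox",
                    covariate=c,
                    estimable=False,
                )
                for c, t in terms
            ]
    results = []
    for covariate, tname in terms:
        coef = float(summary.loc[tname, "coef"])
        se = float(summary.loc[tname, "se(coef)"])
        estimable = abs(coef) <= SEPARATION_COEF and np.isfinite(se) and se < 1e3
        results.append(
            AssociationResult(
                term=tname,
                estimate=float(np.exp(coef)) if estimable else np.nan,
                ci_low=float(np.exp(coef - Z975 * se)) if estimable else np.nan,
                ci_high=float(np.exp(coef + Z975 * se)) if estimable else np.nan,
                p=float(summary.loc[tname, "p"]) if estimable else np.nan,
                n=len(df),
                model="cox",
                covariate=covariate,
                estimable=estimable,
            )
        )
        if not estimable:
            logger.warning("Cox term %s non-estimable (monotone likelihood)", tname)
    return results


def til_correlation(
    mm: MetageneMatrix,
    clinical: pd.DataFrame,
    which: str = "intratumoral",
    metagene: str | None = None,
) -> tuple[AssociationResult, AssociationResult]:
    """Lymphocyte infiltration versus a metagene score.

    Returns (Pearson correlation of score vs TIL percentage, ANOVA of the
    TIL percentage by the metagene's high/low status).  ``metagene``
    defaults to the first cluster row.
    """
    if which not in ("intratumoral", "stromal"):
        raise ValidationError(f"unknown TIL compartment {which!r}")
    col = f"til_{which}_pct"
    if col not in clinical.columns:
        raise ValidationError(f"clinical table lacks {col}")
    label = metagene or mm.cluster_labels[0]
    scores = mm.scores.loc[label]
    shared = scores.index.intersection(clinical.index)
    df = pd.DataFrame(
        {"score": scores.reindex(shared), "til": clinical.loc[shared, col]}
    ).dropna()
    if len(df) < 3:
        raise ValidationError("need at least 3 paired score/TIL observations")
    r, p = stats.pearsonr(df["score"], df["til"])
    corr = AssociationResult(
        term=f"{label}~til_{which}",
        estimate=float(r),
        ci_low=np.nan,
        ci_high=np.nan,
        p=float(p),
        n=len(df),
        model="pearson",
    )
    if mm.status is None:
        raise ValidationError("metagene status not computed; dichotomize first")
    status = mm.status.loc[label].reindex(df.index)
    anova = anova_by_status(df["til"], status, term=f"til_{which}_by_{label}_status")
    return corr, anova
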