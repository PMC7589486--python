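"""Cohort-level statistics for the densitometry study design.

Covers the full downstream analysis applied to the per-eye table: two-group
comparisons (Mann-Whitney U for numeric variables, Pearson chi-square for
categorical ones), Pearson correlations between clinical covariates and the
zonal densities, univariate-then-multivariate binary logistic regression for
anti-VEGF treatment response, an ROC whose optimal cutoff maximises the
Youden index J = sensitivity + specificity - 1, and the a-priori two-sample
sample size from noncentral-t power (the G*Power computation).

Standard tests are delegated to scipy/statsmodels; the ROC (with its
explicit tie-break and its U-statistic identity) and the sample-size search
are implemented here because their exact conventions are part of the
contract.  No multiple-testing correction is applied anywhere — the source
analysis used none, and silently adding one would change every reported p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


# --------------------------------------------------------------------------
# two-group tests and correlation

def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (for sample ``a``) and two-sided p.

    Midranks handle ties.  With n_a * n_b <= 400 and no ties the p-value is
    the exact permutation tail; otherwise the tie-corrected normal
    approximation (with continuity correction) is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if a.size * b.size <= 400 else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square statistic and p for an r x k contingency table."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    expected = sps.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError("zero expected count; chi-square undefined")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def pearson_corr(x, y) -> tuple[float, float]:
    """Product-moment correlation R and its t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant sample")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# logistic regression

def logistic_fit(outcome, predictors: pd.DataFrame) -> pd.DataFrame:
    """Maximum-likelihood binary logistic fit with Wald tests.

    Returns one row per predictor with the coefficient, its exponential
    (the per-unit odds ratio) and the Wald p.  Perfect separation is
    reported as an informative error rather than a silent huge coefficient.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = sm.add_constant(pd.DataFrame(predictors).astype(float), has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise ValueError(f"logistic fit failed (likely separation): {exc}") from exc
    slopes = fit.params.drop(index="const")
    if not fit.mle_retvals.get("converged", True) or np.any(np.abs(slopes) > 30):
        raise ValueError("logistic fit did not converge; predictors may perfectly "
                         "separate the outcome")
    rows = pd.DataFrame({
        "coef": fit.params, "odds_ratio": np.exp(fit.params),
        "p": fit.pvalues,
    })
    return rows.drop(index="const")


def responder_analysis(cohort: pd.DataFrame, candidates: list[str],
                       outcome_col: str = "responder", positive: str = "poor",
                       alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Univariate logistic screens, then a multivariate fit on the p < alpha set.

    Mirrors the study's entry rule: every candidate is fitted alone; those
    reaching univariate p < alpha enter one joint model.  Returns
    ``{"univariate": ..., "multivariate": ...}`` frames (the multivariate
    frame is empty when no candidate qualifies).
    """
    sub = cohort[cohort[outcome_col].isin(["good", "poor"])]
    y = (sub[outcome_col] == positive).astype(float)
    uni = []
    for name in candidates:
        row = logistic_fit(y, sub[[name]]).loc[name]
        uni.append(row.rename(name))
    univariate = pd.DataFrame(uni)
    selected = univariate.index[univariate["p"] < alpha].tolist()
    multivariate = (logistic_fit(y, sub[selected]) if selected
                    else pd.DataFrame(columns=["coef", "odds_ratio", "p"]))
    return {"univariate": univariate, "multivariate": multivariate, "selected": selected}


# --------------------------------------------------------------------------
# ROC / Youden

def youden(sens: float, spec: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sens + spec - 1.0


@dataclass(frozen=True)
class ROCResult:
    """ROC over every distinct-score cutoff, with the Youden-optimal point.

    A case is called positive when its score is >= the cutoff; higher scores
    vote for the positive class.  ``optimal_cutoff`` is the lowest cutoff
    among the J maximisers; all maximisers are kept in ``optimal_cutoffs``.
    """

    auc: float
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    optimal_cutoff: float
    optimal_sens: float
    optimal_spec: float
    optimal_j: float
    optimal_cutoffs: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def j(self) -> np.ndarray:
        return self.sens + self.spec - 1.0


def roc_with_cutoff(scores, labels) -> ROCResult:
    """ROC from all distinct-score cutoffs, trapezoid AUC, Youden-optimal cutoff.

    The trapezoid AUC equals the Mann-Whitney identity
    U / (n_pos * n_neg) with midrank ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    cuts = np.unique(scores)                      # ascending candidate cutoffs
    # sens(t) = P(score >= t | pos); spec(t) = P(score < t | neg)
    sens = np.array([(scores[labels] >= t).mean() for t in cuts])
    spec = np.array([(scores[~labels] < t).mean() for t in cuts])
    j = sens + spec - 1.0

    # trapezoid over the full curve including the (0,0) and (1,1) anchors
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])[::-1]
    tpr = np.concatenate([[1.0], sens, [0.0]])[::-1]
    auc = float(np.trapezoid(tpr, fpr))

    best = np.flatnonzero(np.isclose(j, j.max(), atol=1e-12))
    opt = int(best[0])                            # lowest cutoff among maximisers
    return ROCResult(auc=auc, thresholds=cuts, sens=sens, spec=spec,
                     optimal_cutoff=float(cuts[opt]), optimal_sens=float(sens[opt]),
                     optimal_spec=float(spec[opt]), optimal_j=float(j[opt]),
                     optimal_cutoffs=cuts[best])


# --------------------------------------------------------------------------
# a-priori sample size

def two_sample_t_power(n_per_group: int, d: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test at equal n against Cohen's d.

    Exact noncentral-t computation: df = 2n - 2, noncentrality
    d * sqrt(n/2), rejection at the central-t two-sided critical value.
    """
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_two_group(d: float, alpha: float = 0.05, power: float = 0.80,
                          n_max: int = 1_000_000) -> int:
    """Smallest n per group giving the requested power (noncentral-t, two-sided).

    The normal approximation 2 (z_{1-a/2} + z_{1-b})^2 / d^2 undershoots by
    one subject at moderate effect sizes because it ignores the estimated
    variance; the noncentral-t search reproduces the G*Power answer.
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1) or not (0.5 < power < 1):
        raise ValueError("need 0 < alpha < 1 and 0.5 < power < 1")
    for n in range(2, n_max + 1):
        if two_sample_t_power(n, d, alpha) >= power:
            return n
    raise ValueError(f"power {power} unattainable with n <= {n_max} at d = {d}")


def sample_size_normal_approx(d: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Closed-form normal-approximation n per group, ceil(2 (z_a + z_b)^2 / d^2)."""
    za = sps.norm.ppf(1.0 - alpha / 2.0)
    zb = sps.norm.ppf(power)
    return int(np.ceil(2.0 * (za + zb) ** 2 / d**2))


# --------------------------------------------------------------------------
# table-style summaries

NUMERIC_COMPARISONS = ["age", "refractive_error", "bcva_logmar", "cmt_um", "sfct_um",
                       "haller_um", "inner_layer_um", "cvd_total", "cvd_mr", "cvd_npr",
                       "cvd_mpr", "cvd_fpr"]


def group_comparison(cohort: pd.DataFrame, group_col: str = "group",
                     groups: tuple[str, str] = ("PCV", "control"),
                     variables: list[str] | None = None) -> pd.DataFrame:
    """Mean +/- SD per group with Mann-Whitney p, one row per numeric variable."""
    variables = variables or [v for v in NUMERIC_COMPARISONS if v in cohort.columns]
    g1 = cohort[cohort[group_col] == groups[0]]
    g2 = cohort[cohort[group_col] == groups[1]]
    rows = []
    for var in variables:
        a, b = g1[var].dropna(), g2[var].dropna()
        u, p = mann_whitney(a, b)
        rows.append({"variable": var,
                     f"mean_{groups[0]}": a.mean(), f"sd_{groups[0]}": a.std(ddof=1),
                     f"mean_{groups[1]}": b.mean(), f"sd_{groups[1]}": b.std(ddof=1),
                     "U": u, "p": p})
    return pd.DataFrame(rows).set_index("variable")


def correlation_table(cohort: pd.DataFrame, covariates: list[str],
                      density_cols: list[str] | None = None) -> pd.DataFrame:
    """Pearson R (and p) of each covariate against each regional density."""
    density_cols = density_cols or ["cvd_total", "cvd_mr", "cvd_npr", "cvd_mpr", "cvd_fpr"]
    rows = {}
    for cov in covariates:
        row = {}
        for dens in density_cols:
            sub = cohort[[cov, dens]].dropna()
            r, p = pearson_corr(sub[cov], sub[dens])
            row[f"R_{dens}"] = r
            row[f"p_{dens}"] = p
        rows[cov] = row
    return pd.DataFrame.from_dict(rows, orient="index")
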