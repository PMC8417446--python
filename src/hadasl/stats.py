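"""Test-retest reliability, reproducibility, and association statistics.

Operates on tidy ROI tables (one row per subject x session x run x ROI):
within-subject coefficients of variation (wsCV) for two-run reliability,
two-way ANOVA intra-class correlations (ICC) with 95% confidence intervals
for between-scanner reproducibility, Shapiro-Wilk normality gating, one-way
ANOVA group tests, general-linear-model factor tests (scanner, age, gender),
and Pearson/partial CBF-ATT correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "IccEstimate",
    "CorrelationResult",
    "wscv",
    "icc_two_way",
    "normality_gate",
    "group_difference",
    "factor_effect",
    "att_cbf_correlation",
    "derived_contrasts",
    "exclude_unphysiological",
]


def wscv(run1, run2, sqrt: bool = True) -> float:
    """Within-subject coefficient of variation across two runs, in percent.

    Per subject ``i`` the two-point within-subject variance is
    ``wsVar_i = (x1_i - x2_i)^2 / 2`` and the mean ``(x1_i + x2_i) / 2``;
    the wsCV is ``100 * sqrt(mean_i(wsVar_i / wsMean_i^2))``.  Scale
    invariant, and zero iff the runs are identical.  ``sqrt=False`` returns
    the squared (variance-scale) variant, ``100 * mean(wsVar / wsMean^2)``.
    """
    x1 = np.asarray(run1, dtype=float)
    x2 = np.asarray(run2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("run1 and run2 must be paired 1-D arrays")
    if x1.size < 2:
        raise ValueError("need at least 2 subjects")
    ws_mean = 0.5 * (x1 + x2)
    if np.any(ws_mean <= 0):
        raise ValueError("within-subject means must be positive")
    ws_var = 0.5 * (x1 - x2) ** 2
    ratio = float(np.mean(ws_var / ws_mean**2))
    return 100.0 * np.sqrt(ratio) if sqrt else 100.0 * ratio


@dataclass(frozen=True)
class IccEstimate:
    """Intra-class correlation with its 95% CI and model descriptor."""

    icc: float
    ci_low: float
    ci_high: float
    model: str
    n: int

    def __post_init__(self):
        if not self.ci_low <= self.icc <= self.ci_high:
            raise ValueError("CI must bracket the estimate")


def icc_two_way(table, variant: str = "consistency",
                confidence: float = 0.95) -> IccEstimate:
    """Two-way mixed-effects, single-measures ICC of an n x 2 table.

    From the two-way ANOVA decomposition (subjects x measurements):
    ``consistency`` (ICC(3,1)) is ``(MS_subj - MS_err) / (MS_subj + MS_err)``
    for two measurements and is invariant to a constant offset between the
    measurements; ``absolute`` (ICC(A,1)) additionally charges the
    measurement-mean difference.  The CI follows the F-distribution
    convention for single measures.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("table must be subjects x measurements (>= 2 cols)")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance")
    ms_subj = k * np.var(x.mean(axis=1), ddof=1)
    ms_meas = n * np.var(x.mean(axis=0), ddof=1)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - (k - 1) * ms_meas - (n - 1) * ms_subj
    ms_err = ss_err / ((n - 1) * (k - 1))

    alpha = 1.0 - confidence
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if variant == "consistency":
        icc = (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)
        if ms_err <= 0:  # perfect consistency: degenerate CI at 1
            lo = hi = 1.0
        else:
            f_obs = ms_subj / ms_err
            fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    elif variant == "absolute":
        icc = (ms_subj - ms_err) / (
            ms_subj + (k - 1) * ms_err + k * (ms_meas - ms_err) / n
        )
        # Satterthwaite-style CI (McGraw & Wong convention for ICC(A,1))
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        v = (a * ms_meas + b * ms_err) ** 2 / (
            (a * ms_meas) ** 2 / (k - 1)
            + (b * ms_err) ** 2 / ((n - 1) * (k - 1))
        )
        f_star = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_star2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (ms_subj - f_star * ms_err) / (
            f_star * (k * ms_meas + (k * n - k - n) * ms_err) + n * ms_subj
        )
        hi = n * (f_star2 * ms_subj - ms_err) / (
            k * ms_meas + (k * n - k - n) * ms_err + n * f_star2 * ms_subj
        )
    else:
        raise ValueError("variant must be 'consistency' or 'absolute'")
    lo = min(lo, icc)
    hi = max(hi, icc)
    return IccEstimate(float(icc), float(lo), float(hi),
                       f"two-way mixed, single measures, {variant}", n)


def normality_gate(values, alpha: float = 0.05):
    """Shapiro-Wilk gate: ``(passed, p_value)``.

    Distributions failing the gate are flagged so downstream parametric
    results can carry a listed-for-completeness marker.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant input: normality test undefined")
    stat, p = sps.shapiro(x)
    return bool(p > alpha), float(p)


def group_difference(values, grouping):
    """One-way ANOVA across groups: ``(F, p)``."""
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    groups = [values[grouping == g] for g in np.unique(grouping)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def factor_effect(data: pd.DataFrame, response: str,
                  factors=("scanner", "age", "gender")) -> pd.DataFrame:
    """Per-factor F tests from a general linear model.

    Categorical factors (scanner, gender) and continuous covariates (age)
    enter an ordinary linear model; type-II F statistics are reported per
    factor.  Returns a DataFrame indexed by factor with ``F`` and ``p``.
    """
    terms = []
    for fac in factors:
        if fac not in data.columns:
            raise ValueError(f"column {fac!r} missing from data")
        is_cat = (data[fac].dtype == object
                  or isinstance(data[fac].dtype, pd.CategoricalDtype))
        terms.append(f"C({fac})" if is_cat else fac)
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    table = anova_lm(model, typ=2)
    out = []
    for fac, term in zip(factors, terms):
        out.append({
            "factor": fac,
            "F": float(table.loc[term, "F"]),
            "p": float(table.loc[term, "PR(>F)"]),
        })
    return pd.DataFrame(out).set_index("factor")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation, optionally adjusted for covariates."""

    r: float
    p: float
    r_partial: float | None
    p_partial: float | None
    covariates: tuple
    n: int

    def __post_init__(self):
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.r_partial is not None and abs(self.r_partial) > 1 + 1e-12:
            raise ValueError("|r_partial| must be <= 1")


def att_cbf_correlation(att, cbf, covariates: pd.DataFrame | None = None
                        ) -> CorrelationResult:
    """Pearson correlation of ATT with CBF, with optional covariates.

    The partial correlation residualizes both variables on the covariates
    (categorical columns are dummy-coded) and correlates the residuals.
    """
    att = np.asarray(att, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    if att.shape != cbf.shape or att.ndim != 1:
        raise ValueError("att and cbf must be paired 1-D arrays")
    n = att.size
    n_cov = 0 if covariates is None else covariates.shape[1]
    if n < 4 + n_cov:
        raise ValueError("too few observations for the requested model")
    if np.ptp(att) == 0 or np.ptp(cbf) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(att, cbf)
    r_part = p_part = None
    covs = ()
    if covariates is not None:
        covs = tuple(covariates.columns)
        x = pd.get_dummies(covariates, drop_first=True).astype(float)
        design = sm.add_constant(x.to_numpy())
        res_a = sm.OLS(att, design).fit().resid
        res_c = sm.OLS(cbf, design).fit().resid
        if np.ptp(res_a) == 0 or np.ptp(res_c) == 0:
            r_part, p_part = 0.0, 1.0
        else:
            r_part, p_part = sps.pearsonr(res_a, res_c)
            # p from the t distribution with df reduced by the covariates
            df = n - 2 - x.shape[1]
            if df > 0:
                t = r_part * np.sqrt(df / max(1 - r_part**2, 1e-300))
                p_part = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(
        float(r), float(p),
        None if r_part is None else float(r_part),
        None if p_part is None else float(p_part),
        covs, n,
    )


def derived_contrasts(roi_table: pd.DataFrame) -> pd.DataFrame:
    """Per-acquisition GM/WM contrasts: transit-time lag and CBF ratio.

    ``delta_att = ATT_WM - ATT_GM`` (the labeled bolus reaches white matter
    later) and ``cbf_ratio = CBF_GM / CBF_WM``, one row per subject x
    session x run.
    """
    keys = [c for c in ("subject", "session", "run", "scanner")
            if c in roi_table.columns]
    need = {"gray_matter", "white_matter"}
    if not need <= set(roi_table.roi.unique()):
        missing = need - set(roi_table.roi.unique())
        raise ValueError(f"missing tissue rows: {sorted(missing)}")
    wide = roi_table[roi_table.roi.isin(need)].pivot_table(
        index=keys or None, columns="roi",
        values=["cbf_ml_100g_min", "att_s"],
    )
    out = pd.DataFrame({
        "delta_att_s": wide[("att_s", "white_matter")]
        - wide[("att_s", "gray_matter")],
        "cbf_gm_wm_ratio": wide[("cbf_ml_100g_min", "gray_matter")]
        / wide[("cbf_ml_100g_min", "white_matter")],
    }).reset_index()
    return out


def exclude_unphysiological(roi_table: pd.DataFrame,
                            min_gm_cbf: float = 20.0):
    """Drop subjects whose GM CBF falls below a plausibility floor.

    Mirrors the handling of un-physiological low CBF values in test-retest
    analyses: any subject with a gray matter CBF below ``min_gm_cbf``
    (ml/100 g/min) in any run is excluded; returns ``(kept_table,
    excluded_subject_ids)``.
    """
    gm = roi_table[roi_table.roi == "gray_matter"]
    bad = sorted(gm.loc[gm.cbf_ml_100g_min < min_gm_cbf, "subject"].unique())
    kept = roi_table[~roi_table.subject.isin(bad)].copy()
    return kept, bad
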