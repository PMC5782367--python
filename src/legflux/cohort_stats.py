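"""Longitudinal cohort statistics for serially studied ICU patients.

Two complementary analyses per outcome variable:

* a nonparametric two-period comparison — observations from ICU days 10-20
  versus days 30-40, reduced to at most one observation per patient per
  comparison by the keep-last / keep-first selection rules, then a
  Mann-Whitney U test;
* a random-intercept linear mixed model over all observations,

      y_ij = beta0 + beta1 * day_ij + b_i + eps_ij,
      b_i ~ N(0, sigma_b^2),  eps_ij ~ N(0, sigma_e^2),

  fitted by REML, with a Wald test on the slope (t reference with
  df = n_obs - n_patients - 1 by default, matching the within-group df
  convention of nlme-style mixed-model software; a normal reference is
  available by configuration).

A sensitivity refit drops patients with any conditional residual beyond
±3 SD, and the day at which the fitted mean crosses zero is estimated as
-beta0/beta1 with a first-order delta-method standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .config import StatsConfig
from .errors import ConvergenceError, InsufficientDataError, ValidationError

EARLY = (10, 20)   # closed interval, ICU days
LATE = (30, 40)


# ---------------------------------------------------------------------------
# period comparison
# ---------------------------------------------------------------------------

def assign_periods(icu_day) -> pd.Series:
    """Label each observation 'early' (days 10-20), 'late' (30-40) or
    'neither'. Both intervals are closed."""
    day = pd.Series(icu_day)
    label = pd.Series("neither", index=day.index, dtype=object)
    label[(day >= EARLY[0]) & (day <= EARLY[1])] = "early"
    label[(day >= LATE[0]) & (day <= LATE[1])] = "late"
    return label


def select_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Reduce to at most one observation per patient per period comparison.

    A patient studied in both periods contributes only the last measurement
    (making the groups comparable in size); a patient studied twice within
    one period contributes the first of the two. Input needs columns
    patient_id, icu_day and period (from :func:`assign_periods`).
    """
    d = df[df["period"].isin(["early", "late"])].copy()
    kept = []
    for _, grp in d.groupby("patient_id", sort=False):
        if grp["period"].nunique() == 2:
            kept.append(grp.loc[[grp["icu_day"].idxmax()]])
        elif len(grp) > 1:
            kept.append(grp.loc[[grp["icu_day"].idxmin()]])
        else:
            kept.append(grp)
    return pd.concat(kept) if kept else d


@dataclass
class MannWhitneyResult:
    U: float
    p_value: float
    method: str          # "exact" | "asymptotic"
    degenerate: bool = False


def mann_whitney(group_a, group_b,
                 config: StatsConfig | None = None) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the combined sample is small (<= 12 by default)
    and untied; otherwise the tie-corrected normal approximation. All
    values tied across both groups gives p = 1 with a degenerate flag.
    """
    cfg = config or StatsConfig()
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return MannWhitneyResult(U=a.size * b.size / 2.0, p_value=1.0,
                                 method="degenerate", degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    if (a.size + b.size) <= cfg.exact_mw_max_n and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return MannWhitneyResult(U=float(res.statistic),
                                 p_value=float(res.pvalue), method="exact")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(U=float(res.statistic), p_value=float(res.pvalue),
                             method="asymptotic")


@dataclass
class PeriodComparisonResult:
    n_early: int
    n_late: int
    median_early: float
    median_late: float
    q1_early: float
    q3_early: float
    q1_late: float
    q3_late: float
    U: float
    p_value: float
    method: str


def compare_periods(df: pd.DataFrame, value_col: str,
                    config: StatsConfig | None = None) -> PeriodComparisonResult:
    """Early-vs-late comparison of one outcome after observation selection.

    ``df`` needs patient_id, icu_day and ``value_col`` columns; periods are
    assigned and the selection rules applied here.
    """
    d = df.dropna(subset=[value_col]).copy()
    d["period"] = assign_periods(d["icu_day"]).to_numpy()
    sel = select_observations(d)
    early = sel.loc[sel["period"] == "early", value_col].to_numpy(dtype=float)
    late = sel.loc[sel["period"] == "late", value_col].to_numpy(dtype=float)
    if early.size == 0 or late.size == 0:
        raise InsufficientDataError(
            f"period comparison for '{value_col}': a period has no observations")
    mw = mann_whitney(early, late, config)
    qe = np.percentile(early, [25, 50, 75])
    ql = np.percentile(late, [25, 50, 75])
    return PeriodComparisonResult(
        n_early=early.size, n_late=late.size,
        median_early=qe[1], median_late=ql[1],
        q1_early=qe[0], q3_early=qe[2], q1_late=ql[0], q3_late=ql[2],
        U=mw.U, p_value=mw.p_value, method=mw.method,
    )


# ---------------------------------------------------------------------------
# random-intercept mixed model
# ---------------------------------------------------------------------------

@dataclass
class CohortTrendResult:
    beta0: float
    beta1: float          # slope per ICU day
    se_beta1: float
    p_slope: float
    sigma_b: float        # random-intercept SD
    sigma_e: float        # residual SD
    n_obs: int
    n_patients: int
    df_resid: float       # df used by the slope test (inf for normal reference)
    cov_fixed: np.ndarray = field(repr=False, default=None)  # 2x2, (b0, b1)
    boundary: bool = False          # sigma_b estimated at (or numerically on) 0
    ranef: dict = field(repr=False, default_factory=dict)  # patient -> BLUP

    def ci_beta1(self, alpha: float = 0.05) -> tuple[float, float]:
        crit = (sps.norm.ppf(1 - alpha / 2) if np.isinf(self.df_resid)
                else sps.t.ppf(1 - alpha / 2, self.df_resid))
        return (self.beta1 - crit * self.se_beta1,
                self.beta1 + crit * self.se_beta1)


def _fe_covariance(X: np.ndarray, groups: np.ndarray, var_b: float,
                   var_e: float) -> np.ndarray:
    """(sum_i X_i' V_i^-1 X_i)^-1 with V_i = var_e*I + var_b*J per patient."""
    xtvx = np.zeros((X.shape[1], X.shape[1]))
    for g in np.unique(groups):
        Xi = X[groups == g]
        n_i = Xi.shape[0]
        # Woodbury: V^-1 = (I - J*var_b/(var_e + n_i*var_b)) / var_e
        shrink = var_b / (var_e + n_i * var_b)
        colsum = Xi.sum(axis=0)
        xtvx += (Xi.T @ Xi - shrink * np.outer(colsum, colsum)) / var_e
    return np.linalg.inv(xtvx)


def _slope_test(beta1, se, df_resid):
    if se == 0:
        return 0.0 if beta1 != 0 else 1.0
    t = beta1 / se
    if np.isinf(df_resid):
        return float(2 * sps.norm.sf(abs(t)))
    return float(2 * sps.t.sf(abs(t), df_resid))


def fit_random_intercept(df: pd.DataFrame, value_col: str,
                         day_col: str = "icu_day",
                         group_col: str = "patient_id",
                         config: StatsConfig | None = None,
                         ) -> CohortTrendResult:
    """REML fit of y ~ day with a per-patient random intercept."""
    cfg = config or StatsConfig()
    d = df.dropna(subset=[value_col]).copy()
    y = d[value_col].to_numpy(dtype=float)
    day = d[day_col].to_numpy(dtype=float)
    groups = d[group_col].to_numpy()
    n_obs, n_patients = y.size, len(np.unique(groups))
    if n_patients < 2:
        raise InsufficientDataError("need >= 2 patients for a mixed model")
    df_resid = (np.inf if cfg.slope_df == "normal"
                else max(n_obs - n_patients - 1, 1))

    X = sm.add_constant(day)
    # exact degenerate case: y is an exact linear function of day
    coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    scale_ref = max(float(np.var(y)), 1.0)
    if res_ss.size and float(res_ss[0]) <= 1e-12 * n_obs * scale_ref:
        b0, b1 = float(coef[0]), float(coef[1])
        return CohortTrendResult(
            beta0=b0, beta1=b1, se_beta1=0.0,
            p_slope=_slope_test(b1, 0.0, df_resid),
            sigma_b=0.0, sigma_e=0.0, n_obs=n_obs, n_patients=n_patients,
            df_resid=df_resid, cov_fixed=np.zeros((2, 2)), boundary=True,
            ranef={g: 0.0 for g in np.unique(groups)})

    model = MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = None
        last_exc: Exception | str | None = None
        for method in (None, "powell", "nm"):
            try:
                cand = (model.fit(reml=True) if method is None
                        else model.fit(reml=True, method=method))
            except Exception as exc:  # noqa: BLE001 - retry, then surface
                last_exc = exc
                continue
            if np.isfinite(cand.fe_params).all() and np.isfinite(cand.scale) \
                    and cand.scale > 0:
                fit = cand
                break
            last_exc = "estimates not finite"
        if fit is None:
            raise ConvergenceError(
                f"mixed model for '{value_col}' failed: {last_exc}")

    beta0, beta1 = float(fit.fe_params[0]), float(fit.fe_params[1])
    sigma_e = float(np.sqrt(fit.scale))
    var_b = max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)
    sigma_b = float(np.sqrt(var_b))
    boundary = var_b <= 1e-8 * fit.scale
    # GLS covariance of the fixed effects at the estimated variance
    # components, (sum_i X_i' V_i^-1 X_i)^-1 — well defined even when the
    # random-intercept variance sits on its boundary (where the full
    # Hessian-based covariance is not)
    cov = _fe_covariance(X, groups, var_b, float(fit.scale))
    se_b1 = float(np.sqrt(cov[1, 1]))
    ranef = {g: float(np.asarray(v)[0]) for g, v in fit.random_effects.items()}
    return CohortTrendResult(
        beta0=beta0, beta1=beta1, se_beta1=se_b1,
        p_slope=_slope_test(beta1, se_b1, df_resid),
        sigma_b=sigma_b, sigma_e=sigma_e,
        n_obs=n_obs, n_patients=n_patients, df_resid=df_resid,
        cov_fixed=cov, boundary=boundary, ranef=ranef)


# ---------------------------------------------------------------------------
# sensitivity refit and zero crossing
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    removed_patient_ids: tuple
    refit: CohortTrendResult
    conclusion_changed: bool   # significance at alpha flipped
    residual_sd: float


def conditional_residuals(fit: CohortTrendResult, df: pd.DataFrame,
                          value_col: str, day_col: str = "icu_day",
                          group_col: str = "patient_id") -> np.ndarray:
    """Within-patient residuals y - (beta0 + beta1*day + BLUP_i)."""
    d = df.dropna(subset=[value_col])
    pred = (fit.beta0 + fit.beta1 * d[day_col].to_numpy(dtype=float)
            + np.array([fit.ranef.get(g, 0.0) for g in d[group_col]]))
    return d[value_col].to_numpy(dtype=float) - pred


def sensitivity_refit(fit: CohortTrendResult, df: pd.DataFrame,
                      value_col: str, day_col: str = "icu_day",
                      group_col: str = "patient_id",
                      config: StatsConfig | None = None) -> SensitivityResult:
    """Drop patients with any |conditional residual| > 3 SD and refit.

    The residual SD comes from the original fit's conditional residuals.
    ``conclusion_changed`` records whether slope significance at the
    configured alpha flipped — the study's reported robustness check.
    """
    cfg = config or StatsConfig()
    d = df.dropna(subset=[value_col]).copy()
    resid = conditional_residuals(fit, d, value_col, day_col, group_col)
    sd = float(np.std(resid, ddof=1))
    if sd == 0.0:
        removed: list = []
    else:
        flag = np.abs(resid) > cfg.outlier_sd * sd
        removed = sorted(set(d.loc[flag, group_col]))
    kept = d[~d[group_col].isin(removed)]
    if kept[group_col].nunique() < 2:
        raise InsufficientDataError(
            "sensitivity refit removed too many patients to fit the model")
    if not removed:
        refit = fit
    else:
        refit = fit_random_intercept(kept, value_col, day_col, group_col, cfg)
    changed = (fit.p_slope < cfg.alpha) != (refit.p_slope < cfg.alpha)
    return SensitivityResult(removed_patient_ids=tuple(removed), refit=refit,
                             conclusion_changed=changed, residual_sd=sd)


@dataclass
class ZeroCrossingResult:
    day: float
    se: float
    undefined: bool = False


def zero_crossing_day(fit: CohortTrendResult,
                      slope_tol: float = 1e-12) -> ZeroCrossingResult:
    """ICU day at which the fitted mean outcome crosses zero.

    t0 = -beta0/beta1, with a first-order delta-method SE from the fixed-
    effect covariance: grad = (-1/beta1, beta0/beta1^2).
    """
    if abs(fit.beta1) <= slope_tol:
        return ZeroCrossingResult(day=np.nan, se=np.nan, undefined=True)
    t0 = -fit.beta0 / fit.beta1
    if fit.cov_fixed is None:
        return ZeroCrossingResult(day=float(t0), se=np.nan)
    g = np.array([-1.0 / fit.beta1, fit.beta0 / fit.beta1 ** 2])
    var = float(g @ fit.cov_fixed @ g)
    return ZeroCrossingResult(day=float(t0), se=float(np.sqrt(max(var, 0.0))))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment (optional multiplicity correction)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
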