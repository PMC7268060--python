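"""Two-stage longitudinal modeling.

Stage 1 fits a linear mixed-effects model ``erd ~ session`` with correlated
random intercept and slope per subject (restricted likelihood by default) and
extracts per-subject coefficients as fixed effect + conditional mode (BLUP).
Stage 2 regresses each subject's clinical change on those coefficients,
including their interaction; subgroup and laterality (pLC) regressions reuse
the same machinery.  Session indices are 0-based at the first chronological
session and are not renumbered after exclusions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)


@dataclass
class LmemFit:
    """Stage-1 mixed-model fit for one hemisphere/band."""

    beta0: float               # population initial ERD, %
    beta1: float               # population slope, %/session
    sd_b0: float
    sd_b1: float
    corr_b: float
    sigma: float               # residual SD
    llf: float
    reml: bool
    n_params: int              # fixed + covariance + residual parameters
    subjects: pd.DataFrame     # subject, intercept, slope (BLUP-based)
    hemisphere: str = ""
    band: str = ""
    converged: bool = True
    downgraded: str = ""       # "", "independent", or "ols_fallback"

    @property
    def fixed_effects(self) -> tuple[float, float]:
        return (self.beta0, self.beta1)


@dataclass
class Stage2Result:
    """Cross-sectional OLS of clinical change on trajectory coefficients."""

    coefficients: dict[str, float]
    fvalue: float
    df1: int
    df2: int
    pvalue: float
    r2: float
    adj_r2: float
    n: int
    coef_pvalues: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "F": self.fvalue, "df": [self.df1, self.df2],
            "p": self.pvalue, "r2": self.r2, "adj_r2": self.adj_r2,
            "n": self.n, "coef_pvalues": self.coef_pvalues,
        }


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    pvalue: float


def per_subject_ols(erd_df: pd.DataFrame) -> pd.DataFrame:
    """Independent per-subject OLS of erd_percent on session (test oracle)."""
    rows = []
    for subject, grp in erd_df.groupby("subject", sort=True):
        if grp.session.nunique() < 2:
            continue
        slope, intercept = np.polyfit(grp.session, grp.erd_percent, 1)
        rows.append(dict(subject=subject, intercept=intercept, slope=slope))
    return pd.DataFrame(rows)


def _subset(erd_df: pd.DataFrame, hemisphere: str | None,
            band: str | None) -> pd.DataFrame:
    df = erd_df
    if hemisphere is not None and "hemisphere" in df.columns:
        df = df[df.hemisphere == hemisphere]
    if band is not None and "band" in df.columns:
        df = df[df.band == band]
    return df.reset_index(drop=True)


def fit_stage1(erd_df: pd.DataFrame, hemisphere: str | None = None,
               band: str | None = None, *, reml: bool = True,
               correlated: bool = True,
               random_slopes: bool = True) -> LmemFit:
    """Fit ``erd_percent ~ session`` with per-subject random effects.

    Unequal session counts and spacing per subject are allowed.  A singular
    correlated random-effects covariance triggers a refit with independent
    random effects (logged as a downgrade); a degenerate (zero-variance)
    problem falls back to exact per-subject OLS aggregation.
    """
    df = _subset(erd_df, hemisphere, band)
    counts = df.groupby("subject").session.nunique()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 subjects with at least 2 sessions")

    endog = df.erd_percent.to_numpy(dtype=float)
    exog = sm.add_constant(df.session.to_numpy(dtype=float))
    groups = df.subject.to_numpy()
    exog_re = exog if random_slopes else exog[:, :1]

    def _ols_fallback() -> LmemFit:
        sub = per_subject_ols(df)
        resid = []
        for subject, grp in df.groupby("subject"):
            row = sub[sub.subject == subject]
            if row.empty:
                continue
            pred = row.intercept.iloc[0] + row.slope.iloc[0] * grp.session
            resid.extend(grp.erd_percent - pred)
        logger.warning("stage-1 mixed model degenerate; using per-subject OLS")
        return LmemFit(
            beta0=float(sub.intercept.mean()), beta1=float(sub.slope.mean()),
            sd_b0=float(sub.intercept.std(ddof=1)),
            sd_b1=float(sub.slope.std(ddof=1)),
            corr_b=float(np.nan), sigma=float(np.std(resid)),
            llf=float("nan"), reml=reml, n_params=6 if correlated else 5,
            subjects=sub, hemisphere=hemisphere or "", band=band or "",
            converged=False, downgraded="ols_fallback",
        )

    model = MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    free = None
    downgraded = ""
    if random_slopes and not correlated:
        free = MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2))
        downgraded = ""

    def _fit(free_params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            return model.fit(reml=reml, free=free_params,
                             method=["lbfgs", "powell"])

    try:
        res = _fit(free)
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
        return _ols_fallback()

    if random_slopes and correlated:
        eig = np.linalg.eigvalsh(res.cov_re)
        if np.min(eig) < 1e-8 * max(np.max(eig), 1e-12):
            logger.warning(
                "singular random-effects covariance; refitting with "
                "independent random effects")
            free = MixedLMParams.from_components(
                fe_params=np.ones(2), cov_re=np.eye(2))
            downgraded = "independent"
            try:
                res = _fit(free)
            except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
                return _ols_fallback()

    fe = np.asarray(res.fe_params, dtype=float)
    beta0, beta1 = float(fe[0]), float(fe[1] if len(fe) > 1 else 0.0)
    cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
    scale = float(res.scale)
    # statsmodels reports cov_re already on the response scale
    sd_b0 = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    if random_slopes and cov_re.shape[0] > 1:
        sd_b1 = float(np.sqrt(max(cov_re[1, 1], 0.0)))
        denom = sd_b0 * sd_b1
        corr_b = float(cov_re[0, 1] / denom) if denom > 0 else 0.0
    else:
        sd_b1, corr_b = 0.0, 0.0

    rows = []
    for subject, re_vals in res.random_effects.items():
        re_arr = np.asarray(re_vals, dtype=float)
        b0 = re_arr[0]
        b1 = re_arr[1] if random_slopes and re_arr.size > 1 else 0.0
        rows.append(dict(subject=subject, intercept=beta0 + b0,
                         slope=beta1 + b1))
    subjects = pd.DataFrame(rows).sort_values("subject").reset_index(drop=True)

    n_cov = 1 if not random_slopes else (3 if (correlated and not downgraded) else 2)
    return LmemFit(
        beta0=beta0, beta1=beta1, sd_b0=sd_b0, sd_b1=sd_b1, corr_b=corr_b,
        sigma=float(np.sqrt(scale)), llf=float(res.llf), reml=reml,
        n_params=2 + n_cov + 1, subjects=subjects,
        hemisphere=hemisphere or "", band=band or "",
        converged=bool(getattr(res, "converged", True)), downgraded=downgraded,
    )


def _ols_result(X: np.ndarray, y: np.ndarray, names: list[str]) -> Stage2Result:
    n, k = X.shape  # k includes the constant
    cond = np.linalg.cond(X)
    if cond > 1e10:
        warnings.warn(f"ill-conditioned design matrix (cond={cond:.3g})")
    res = sm.OLS(y, X).fit()
    df1, df2 = k - 1, n - k
    coeffs = dict(zip(names, map(float, res.params)))
    pvals = dict(zip(names, map(float, res.pvalues)))
    if np.allclose(np.std(y), 0):  # constant outcome: no variance to explain
        return Stage2Result(
            coefficients=coeffs, fvalue=0.0, df1=int(df1), df2=int(df2),
            pvalue=1.0, r2=0.0, adj_r2=0.0, n=int(n), coef_pvalues=pvals,
        )
    return Stage2Result(
        coefficients=coeffs, fvalue=float(res.fvalue), df1=int(df1),
        df2=int(df2), pvalue=float(res.f_pvalue), r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj), n=int(n), coef_pvalues=pvals,
    )


def _merge_outcomes(traj: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    merged = traj.merge(outcomes[["subject", "delta"]], on="subject", how="inner")
    if len(merged) < len(traj):
        missing = set(traj.subject) - set(merged.subject)
        raise ValueError(f"no outcome for subjects: {sorted(missing)}")
    return merged


def fit_stage2(trajectories: pd.DataFrame, outcomes: pd.DataFrame) -> Stage2Result:
    """OLS of delta on intercept, slope and their interaction (raw predictors)."""
    d = _merge_outcomes(trajectories, outcomes)
    n = len(d)
    if n <= 5:
        raise ValueError("stage 2 requires more than 5 subjects")
    I = d.intercept.to_numpy(dtype=float)
    S = d.slope.to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), I, S, I * S])
    return _ols_result(X, d.delta.to_numpy(dtype=float),
                       ["gamma0", "gamma1", "gamma2", "gamma3"])


def _simple_regression(x: np.ndarray, y: np.ndarray,
                       name: str) -> Stage2Result:
    x = np.asarray(x, dtype=float)
    if np.allclose(x.std(), 0):
        raise ValueError("degenerate design: predictor is constant")
    X = np.column_stack([np.ones(len(x)), x])
    return _ols_result(X, np.asarray(y, dtype=float), ["intercept", name])


def median_split(trajectories: pd.DataFrame, key: str = "intercept"):
    """Split subjects at the median of ``key`` into strong/weak initial-ERD groups.

    More negative ERD is *stronger*, so subjects below the median form the
    strong group.  Ties at the median are assigned deterministically in
    subject-id order to balance the split (logged).
    """
    if len(trajectories) < 4:
        raise ValueError("median split requires at least 4 subjects")
    d = trajectories.sort_values([key, "subject"]).reset_index(drop=True)
    n = len(d)
    m = float(d[key].median())
    n_strong = n // 2
    if (d[key] == m).sum() > 1 and (d[key] == m).iloc[n_strong - 1:n_strong + 1].any():
        logger.info("median tie at %g resolved by subject-id order", m)
    strong = d.iloc[:n_strong].reset_index(drop=True)
    weak = d.iloc[n_strong:].reset_index(drop=True)
    return strong, weak


def fit_subgroup_contralesional(subgroup: pd.DataFrame,
                                outcomes: pd.DataFrame) -> Stage2Result:
    """Simple regression of delta on the contralesional slope within a subgroup."""
    if len(subgroup) < 3:
        raise ValueError("subgroup regression requires at least 3 subjects")
    d = _merge_outcomes(subgroup, outcomes)
    return _simple_regression(d.slope.to_numpy(), d.delta.to_numpy(), "slope")


def compute_plc(trajectory_ipsi: pd.DataFrame,
                trajectory_contra: pd.DataFrame) -> pd.DataFrame:
    """Progressive laterality coefficient per subject: S_healthy - S_lesion.

    Positive values mean ipsilesional desynchronization grows faster (more
    negative slope) than contralesional.
    """
    ipsi = trajectory_ipsi.set_index("subject").slope
    contra = trajectory_contra.set_index("subject").slope
    common = ipsi.index.intersection(contra.index)
    missing = ipsi.index.symmetric_difference(contra.index)
    if len(missing):
        raise ValueError(
            f"missing hemisphere fit for subjects: {sorted(missing)}")
    plc = (contra.loc[common] - ipsi.loc[common]).rename("plc")
    return plc.reset_index().sort_values("subject").reset_index(drop=True)


def fit_plc_regression(plc: pd.DataFrame, outcomes: pd.DataFrame) -> Stage2Result:
    """Simple regression of delta on the progressive laterality coefficient."""
    if len(plc) < 3:
        raise ValueError("pLC regression requires at least 3 subjects")
    d = plc.merge(outcomes[["subject", "delta"]], on="subject", how="inner")
    return _simple_regression(d.plc.to_numpy(), d.delta.to_numpy(), "plc")


def lrt_compare(full: LmemFit, reduced: LmemFit) -> LRTResult:
    """Likelihood-ratio test between nested stage-1 fits."""
    if reduced.n_params > full.n_params:
        raise ValueError("reduced model has more parameters than the full model")
    if full.reml != reduced.reml:
        raise ValueError("models must be fitted with the same objective")
    if np.isnan(full.llf) or np.isnan(reduced.llf):
        raise ValueError("log-likelihood unavailable (degenerate fit)")
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = full.n_params - reduced.n_params
    p = float(stats.chi2.sf(chi2, df)) if df > 0 and chi2 > 0 else 1.0
    return LRTResult(chi2=float(chi2), df=int(df), pvalue=p)
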