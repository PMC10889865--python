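"""Per-parameter linear mixed models for the context effect.

One model per acoustic parameter: response = intercept + offset·[context ==
begging] + individual random intercept + residual. Handling is the reference
level, so the intercept is the handling mean and the offset the begging
shift. Because every individual occurs in exactly one context, random slopes
are inestimable and only random intercepts are fitted.

The fitter profiles the likelihood down to a one-dimensional search over the
variance ratio σ²_ind/σ²_res, which makes the parametric-bootstrap
likelihood-ratio test (the p-value the study design calls for, robust at
these group counts where asymptotic χ² is not) cheap enough to run at
hundreds of bootstraps per parameter. Estimates are REML by default;
likelihood-ratio comparisons always use ML refits.
"""
from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schema import ConfigError, DataError, PARAMETER_COLUMNS

logger = logging.getLogger(__name__)


def transform_entropy(values: Sequence[float]) -> np.ndarray:
    """Normalising transform for mean entropy: log(x + 1 - min(x)).

    The dataset minimum maps to 0; the map is strictly increasing and its
    log argument is >= 1 by construction.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("empty input")
    if not np.all(np.isfinite(v)):
        raise DataError("non-finite entropy values")
    return np.log(v + 1.0 - v.min())


@dataclass
class RandomInterceptFit:
    """A fitted random-intercept model."""

    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    sigma_individual: float
    sigma_residual: float
    loglik: float
    reml: bool
    exog_names: List[str]
    n_obs: int
    n_groups: int
    converged: bool
    residuals: np.ndarray = field(repr=False)
    scaled_residuals: np.ndarray = field(repr=False)
    _data: "_RIData" = field(repr=False, default=None)


class _RIData:
    """Sorted-by-group sufficient statistics for the profiled likelihood."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.y = np.asarray(y, float)[order]
        self.X = np.asarray(X, float)[order]
        codes = np.asarray(groups)[order]
        _, self.group_idx, self.ng = np.unique(codes, return_inverse=True,
                                               return_counts=True)
        self.n, self.p = self.X.shape
        self.m = self.ng.size
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        # per-group sums of columns of X and of y
        self.Sx = np.zeros((self.m, self.p))
        for j in range(self.p):
            self.Sx[:, j] = np.bincount(self.group_idx, weights=self.X[:, j])
        self.Sy = np.bincount(self.group_idx, weights=self.y)

    def profile(self, theta: float) -> Tuple[np.ndarray, float, float]:
        """GLS beta, whitened RSS and Σ log|V_g| at variance ratio theta."""
        cg = theta / (1.0 + theta * self.ng)
        A = self.XtX - (self.Sx * cg[:, None]).T @ self.Sx
        c = self.Xty - self.Sx.T @ (cg * self.Sy)
        beta = np.linalg.solve(A, c)
        yvy = self.yty - float(cg @ self.Sy**2)
        rss = max(yvy - float(beta @ c), 1e-300)
        logdet_v = float(np.sum(np.log1p(theta * self.ng)))
        return beta, rss, logdet_v

    def loglik(self, theta: float, reml: bool) -> float:
        beta, rss, logdet_v = self.profile(theta)
        if reml:
            dof = self.n - self.p
            sigma2 = rss / dof
            cg = theta / (1.0 + theta * self.ng)
            A = self.XtX - (self.Sx * cg[:, None]).T @ self.Sx
            _, logdet_a = np.linalg.slogdet(A)
            return -0.5 * (dof * math.log(2 * math.pi * sigma2) + logdet_v
                           + logdet_a - self.p * math.log(sigma2) + dof)
        sigma2 = rss / self.n
        return -0.5 * (self.n * math.log(2 * math.pi * sigma2) + logdet_v + self.n)

    def fit(self, reml: bool, exog_names: Optional[List[str]] = None
            ) -> RandomInterceptFit:
        if self.m < 2:
            raise DataError("need >= 2 groups (individuals)")

        def neg(u: float) -> float:
            return -self.loglik(math.exp(u), reml)

        res = optimize.minimize_scalar(neg, bounds=(-15.0, 15.0),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        cand = [(math.exp(res.x), -res.fun), (0.0, self.loglik(0.0, reml))]
        theta, ll = max(cand, key=lambda t: t[1])

        beta, rss, _ = self.profile(theta)
        dof = (self.n - self.p) if reml else self.n
        sigma2 = rss / dof
        cg = theta / (1.0 + theta * self.ng)
        A = self.XtX - (self.Sx * cg[:, None]).T @ self.Sx
        cov_beta = sigma2 * np.linalg.inv(A)
        se = np.sqrt(np.diag(cov_beta))
        resid = self.y - self.X @ beta
        sigma_e = math.sqrt(sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = resid / sigma_e if sigma_e > 0 else np.zeros_like(resid)
            tvals = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
        return RandomInterceptFit(
            beta=beta, se=se, tvalues=tvals,
            sigma_individual=math.sqrt(theta * sigma2),
            sigma_residual=sigma_e,
            loglik=float(ll), reml=reml,
            exog_names=exog_names or [f"x{j}" for j in range(self.p)],
            n_obs=self.n, n_groups=self.m,
            converged=bool(getattr(res, "success", True)),
            residuals=resid, scaled_residuals=scaled, _data=self,
        )

    def simulate(self, beta: np.ndarray, sigma_ind: float, sigma_res: float,
                 rng: np.random.Generator) -> np.ndarray:
        b = rng.normal(0.0, sigma_ind, size=self.m)
        e = rng.normal(0.0, sigma_res, size=self.n)
        return self.X @ beta + b[self.group_idx] + e


@dataclass
class LMMReport:
    parameter: str
    reference_context: str
    estimate_intercept: float
    estimate_offset: float
    se_intercept: float
    se_offset: float
    t_intercept: float
    t_offset: float
    sigma_individual: float
    sigma_residual: float
    scaled_residual_summary: Dict[str, float]
    p_bootstrap: Optional[float] = None
    n_boot: int = 0
    n_boot_failed: int = 0
    interpretation: str = ""
    transformed_response: bool = False

    def as_dict(self) -> Dict:
        return asdict(self)


def _design(features: pd.DataFrame, parameter: str, reference_context: str
            ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    if parameter not in features.columns:
        raise ConfigError(f"unknown parameter {parameter!r}")
    df = features.dropna(subset=[parameter])
    contexts = sorted(df["context"].unique())
    if len(contexts) != 2 or reference_context not in contexts:
        raise DataError(
            f"need two contexts incl. reference {reference_context!r}, "
            f"got {contexts}"
        )
    other = next(c for c in contexts if c != reference_context)
    per_ctx = df.groupby("context")["individual_id"].nunique()
    if per_ctx.min() < 2:
        raise DataError(f"need >= 2 individuals per context, got {dict(per_ctx)}")
    y = df[parameter].to_numpy(float)
    X = np.column_stack([np.ones(len(df)),
                         (df["context"] == other).to_numpy(float)])
    groups = df["individual_id"].to_numpy()
    return y, X, groups, other


def fit_context_lmm(
    features: pd.DataFrame,
    parameter: str,
    reference_context: str = "handling",
    reml: bool = True,
) -> Tuple[RandomInterceptFit, LMMReport]:
    """Fit the context model for one parameter and summarise it."""
    y, X, groups, other = _design(features, parameter, reference_context)
    data = _RIData(y, X, groups)
    fit = data.fit(reml=reml, exog_names=["intercept", f"context[{other}]"])
    q = np.percentile(fit.scaled_residuals, [0, 25, 50, 75, 100])
    report = LMMReport(
        parameter=parameter,
        reference_context=reference_context,
        estimate_intercept=float(fit.beta[0]),
        estimate_offset=float(fit.beta[1]),
        se_intercept=float(fit.se[0]),
        se_offset=float(fit.se[1]),
        t_intercept=float(fit.tvalues[0]),
        t_offset=float(fit.tvalues[1]),
        sigma_individual=fit.sigma_individual,
        sigma_residual=fit.sigma_residual,
        scaled_residual_summary={
            "min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "max": float(q[4]),
        },
    )
    return fit, report


def pb_modcomp(
    features: pd.DataFrame,
    parameter: str,
    reference_context: str = "handling",
    n_boot: int = 1000,
    seed: int = 0,
) -> Tuple[float, float, int]:
    """Parametric-bootstrap p-value for the context fixed effect.

    Observed statistic: LRT = 2(logLik_full − logLik_null), both ML, where
    the null model drops the context term. Each bootstrap simulates a
    response from the fitted null (its random-intercept and residual
    variances included), refits both models, and records the LRT;
    p = (1 + #{boot >= observed}) / (n_boot + 1). Returns (p, observed LRT,
    number of failed refits).
    """
    y, X, groups, _ = _design(features, parameter, reference_context)
    full_data = _RIData(y, X, groups)
    null_data = _RIData(y, X[:, :1], groups)
    ll_full = full_data.fit(reml=False).loglik
    null_fit = null_data.fit(reml=False)
    obs = max(0.0, 2.0 * (ll_full - null_fit.loglik))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    # bootstrap designs reuse the sorted layout of full_data
    null_sorted = _RIData(full_data.y, full_data.X[:, :1],
                          full_data.group_idx)
    n_ge, n_fail = 0, 0
    for _ in range(n_boot):
        ystar = null_sorted.simulate(null_fit.beta, null_fit.sigma_individual,
                                     null_fit.sigma_residual, rng)
        try:
            d_full = _RIData(ystar, full_data.X, full_data.group_idx)
            d_null = _RIData(ystar, full_data.X[:, :1], full_data.group_idx)
            lrt = 2.0 * (d_full.fit(reml=False).loglik
                         - d_null.fit(reml=False).loglik)
        except (np.linalg.LinAlgError, DataError, ValueError):
            n_fail += 1
            continue
        if lrt >= obs:
            n_ge += 1
    if n_fail > 0.1 * n_boot:
        raise DataError(f"{n_fail}/{n_boot} bootstrap refits failed")
    if n_fail:
        logger.warning("pb_modcomp(%s): %d bootstrap refits failed", parameter,
                       n_fail)
    n_ok = n_boot - n_fail
    p = (1.0 + n_ge) / (n_ok + 1.0)
    return float(p), float(obs), n_fail


@dataclass
class QQDiagnostic:
    theoretical_quantiles: np.ndarray
    ordered_residuals: np.ndarray
    correlation: float


def qq_residual_check(residuals: Sequence[float]) -> QQDiagnostic:
    """Normal Q-Q diagnostic: ordered residuals vs normal quantiles and
    their correlation. Purely descriptive, no automatic rejection."""
    r = np.asarray(residuals, float)
    if r.size < 3:
        raise DataError("insufficient residuals (need >= 3)")
    (theo, ordered), (_, _, corr) = stats.probplot(r, dist="norm")
    return QQDiagnostic(theoretical_quantiles=theo, ordered_residuals=ordered,
                        correlation=float(corr))


def _interpret(report: LMMReport, alpha: float = 0.05) -> str:
    if report.p_bootstrap is None or report.p_bootstrap >= alpha:
        return "no effect"
    # offset is the begging shift relative to the handling intercept
    if report.parameter == "spectral_slope_per_khz":
        return ("less steep during handling" if report.estimate_offset < 0
                else "steeper during handling")
    return ("increase during handling" if report.estimate_offset < 0
            else "decrease during handling")


def run_context_models(
    features: pd.DataFrame,
    parameters: Optional[Sequence[str]] = None,
    reference_context: str = "handling",
    n_boot: int = 1000,
    seed: int = 0,
) -> Dict[str, LMMReport]:
    """Fit the full battery of per-parameter context models.

    Mean entropy is the one transformed response (log(x + 1 - min(x)),
    applied over the whole dataset before fitting); all other parameters are
    modelled raw.
    """
    parameters = list(parameters or PARAMETER_COLUMNS)
    reports: Dict[str, LMMReport] = {}
    for i, param in enumerate(parameters):
        df = features
        transformed = param == "mean_entropy"
        if transformed:
            df = features.copy()
            df[param] = transform_entropy(df[param].to_numpy())
        _, report = fit_context_lmm(df, param, reference_context)
        report.transformed_response = transformed
        p, _, n_fail = pb_modcomp(df, param, reference_context, n_boot=n_boot,
                                  seed=seed + i)
        report.p_bootstrap = p
        report.n_boot = n_boot
        report.n_boot_failed = n_fail
        report.interpretation = _interpret(report)
        reports[param] = report
    return reports


def format_lmm_table(reports: Dict[str, LMMReport]) -> str:
    """Fixed-effect table, one block per parameter."""
    hdr = (f"{'Parameter':<24}{'begging':>10}{'handling':>10}"
           f"{'SE(b)':>8}{'SE(h)':>8}{'p(boot)':>9}  Interpretation")
    lines = [hdr]
    for name, r in reports.items():
        p = "NA" if r.p_bootstrap is None else f"{r.p_bootstrap:.4f}"
        label = name + ("*" if r.transformed_response else "")
        lines.append(
            f"{label:<24}{r.estimate_offset:>10.3f}{r.estimate_intercept:>10.3f}"
            f"{r.se_offset:>8.3f}{r.se_intercept:>8.3f}{p:>9}  {r.interpretation}"
        )
    lines.append("(* response transformed as log(x + 1 - min(x)))")
    return "\n".join(lines)
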