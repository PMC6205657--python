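"""Log-concentration probit (LC-P) bioassay analysis and cohort tests.

Mortality at concentration d is modelled as Phi(alpha + beta * log10 d):
a binomial GLM with probit link fitted by iteratively reweighted least
squares. Lethal concentrations are read off the fitted line,
LCq = 10^((Phi^-1(q) - alpha)/beta), with 95% confidence limits from
Fieller's theorem on the ratio (delta-method fallback when the Fieller
denominator is not positive, flagged in the result). Goodness of fit is
summarised by the Pearson heterogeneity chi-square over doses.

Strain-frequency changes between cohorts (e.g. before and after
insecticide selection) are tested with the two-proportion z-test using
the pooled variance — the "u-test" of classical entomological usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

Z95 = norm.ppf(0.975)


@dataclass
class LCPoint:
    """A lethal-concentration point estimate with 95% confidence limits."""

    quantile: float
    value: float
    ci_low: float
    ci_high: float
    method: str  # "fieller" or "delta"


@dataclass
class ProbitFit:
    """A fitted LC-P line.

    ``intercept``/``slope`` parameterise probit(mortality) =
    intercept + slope * log10(concentration) on the z scale (no +5
    offset). ``cov`` is the parameter covariance matrix.
    """

    intercept: float
    slope: float
    cov: np.ndarray = field(repr=False)
    lc50: LCPoint
    lc10: LCPoint
    lc90: LCPoint
    heterogeneity_chi2: float
    heterogeneity_df: int
    converged: bool
    n_doses: int

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "lc50": self.lc50.__dict__,
            "lc10": self.lc10.__dict__,
            "lc90": self.lc90.__dict__,
            "heterogeneity_chi2": self.heterogeneity_chi2,
            "heterogeneity_df": self.heterogeneity_df,
            "converged": self.converged,
            "n_doses": self.n_doses,
        }


def abbott_correction(mortality: np.ndarray, control_mortality: float) -> np.ndarray:
    """Abbott's correction for natural (control) mortality.

    Off by default in :func:`fit_probit`; apply to observed mortalities
    before fitting when a control cup shows background death.
    """
    if not 0 <= control_mortality < 1:
        raise ValueError("control_mortality must be in [0, 1)")
    return (np.asarray(mortality) - control_mortality) / (1 - control_mortality)


def fit_probit(records: pd.DataFrame) -> ProbitFit:
    """Fit the LC-P line by binomial ML probit regression.

    ``records`` has columns concentration, n, dead (replicates as
    separate rows are pooled per concentration for the heterogeneity
    chi-square but fitted as given). Requires at least two distinct
    concentrations and some partial mortality; a response jumping from
    0% straight to 100% carries no slope information (complete
    separation) and raises with advice to add intermediate doses.
    """
    df = records.copy()
    if (df["concentration"] <= 0).any():
        raise ValueError("concentrations must be > 0")
    by_dose = df.groupby("concentration", sort=True).agg(
        n=("n", "sum"), dead=("dead", "sum")
    )
    if len(by_dose) < 2:
        raise ValueError("need >= 2 distinct concentrations")
    pooled_mort = by_dose["dead"] / by_dose["n"]
    if ((pooled_mort <= 0) | (pooled_mort >= 1)).all():
        raise ValueError(
            "complete separation: every dose shows 0% or 100% mortality; "
            "add intermediate concentrations to estimate the slope"
        )
    x = np.log10(df["concentration"].to_numpy(dtype=float))
    exog = sm.add_constant(x)
    endog = np.column_stack(
        [df["dead"].to_numpy(dtype=float), (df["n"] - df["dead"]).to_numpy(dtype=float)]
    )
    model = sm.GLM(endog, exog, family=sm.families.Binomial(link=sm.families.links.Probit()))
    res = model.fit(maxiter=100, tol=1e-8)
    alpha, beta = res.params
    cov = np.asarray(res.cov_params())
    converged = bool(res.converged)

    # Pearson heterogeneity chi-square on per-dose pooled counts
    xd = np.log10(by_dose.index.to_numpy(dtype=float))
    p_hat = norm.cdf(alpha + beta * xd)
    n_d = by_dose["n"].to_numpy(dtype=float)
    obs = by_dose["dead"].to_numpy(dtype=float)
    exp = n_d * p_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_terms = (obs - exp) ** 2 / (n_d * p_hat * (1 - p_hat))
    chi2 = float(np.nansum(chi2_terms))
    dof = max(len(by_dose) - 2, 0)

    fit = ProbitFit(
        intercept=float(alpha),
        slope=float(beta),
        cov=cov,
        lc50=None,
        lc10=None,
        lc90=None,
        heterogeneity_chi2=chi2,
        heterogeneity_df=dof,
        converged=converged,
        n_doses=len(by_dose),
    )
    fit.lc50 = lc_point(fit, 0.5)
    fit.lc10 = lc_point(fit, 0.1)
    fit.lc90 = lc_point(fit, 0.9)
    return fit


def lc_point(fit: ProbitFit, q: float) -> LCPoint:
    """Lethal concentration for kill fraction ``q`` with 95% limits.

    LCq = 10^theta with theta = (Phi^-1(q) - alpha)/beta. The interval
    for theta comes from Fieller's theorem on the ratio
    (z_q - alpha)/beta using the fitted covariance; when the Fieller
    quadratic is degenerate (denominator not positive, i.e. the slope is
    not significantly nonzero) the delta method is used and flagged.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if fit.slope <= 0:
        raise ValueError("slope must be > 0 to invert the LC-P line")
    zq = norm.ppf(q)
    a = zq - fit.intercept  # numerator
    b = fit.slope
    v_aa = fit.cov[0, 0]            # Var(alpha) = Var(a)
    c_ab = -fit.cov[0, 1]           # Cov(a, b) = -Cov(alpha, beta)
    v_bb = fit.cov[1, 1]
    theta = a / b
    t = Z95
    # Fieller: roots of (b^2 - t^2 v_bb) th^2 - 2(ab - t^2 c_ab) th + (a^2 - t^2 v_aa) = 0
    A = b * b - t * t * v_bb
    B = -2 * (a * b - t * t * c_ab)
    C = a * a - t * t * v_aa
    disc = B * B - 4 * A * C
    if A > 0 and disc >= 0:
        r = np.sqrt(disc)
        lo = (-B - r) / (2 * A)
        hi = (-B + r) / (2 * A)
        method = "fieller"
    else:
        se = np.sqrt(
            (v_aa + 2 * theta * c_ab + theta * theta * v_bb)
        ) / abs(b)
        lo, hi = theta - t * se, theta + t * se
        method = "delta"
    return LCPoint(
        quantile=q,
        value=float(10**theta),
        ci_low=float(10**lo),
        ci_high=float(10**hi),
        method=method,
    )


@dataclass
class TestResult:
    """A two-proportion test outcome."""

    z: float
    p_value: float
    p1: float
    p2: float
    n1: int
    n2: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "z": self.z,
            "p_value": self.p_value,
            "p1": self.p1,
            "p2": self.p2,
            "n1": self.n1,
            "n2": self.n2,
            "degenerate": self.degenerate,
        }


def two_proportion_u_test(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled-variance two-proportion z-test ("u-test").

    z = (p1 - p2) / sqrt(pbar (1 - pbar) (1/n1 + 1/n2)) with the pooled
    proportion pbar = (x1 + x2)/(n1 + n2); two-sided P from the standard
    normal. When the pooled proportion is 0 or 1 the statistic is
    undefined: P = 1 is returned with the degenerate flag set.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be > 0")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        return TestResult(
            z=float("nan"), p_value=1.0, p1=p1, p2=p2, n1=n1, n2=n2, degenerate=True
        )
    se = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2 * norm.sf(abs(z))
    return TestResult(z=float(z), p_value=float(p), p1=p1, p2=p2, n1=n1, n2=n2)
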