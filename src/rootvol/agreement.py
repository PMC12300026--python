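"""Method-comparison statistics.

Everything needed to compare two volume (or measurement) series obtained on
the same cases by different methods: paired t-test, Pearson correlation,
Bland-Altman agreement limits, Kolmogorov-Smirnov normality (Lilliefors
corrected by default), post-hoc power and required sample size for the paired
t-test via the noncentral t distribution, and a conjugate Bayesian linear
regression for surface-predicts-volume checks.

Conventions: all tests two-sided, alpha 0.05 by default; Bland-Altman
differences are method A minus method B (put the candidate method first and
the reference second); effect size for power is Cohen's dz, the mean paired
difference divided by the SD of the differences.  p-values are returned in
full precision — formatting as "p < x" is a display concern.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .errors import EstimationError, InputError

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "PairedTResult",
    "BlandAltmanResult",
    "BayesLinregResult",
    "paired_t",
    "pearson",
    "bland_altman",
    "ks_normality",
    "posthoc_power_paired_t",
    "required_n_paired_t",
    "bayes_linreg",
    "agreement_report",
]


@dataclass(frozen=True)
class PairedSeries:
    """Two equal-length measurement series on the same cases, same order."""

    label_a: str
    label_b: str
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.ndim != 1 or b.ndim != 1:
            raise InputError("paired series must be one-dimensional")
        if len(a) != len(b):
            raise InputError(
                f"length mismatch: {self.label_a} has {len(a)}, "
                f"{self.label_b} has {len(b)}"
            )
        if len(a) < 2:
            raise InputError("paired series need n >= 2")
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise InputError("paired series must not contain missing/non-finite values")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @property
    def n(self) -> int:
        return len(self.values_a)

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b

    def swapped(self) -> "PairedSeries":
        return PairedSeries(self.label_b, self.label_a, self.values_b, self.values_a)


class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float


def paired_t(series: PairedSeries) -> PairedTResult:
    """Classical paired t-test on a - b; two-sided p from t with n-1 df.

    A zero-variance difference (including a == b elementwise) has no defined
    t statistic: a warning is emitted and t/p are NaN.
    """
    d = series.differences
    n = series.n
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "paired differences have zero variance; t statistic undefined",
            UserWarning,
            stacklevel=2,
        )
        return PairedTResult(float("nan"), n - 1, float("nan"))
    t, p = stats.ttest_rel(series.values_a, series.values_b)
    return PairedTResult(float(t), n - 1, float(p))


def pearson(series: PairedSeries) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t transform)."""
    if series.n < 3:
        raise InputError("pearson correlation needs n >= 3")
    if np.std(series.values_a) == 0 or np.std(series.values_b) == 0:
        raise InputError("correlation undefined for a zero-variance series")
    r, p = stats.pearsonr(series.values_a, series.values_b)
    return float(r), float(p)


@dataclass
class BlandAltmanResult:
    """Agreement between two methods: bias and limits of agreement (LoA).

    ``means`` / ``differences`` are the plot-ready per-case pairs
    ((a+b)/2, a-b).
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_multiplier: float
    means: np.ndarray
    differences: np.ndarray

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "loa_multiplier": self.loa_multiplier,
        }


def bland_altman(series: PairedSeries, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman analysis of a vs b (bias = mean of a - b).

    LoA = bias +/- loa_multiplier * SD(a - b), SD with the n-1 denominator.
    """
    d = series.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        loa_multiplier=loa_multiplier,
        means=0.5 * (series.values_a + series.values_b),
        differences=d,
    )


def ks_normality(values, method: str = "lilliefors") -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with estimated mean/SD.

    ``method="lilliefors"`` (default) applies the Lilliefors correction,
    required for a calibrated p-value when the normal's parameters are
    estimated from the sample; ``method="ks"`` uses the plain one-sample KS
    p-value (conservative under estimated parameters, and what legacy
    point-and-click packages report from their classic KS dialog).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise InputError("normality test needs a 1-D sample with n >= 4")
    if np.any(~np.isfinite(x)):
        raise InputError("sample must be finite")
    if np.std(x, ddof=1) == 0:
        raise InputError("normality test undefined for a constant sample")
    if method == "lilliefors":
        d, p = _lilliefors(x, dist="norm")
    elif method == "ks":
        d, p = stats.kstest(x, "norm", args=(np.mean(x), np.std(x, ddof=1)))
    else:
        raise InputError(f"unknown normality method {method!r}")
    return float(d), float(p)


def posthoc_power_paired_t(dz: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided paired t-test at effect size dz (Cohen's dz).

    The paired t on n differences is a one-sample t with n-1 df and
    noncentrality sqrt(n)*dz; power is the probability the |t| exceeds the
    central-t critical value, evaluated on the noncentral t distribution.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise InputError("n must be an integer >= 2")
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must lie in (0, 1)")
    if not np.isfinite(dz):
        raise InputError("dz must be finite")
    df = n - 1
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    ncp = math.sqrt(n) * dz
    power = stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    return float(min(max(power, 0.0), 1.0))


def required_n_paired_t(dz: float, power: float = 0.80, alpha: float = 0.05) -> int:
    """Smallest n whose paired-t power reaches ``power`` at effect size dz.

    Starts from the normal approximation
    ``n ~ ((z_{1-alpha/2} + z_{power}) / dz)^2`` and refines with the exact
    noncentral-t power by bisection on integers.
    """
    if dz == 0:
        raise InputError("dz = 0 admits no finite sample size")
    if not (0.0 < power < 1.0) or not (0.0 < alpha < 1.0):
        raise InputError("power and alpha must lie in (0, 1)")
    if power <= alpha:
        return 2
    adz = abs(dz)
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    n_approx = max(2, int(math.ceil((z / adz) ** 2)))
    # bracket the target
    lo, hi = 2, n_approx
    while posthoc_power_paired_t(adz, hi, alpha) < power:
        lo = hi
        hi = max(hi + 1, int(hi * 2))
        if hi > 10**10:
            raise EstimationError("required sample size exceeds 1e10")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if posthoc_power_paired_t(adz, mid, alpha) >= power:
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class BayesLinregResult:
    """Posterior summaries for y = b0 + b1 x + eps.

    Under the conjugate normal-inverse-gamma model the marginal posterior of
    each coefficient is a scaled/shifted Student t; means, SDs and central
    95% credible intervals are reported.  ``rhat`` / ``ess`` are populated
    only by the MCMC path.
    """

    intercept_mean: float
    intercept_sd: float
    intercept_ci95: tuple[float, float]
    slope_mean: float
    slope_sd: float
    slope_ci95: tuple[float, float]
    sigma_mean: float
    method: str
    rhat: Optional[dict] = None
    ess: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {
            "intercept": {
                "mean": self.intercept_mean,
                "sd": self.intercept_sd,
                "ci95": list(self.intercept_ci95),
            },
            "slope": {
                "mean": self.slope_mean,
                "sd": self.slope_sd,
                "ci95": list(self.slope_ci95),
            },
            "sigma_mean": self.sigma_mean,
            "method": self.method,
        }
        if self.rhat is not None:
            out["rhat"] = self.rhat
            out["ess"] = self.ess
        return out


def bayes_linreg(
    x,
    y,
    prior_mean: tuple[float, float] = (0.0, 0.0),
    prior_scale: tuple[float, float] = (1e4, 1e4),
    a0: float = 1e-3,
    b0: float = 1e-3,
    method: str = "conjugate",
    seed: Optional[int] = None,
    n_samples: int = 4000,
) -> BayesLinregResult:
    """Bayesian simple linear regression with fully explicit priors.

    Default prior: normal-inverse-gamma with coefficient means ``prior_mean``,
    coefficient scales ``prior_scale`` expressed in units of the residual SD
    (the standard NIG parameterisation, beta | sigma^2 ~ N(m0, sigma^2 V0)),
    and a vague InvGamma(a0, b0) on sigma^2.  With the default wide scales the
    posterior coefficient means coincide with ordinary least squares to
    numerical precision.

    ``method="conjugate"`` (default) returns the exact closed-form posterior.
    ``method="mcmc"`` samples the same likelihood with independent (not
    sigma-scaled) normal priors via emcee, and reports R-hat / effective
    sample size; a seed is mandatory there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise InputError("x and y must be 1-D and equally long")
    if len(x) < 3:
        raise InputError("regression needs n >= 3")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise InputError("x and y must be finite")
    if np.std(x) == 0:
        raise EstimationError("x is constant; slope unidentifiable")

    if method == "conjugate":
        return _conjugate_linreg(x, y, prior_mean, prior_scale, a0, b0)
    if method == "mcmc":
        if seed is None:
            raise InputError("MCMC sampling requires an explicit seed")
        return _mcmc_linreg(x, y, prior_mean, prior_scale, seed, n_samples)
    raise InputError(f"unknown method {method!r}")


def _conjugate_linreg(x, y, prior_mean, prior_scale, a0, b0) -> BayesLinregResult:
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    m0 = np.asarray(prior_mean, dtype=float)
    V0_inv = np.diag(1.0 / np.square(np.asarray(prior_scale, dtype=float)))
    Vn_inv = V0_inv + X.T @ X
    Vn = np.linalg.inv(Vn_inv)
    mn = Vn @ (V0_inv @ m0 + X.T @ y)
    an = a0 + n / 2.0
    bn = b0 + 0.5 * float(y @ y + m0 @ V0_inv @ m0 - mn @ Vn_inv @ mn)
    if bn <= 0 or not np.isfinite(bn):
        raise EstimationError("degenerate posterior (non-positive scale)")
    df = 2.0 * an
    # marginal posterior of beta_j: t_df(mn_j, sqrt(bn/an * Vn_jj))
    scales = np.sqrt(bn / an * np.diag(Vn))
    t975 = stats.t.ppf(0.975, df)
    sds = scales * math.sqrt(df / (df - 2.0)) if df > 2 else np.full(2, np.inf)
    # posterior mean of sigma = sqrt(bn) * Gamma(an - 1/2) / Gamma(an)
    if an > 0.5:
        sigma_mean = math.sqrt(bn) * math.exp(
            math.lgamma(an - 0.5) - math.lgamma(an)
        )
    else:
        sigma_mean = float("nan")
    return BayesLinregResult(
        intercept_mean=float(mn[0]),
        intercept_sd=float(sds[0]),
        intercept_ci95=(float(mn[0] - t975 * scales[0]), float(mn[0] + t975 * scales[0])),
        slope_mean=float(mn[1]),
        slope_sd=float(sds[1]),
        slope_ci95=(float(mn[1] - t975 * scales[1]), float(mn[1] + t975 * scales[1])),
        sigma_mean=float(sigma_mean),
        method="conjugate",
    )


def _mcmc_linreg(x, y, prior_mean, prior_scale, seed, n_samples) -> BayesLinregResult:
    import arviz as az
    import emcee

    n = len(x)
    m0 = np.asarray(prior_mean, dtype=float)
    s0 = np.asarray(prior_scale, dtype=float)
    sd_y = float(np.std(y, ddof=1)) or 1.0

    def log_post(theta):
        b0_, b1_, log_sigma = theta
        if not np.all(np.isfinite(theta)) or abs(log_sigma) > 20:
            return -np.inf
        sigma = math.exp(log_sigma)
        resid = y - b0_ - b1_ * x
        ll = -n * log_sigma - 0.5 * float(resid @ resid) / sigma**2
        lp = -0.5 * ((b0_ - m0[0]) / s0[0]) ** 2 - 0.5 * ((b1_ - m0[1]) / s0[1]) ** 2
        return ll + lp

    rng = np.random.default_rng(seed)
    nwalkers, ndim, burn = 32, 3, 1000
    ols = np.polyfit(x, y, 1)
    start = np.array([ols[1], ols[0], math.log(sd_y)])
    p0 = start + 1e-2 * (np.abs(start) + 1.0) * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post)
    sampler.random_state = np.random.RandomState(seed).get_state()
    keep = max(1000, n_samples // nwalkers)
    sampler.run_mcmc(p0, burn + keep, progress=False)
    chain = sampler.get_chain(discard=burn)  # (steps, walkers, dim)
    idata = az.from_dict(
        posterior={
            "intercept": chain[:, :, 0].T,
            "slope": chain[:, :, 1].T,
            "sigma": np.exp(chain[:, :, 2]).T,
        }
    )
    summ = az.summary(idata, hdi_prob=0.95)
    flat = chain.reshape(-1, 3)
    ci = lambda v: tuple(np.percentile(v, [2.5, 97.5]).tolist())
    return BayesLinregResult(
        intercept_mean=float(flat[:, 0].mean()),
        intercept_sd=float(flat[:, 0].std(ddof=1)),
        intercept_ci95=ci(flat[:, 0]),
        slope_mean=float(flat[:, 1].mean()),
        slope_sd=float(flat[:, 1].std(ddof=1)),
        slope_ci95=ci(flat[:, 1]),
        sigma_mean=float(np.exp(flat[:, 2]).mean()),
        method="mcmc",
        rhat={k: float(summ.loc[k, "r_hat"]) for k in ("intercept", "slope", "sigma")},
        ess={k: float(summ.loc[k, "ess_bulk"]) for k in ("intercept", "slope", "sigma")},
    )


@dataclass
class AgreementReport:
    """Full method-comparison report for one pair of series."""

    label_a: str
    label_b: str
    n: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    df: int
    p_value: float
    pearson_r: float
    pearson_p: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_multiplier: float
    ks_p_a: float
    ks_p_b: float
    normality_method: str
    alpha: float

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def to_dict(self) -> dict:
        return {
            "methods": [self.label_a, self.label_b],
            "n": self.n,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sd_a": self.sd_a,
            "sd_b": self.sd_b,
            "paired_t": {"t": self.t_statistic, "df": self.df, "p": self.p_value},
            "pearson": {"r": self.pearson_r, "p": self.pearson_p},
            "bland_altman": {
                "bias": self.bias,
                "sd_diff": self.sd_diff,
                "loa_low": self.loa_low,
                "loa_high": self.loa_high,
                "loa_multiplier": self.loa_multiplier,
            },
            "normality": {
                "method": self.normality_method,
                "p_a": self.ks_p_a,
                "p_b": self.ks_p_b,
            },
            "alpha": self.alpha,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def agreement_report(
    series: PairedSeries,
    alpha: float = 0.05,
    loa_multiplier: float = 1.96,
    normality_method: str = "lilliefors",
) -> AgreementReport:
    """Run the full comparison battery on one pair of series."""
    t_res = paired_t(series)
    r, rp = pearson(series)
    ba = bland_altman(series, loa_multiplier=loa_multiplier)
    _, ks_a = ks_normality(series.values_a, method=normality_method)
    _, ks_b = ks_normality(series.values_b, method=normality_method)
    return AgreementReport(
        label_a=series.label_a,
        label_b=series.label_b,
        n=series.n,
        mean_a=float(np.mean(series.values_a)),
        mean_b=float(np.mean(series.values_b)),
        sd_a=float(np.std(series.values_a, ddof=1)),
        sd_b=float(np.std(series.values_b, ddof=1)),
        t_statistic=t_res.t,
        df=t_res.df,
        p_value=t_res.p,
        pearson_r=r,
        pearson_p=rp,
        bias=ba.bias,
        sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        loa_multiplier=loa_multiplier,
        ks_p_a=ks_a,
        ks_p_b=ks_b,
        normality_method=normality_method,
        alpha=alpha,
    )
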