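"""Univariable two-sample MR estimators and instrument diagnostics.

All four estimators consume a :class:`~smoketrace.harmonise.HarmonisedData`
with a single exposure column: per-SNP exposure effects ``gamma`` with
standard errors, and outcome effects ``Gamma`` with standard errors.

* IVW: weighted least squares of Gamma on gamma through the origin, weights
  1/Gamma_se^2.  Under the multiplicative random-effects model the standard
  error is inflated by ``max(1, sqrt(Q / (L - 1)))``.
* MR-Egger: the same regression with an intercept after orienting every SNP
  so gamma >= 0; the intercept estimates directional pleiotropy, and
  inference uses a t distribution with L - 2 degrees of freedom.
* Weighted median: inverse-variance-weighted median of the per-SNP Wald
  ratios (linear interpolation of the cumulative weight at 0.5), bootstrap
  standard error.
* Weighted mode: argmax of a normal-kernel weighted density of the Wald
  ratios with a modified-Silverman bandwidth, bootstrap standard error.

Cochran's Q from the IVW fit is the heterogeneity diagnostic; the mean
squared instrument z-statistic is the univariable F statistic, conventionally
required to exceed 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm, t as t_dist

from .errors import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .harmonise import HarmonisedData
from .sumstats import Z_95

__all__ = [
    "MREstimate",
    "DiagnosticReport",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "f_statistic",
]


@dataclass
class MREstimate:
    """One causal-effect estimate: beta per SD of exposure with normal-theory CI."""

    method: str
    exposure: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    outcome: str = "outcome"
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    or_: float | None = None
    or_low: float | None = None
    or_high: float | None = None
    interpretation: str | None = None

    def __post_init__(self) -> None:
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(f"estimate se must be finite and > 0, got {self.se}")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class DiagnosticReport:
    """Heterogeneity and instrument-strength statistics attached to a fit."""

    q_stat: float
    q_df: int
    q_pvalue: float
    f_stat: float | None = None
    conditional_f: dict[str, float] = field(default_factory=dict)
    egger_intercept: tuple[float, float, float] | None = None
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def q_exceeds_nsnp(self) -> bool:
        """The working heterogeneity rule: Q greater than the number of SNPs in the model."""
        return self.q_stat > self.q_df + (1 if self.egger_intercept is None else 2)


def _check_univariable(H: HarmonisedData, min_snps: int, method: str) -> tuple[np.ndarray, ...]:
    if H.n_exposures != 1:
        raise ValueError(f"{method} requires a single exposure column (got {H.n_exposures})")
    if H.n_snps < min_snps:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {min_snps} SNPs, got {H.n_snps}"
        )
    g = H.exposure_beta[:, 0]
    gs = H.exposure_se[:, 0]
    if np.all(g == 0):
        raise DegenerateInstrumentError("all SNP-exposure effects are zero")
    return g, gs, H.outcome_beta, H.outcome_se


def wald_ratio(
    gamma: float, gamma_se: float, Gamma: float, Gamma_se: float
) -> tuple[float, float]:
    """Single-SNP causal estimate Gamma/gamma with its first-order delta-method se."""
    if gamma == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for a zero SNP-exposure effect")
    return Gamma / gamma, abs(Gamma_se / gamma)


def _wald_ratios(H: HarmonisedData) -> tuple[np.ndarray, np.ndarray]:
    g = H.exposure_beta[:, 0]
    if np.any(g == 0):
        raise DegenerateInstrumentError("zero SNP-exposure effect among the instruments")
    return H.outcome_beta / g, np.abs(H.outcome_se / g)


def ivw(
    H: HarmonisedData, model: str = "multiplicative_random"
) -> tuple[MREstimate, DiagnosticReport]:
    """Inverse-variance-weighted estimate: through-origin WLS of Gamma on gamma."""
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown variance model {model!r}")
    g, gs, G, Gs = _check_univariable(H, 2, "ivw")
    w = 1.0 / Gs**2
    swg2 = np.sum(w * g**2)
    beta = np.sum(w * g * G) / swg2
    se = math.sqrt(1.0 / swg2)
    L = H.n_snps
    q = float(np.sum(w * (G - beta * g) ** 2))
    q_df = L - 1
    if model == "multiplicative_random" and q_df > 0:
        se *= max(1.0, math.sqrt(q / q_df))
    p = 2.0 * norm.sf(abs(beta / se))
    est = MREstimate(
        method="ivw",
        exposure=H.exposure_names[0],
        outcome=H.outcome_name,
        beta=float(beta),
        se=se,
        ci_low=float(beta - Z_95 * se),
        ci_high=float(beta + Z_95 * se),
        pvalue=float(p),
        n_snps=L,
    )
    diag = DiagnosticReport(
        q_stat=q,
        q_df=q_df,
        q_pvalue=_chi2_sf(q, q_df),
        f_stat=f_statistic(H),
    )
    return est, diag


def _chi2_sf(q: float, df: int) -> float:
    from scipy.stats import chi2

    return float(chi2.sf(q, df)) if df > 0 else float("nan")


def egger(H: HarmonisedData) -> tuple[MREstimate, DiagnosticReport]:
    """MR-Egger: oriented WLS with intercept; the intercept tests directional pleiotropy."""
    g, gs, G, Gs = _check_univariable(H, 3, "egger")
    # Orient every SNP so the exposure effect is non-negative; the outcome
    # effect flips with it, making the fit invariant to allele-frame choices.
    sign = np.where(g < 0, -1.0, 1.0)
    g = g * sign
    G = G * sign
    w = 1.0 / Gs**2
    if np.ptp(g) == 0:
        raise CollinearityError("oriented exposure effects are constant; intercept inseparable")
    X = np.column_stack([np.ones_like(g), g])
    XtW = X.T * w
    xtx = XtW @ X
    try:
        coef = np.linalg.solve(xtx, XtW @ G)
        cov = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError("rank-deficient Egger design") from exc
    L = H.n_snps
    q = float(np.sum(w * (G - X @ coef) ** 2))
    q_df = L - 2
    scale = max(1.0, math.sqrt(q / q_df)) if q_df > 0 else 1.0
    ses = np.sqrt(np.diag(cov)) * scale
    tq = t_dist.ppf(0.975, q_df)
    slope, slope_se = float(coef[1]), float(ses[1])
    inter, inter_se = float(coef[0]), float(ses[0])
    est = MREstimate(
        method="egger",
        exposure=H.exposure_names[0],
        outcome=H.outcome_name,
        beta=slope,
        se=slope_se,
        ci_low=slope - tq * slope_se,
        ci_high=slope + tq * slope_se,
        pvalue=float(2.0 * t_dist.sf(abs(slope / slope_se), q_df)),
        n_snps=L,
        intercept=inter,
        intercept_se=inter_se,
        intercept_p=float(2.0 * t_dist.sf(abs(inter / inter_se), q_df)),
    )
    diag = DiagnosticReport(
        q_stat=q,
        q_df=q_df,
        q_pvalue=_chi2_sf(q, q_df),
        f_stat=f_statistic(H),
        egger_intercept=(inter, inter_se, est.intercept_p),
    )
    return est, diag


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    # Interpolate the cumulative weight evaluated at each ratio's midpoint.
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _parametric_bootstrap(
    H: HarmonisedData,
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """Bootstrap se: redraw summary statistics from their sampling distributions."""
    rng = np.random.default_rng(seed)
    g = H.exposure_beta[:, 0]
    gs = H.exposure_se[:, 0]
    G = H.outcome_beta
    Gs = H.outcome_se
    L = len(g)
    est = np.empty(n_boot)
    g_star = rng.normal(g, gs, size=(n_boot, L))
    G_star = rng.normal(G, Gs, size=(n_boot, L))
    g_star[g_star == 0] = np.finfo(float).tiny  # zero-crossing draws are measure-zero guards
    for b in range(n_boot):
        ratios = G_star[b] / g_star[b]
        weights = (g_star[b] / Gs) ** 2
        est[b] = point_fn(ratios, weights)
    return float(np.std(est, ddof=1))


def weighted_median(
    H: HarmonisedData, n_boot: int = 5000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator; consistent when >= 50% of the weight is valid."""
    _check_univariable(H, 3, "weighted_median")
    ratios, ratio_se = _wald_ratios(H)
    weights = 1.0 / ratio_se**2
    beta = _weighted_median_point(ratios, weights)
    se = _parametric_bootstrap(H, _weighted_median_point, n_boot, seed)
    se = max(se, np.finfo(float).tiny)
    return MREstimate(
        method="weighted_median",
        exposure=H.exposure_names[0],
        outcome=H.outcome_name,
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        pvalue=float(2.0 * norm.sf(abs(beta / se))),
        n_snps=H.n_snps,
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman rule on the ratio spread, scaled by the tuning factor phi."""
    s = np.std(ratios, ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    if spread == 0:
        return max(phi, np.finfo(float).tiny)
    return phi * 0.9 * spread * len(ratios) ** (-0.2)


_MODE_GRID = 512


def _weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0
) -> float:
    if np.ptp(ratios) == 0:  # degenerate spread: the common ratio is the mode
        return float(ratios[0])
    h = _mode_bandwidth(ratios, phi)
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, _MODE_GRID)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    H: HarmonisedData,
    bandwidth_factor: float = 1.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-mode estimator: argmax of the smoothed weighted Wald-ratio density."""
    _check_univariable(H, 3, "weighted_mode")
    ratios, ratio_se = _wald_ratios(H)
    weights = 1.0 / ratio_se**2
    beta = _weighted_mode_point(ratios, weights, bandwidth_factor)
    se = _parametric_bootstrap(
        H,
        lambda r, w: _weighted_mode_point(r, w, bandwidth_factor),
        n_boot,
        seed,
    )
    se = max(se, np.finfo(float).tiny)
    return MREstimate(
        method="weighted_mode",
        exposure=H.exposure_names[0],
        outcome=H.outcome_name,
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        pvalue=float(2.0 * norm.sf(abs(beta / se))),
        n_snps=H.n_snps,
    )


def f_statistic(H: HarmonisedData) -> float:
    """Mean squared instrument z-statistic, the univariable strength measure."""
    if H.n_exposures != 1:
        raise ValueError("univariable F statistic requires a single exposure column")
    z = H.exposure_beta[:, 0] / H.exposure_se[:, 0]
    return float(np.mean(z**2))


def attach_odds_ratio(est: MREstimate) -> MREstimate:
    """Report the estimate additionally as an odds ratio (log-odds outcomes only).

    The OR interval exponentiates the estimate's own CI bounds so Egger-style
    t intervals carry through unchanged.
    """
    return replace(
        est,
        or_=math.exp(est.beta),
        or_low=math.exp(est.ci_low),
        or_high=math.exp(est.ci_high),
    )
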