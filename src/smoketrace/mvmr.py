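"""Multivariable MR: joint direct effects, conditional instrument strength, direction flip.

With K exposures (here typically the nicotine metabolite ratio and cigarettes
per day), the SNP-outcome effects are regressed jointly on the K columns of
SNP-exposure effects, weights 1/Gamma_se^2.  Each coefficient is the direct
effect of that exposure holding the others fixed.  MVMR-Egger adds an
intercept after orienting all SNPs on one exposure's sign; the intercept
tests directional pleiotropy, and estimates are reported for the chosen
orientation only (orientation invariance does not hold and is not claimed).

The conditional F statistic measures how strongly the SNPs predict one
exposure beyond their prediction of the others: the weighted residual sum of
squares from regressing that exposure's effects on the other exposures'
columns, divided by L - K + 1.  Values above 10 are the conventional adequacy
threshold.

Because a higher nicotine metabolite ratio means *less* circulating nicotine
per cigarette, the direct effect of the ratio can be sign-flipped to read as
the effect of increased nicotine exposure per cigarette smoked;
:func:`flip_direction` performs that relabelling as an involution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import chi2, norm, t as t_dist

from .errors import CollinearityError, InsufficientInstrumentsError
from .harmonise import HarmonisedData
from .sumstats import Z_95
from .univariable import DiagnosticReport, MREstimate

__all__ = ["MvmrResult", "mvmr_ivw", "mvmr_egger", "conditional_f", "flip_direction"]


@dataclass
class MvmrResult:
    """Per-exposure direct-effect estimates plus shared diagnostics."""

    estimates: dict[str, MREstimate]
    diagnostics: DiagnosticReport
    intercept: tuple[float, float, float] | None = None


def _design(H: HarmonisedData, min_extra: int, method: str) -> tuple[np.ndarray, ...]:
    K = H.n_exposures
    if K < 2:
        raise ValueError(f"{method} requires K >= 2 exposures, got {K}")
    if H.n_snps < K + min_extra:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {K + min_extra} SNPs for {K} exposures, got {H.n_snps}"
        )
    return H.exposure_beta.copy(), H.outcome_beta.copy(), 1.0 / H.outcome_se**2


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    XtW = X.T * w
    xtx = XtW @ X
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise CollinearityError("exposure effect columns are collinear")
    coef = np.linalg.solve(xtx, XtW @ y)
    return coef, np.linalg.inv(xtx)


def mvmr_ivw(H: HarmonisedData, model: str = "multiplicative_random") -> MvmrResult:
    """MVMR-IVW: weighted multivariable regression of Gamma on the gamma matrix, no intercept."""
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown variance model {model!r}")
    X, y, w = _design(H, 1, "mvmr_ivw")
    coef, cov = _wls(X, y, w)
    L, K = X.shape
    q = float(np.sum(w * (y - X @ coef) ** 2))
    q_df = L - K
    scale = 1.0
    if model == "multiplicative_random" and q_df > 0:
        scale = max(1.0, math.sqrt(q / q_df))
    ses = np.sqrt(np.diag(cov)) * scale
    estimates = {}
    for k, name in enumerate(H.exposure_names):
        b, s = float(coef[k]), float(ses[k])
        estimates[name] = MREstimate(
            method="mvmr_ivw",
            exposure=name,
            outcome=H.outcome_name,
            beta=b,
            se=s,
            ci_low=b - Z_95 * s,
            ci_high=b + Z_95 * s,
            pvalue=float(2.0 * norm.sf(abs(b / s))),
            n_snps=L,
        )
    diag = DiagnosticReport(
        q_stat=q,
        q_df=q_df,
        q_pvalue=float(chi2.sf(q, q_df)) if q_df > 0 else float("nan"),
        conditional_f={
            name: conditional_f(H, k) for k, name in enumerate(H.exposure_names)
        },
    )
    return MvmrResult(estimates=estimates, diagnostics=diag)


def mvmr_egger(H: HarmonisedData, orient_on: int | str = 0) -> MvmrResult:
    """MVMR-Egger: SNPs oriented so the chosen exposure's effects are non-negative.

    Slope estimates depend on which exposure anchors the orientation; both
    orientations are legitimate reports and the choice is recorded in the
    estimates' ``interpretation`` field.
    """
    k_or = orient_on if isinstance(orient_on, int) else H.exposure_names.index(orient_on)
    X, y, w = _design(H, 2, "mvmr_egger")
    sign = np.where(X[:, k_or] < 0, -1.0, 1.0)
    X = X * sign[:, None]
    y = y * sign
    L, K = X.shape
    Xd = np.column_stack([np.ones(L), X])
    coef, cov = _wls(Xd, y, w)
    q = float(np.sum(w * (y - Xd @ coef) ** 2))
    q_df = L - K - 1
    scale = max(1.0, math.sqrt(q / q_df)) if q_df > 0 else 1.0
    ses = np.sqrt(np.diag(cov)) * scale
    tq = t_dist.ppf(0.975, q_df)
    inter, inter_se = float(coef[0]), float(ses[0])
    inter_p = float(2.0 * t_dist.sf(abs(inter / inter_se), q_df))
    estimates = {}
    for k, name in enumerate(H.exposure_names):
        b, s = float(coef[k + 1]), float(ses[k + 1])
        estimates[name] = MREstimate(
            method="mvmr_egger",
            exposure=name,
            outcome=H.outcome_name,
            beta=b,
            se=s,
            ci_low=b - tq * s,
            ci_high=b + tq * s,
            pvalue=float(2.0 * t_dist.sf(abs(b / s), q_df)),
            n_snps=L,
            intercept=inter,
            intercept_se=inter_se,
            intercept_p=inter_p,
            interpretation=f"oriented on {H.exposure_names[k_or]}",
        )
    diag = DiagnosticReport(
        q_stat=q,
        q_df=q_df,
        q_pvalue=float(chi2.sf(q, q_df)) if q_df > 0 else float("nan"),
        egger_intercept=(inter, inter_se, inter_p),
        conditional_f={
            name: conditional_f(H, k) for k, name in enumerate(H.exposure_names)
        },
    )
    return MvmrResult(estimates=estimates, diagnostics=diag, intercept=(inter, inter_se, inter_p))


def conditional_f(H: HarmonisedData, k: int | str) -> float:
    """Instrument strength of exposure ``k`` conditional on the other exposures.

    Weighted (1/gamma_se_k^2) regression of the k-th exposure's SNP effects on
    the other exposures' columns, through the origin; the weighted residual
    sum of squares over L - K + 1 is the conditional F.  Covariance between
    the exposure GWAS is ignored (they come from non-overlapping samples),
    which makes this the simplified, equal-weights version of the statistic.
    """
    if isinstance(k, str):
        k = H.exposure_names.index(k)
    K = H.n_exposures
    if K < 2:
        raise ValueError("conditional F requires K >= 2 exposures")
    if H.n_snps < K + 1:
        raise InsufficientInstrumentsError(
            f"conditional F needs at least {K + 1} SNPs, got {H.n_snps}"
        )
    y = H.exposure_beta[:, k]
    w = 1.0 / H.exposure_se[:, k] ** 2
    others = [j for j in range(K) if j != k]
    X = H.exposure_beta[:, others]
    if np.all(X == 0):
        fitted = np.zeros_like(y)
    else:
        XtW = X.T * w
        xtx = XtW @ X
        if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
            raise CollinearityError("other exposures' effect columns are collinear")
        fitted = X @ np.linalg.solve(xtx, XtW @ y)
    q_x = float(np.sum(w * (y - fitted) ** 2))
    return q_x / (H.n_snps - K + 1)


_FLIP_TAG = "nicotine-per-cigarette"


def flip_direction(est: MREstimate) -> MREstimate:
    """Re-express an NMR direct effect as the effect of increased nicotine per cigarette.

    Beta and CI bounds are negated (bounds swapped), any odds ratio becomes
    its reciprocal with a reciprocal, swapped CI, and the p-value is
    unchanged.  Applying the flip twice returns the original estimate.
    """
    current = est.interpretation or ""
    if _FLIP_TAG in current:
        new_interp = "; ".join(p for p in current.split("; ") if p != _FLIP_TAG) or None
    else:
        new_interp = f"{current}; {_FLIP_TAG}" if current else _FLIP_TAG
    return replace(
        est,
        beta=-est.beta,
        ci_low=-est.ci_high,
        ci_high=-est.ci_low,
        or_=None if est.or_ is None else 1.0 / est.or_,
        or_low=None if est.or_high is None else 1.0 / est.or_high,
        or_high=None if est.or_low is None else 1.0 / est.or_low,
        intercept=None if est.intercept is None else -est.intercept,
        interpretation=new_interp,
    )
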