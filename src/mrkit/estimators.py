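"""Causal-estimator suite for harmonized instruments.

All estimators pool per-SNP Wald ratios (outcome effect / exposure
effect) with first-order delta-method standard errors, and report the
causal effect per unit exposure on the log-odds scale together with the
exponentiated odds ratio.

* IVW: inverse-variance-weighted mean of the ratios.  The fixed-effect
  model assumes a single causal effect; the multiplicative random-effects
  model rescales the standard error by the estimated overdispersion
  sqrt(Q/(k-1)), by default without flooring at 1, so it can be either
  larger or smaller than the fixed-effect one.
* Weighted median: the 50th weighted percentile of the ordered ratios,
  consistent when more than half the instrument weight is valid;
  standard error by parametric bootstrap.
* MR-Egger: weighted regression of outcome on exposure effects with a
  free intercept; a nonzero intercept signals directional horizontal
  pleiotropy, and the slope is the pleiotropy-corrected causal effect.
* Cochran's Q and the derived I² quantify heterogeneity among the
  per-SNP ratios under the fixed-effect IVW fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EstimationError
from .sumstats_io import HarmonizedInstrument

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate on the log-odds scale with its exponentiated OR."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)


@dataclass(frozen=True)
class HeterogeneityReport:
    """Cochran's Q heterogeneity statistics under the fixed-effect IVW model."""

    q: float
    df: int
    q_pvalue: float
    i2: float  # percentage in [0, 100]


def _normal_estimate(method: str, beta: float, se: float, k: int) -> MrEstimate:
    z = beta / se
    return MrEstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=float(2 * stats.norm.sf(abs(z))),
        n_snps=k,
    )


def _ratios(insts: Sequence[HarmonizedInstrument]) -> tuple[np.ndarray, np.ndarray]:
    bx = np.array([i.beta_exposure for i in insts])
    by = np.array([i.beta_outcome for i in insts])
    sy = np.array([i.se_outcome for i in insts])
    if np.any(bx == 0):
        bad = [i.snp_id for i in insts if i.beta_exposure == 0]
        raise EstimationError(f"zero exposure effect, Wald ratio undefined: {bad}")
    return by / bx, sy / np.abs(bx)


def wald_ratio(inst: HarmonizedInstrument) -> MrEstimate:
    """Single-SNP causal estimate: beta_outcome / beta_exposure.

    The first-order delta-method standard error se_outcome /
    |beta_exposure| ignores exposure-side uncertainty (the common NOME
    approximation).
    """
    ratio, se = _ratios([inst])
    return _normal_estimate("wald", float(ratio[0]), float(se[0]), 1)


def ivw(
    insts: Sequence[HarmonizedInstrument],
    model: str = "fixed",
    *,
    floor_dispersion: bool = False,
) -> MrEstimate:
    """Inverse-variance-weighted pooled causal estimate.

    ``model="fixed"`` gives se = (sum of weights)^(-1/2).
    ``model="random"`` applies multiplicative overdispersion: the fixed
    standard error is scaled by sqrt(Q/(k-1)), unfloored by default so
    under-dispersed data yield a smaller standard error than the fixed
    model (set ``floor_dispersion=True`` to clamp the scale at 1).
    A single instrument degenerates to the Wald ratio.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if len(insts) == 0:
        raise EstimationError("IVW requires at least one instrument")
    if len(insts) == 1:
        est = wald_ratio(insts[0])
        return MrEstimate(**{**est.__dict__, "method": f"ivw_{model}"})

    ratios, ses = _ratios(insts)
    w = 1.0 / ses**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if model == "random":
        k = len(insts)
        q = float(np.sum(w * (ratios - beta) ** 2))
        scale = math.sqrt(q / (k - 1))
        if floor_dispersion:
            scale = max(scale, 1.0)
        se = se_fixed * scale
    else:
        se = se_fixed
    return _normal_estimate(f"ivw_{model}", beta, se, len(insts))


def weighted_median(
    insts: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap standard error.

    The estimate is the linear interpolation of adjacent ordered Wald
    ratios at cumulative standardized inverse-variance weight 0.5, with
    standardized weights s_j = (cum_j - w_j/2) / sum(w).  The bootstrap
    redraws each exposure and outcome effect from a normal centred on
    its observed value with its reported standard error, recomputes the
    ratios and takes the weighted median with the original weights; the
    standard error is the standard deviation over ``n_boot`` draws.
    """
    if len(insts) < 3:
        raise EstimationError("weighted median requires at least 3 instruments")
    ratios, ses = _ratios(insts)
    w = 1.0 / ses**2
    beta = _weighted_median_value(ratios, w)

    rng = np.random.default_rng(seed)
    bx = np.array([i.beta_exposure for i in insts])
    sx = np.array([i.se_exposure for i in insts])
    by = np.array([i.beta_outcome for i in insts])
    sy = np.array([i.se_outcome for i in insts])
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        boots[b] = _weighted_median_value(by_b / bx_b, w)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_median", float(beta), se, len(insts))


def _weighted_median_value(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - w / 2) / np.sum(w)
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def egger(insts: Sequence[HarmonizedInstrument]) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger weighted regression; returns (slope, intercept) estimates.

    Outcome effects are regressed on exposure effects with a free
    intercept and weights 1/se_outcome², after orienting every
    instrument so its exposure effect is positive (the intercept's sign
    is otherwise arbitrary).  Coefficient standard errors are scaled by
    the square root of the estimated residual variance, unfloored;
    inference uses the t distribution with k-2 degrees of freedom.
    """
    k = len(insts)
    if k < 3:
        raise EstimationError("MR-Egger requires at least 3 instruments")
    bx = np.array([i.beta_exposure for i in insts])
    by = np.array([i.beta_outcome for i in insts])
    sy = np.array([i.se_outcome for i in insts])
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise EstimationError("zero spread in exposure effects: Egger design is singular")

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = sigma2 * np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov))

    tdist = stats.t(k - 2)
    tq = tdist.ppf(0.975)

    def make(method: str, b: float, se: float) -> MrEstimate:
        return MrEstimate(
            method=method,
            beta=b,
            se=se,
            ci_low=b - tq * se,
            ci_high=b + tq * se,
            pvalue=float(2 * tdist.sf(abs(b / se))),
            n_snps=k,
        )

    slope = make("egger_slope", float(coef[1]), float(ses[1]))
    intercept = make("egger_intercept", float(coef[0]), float(ses[0]))
    return slope, intercept


def heterogeneity(insts: Sequence[HarmonizedInstrument]) -> HeterogeneityReport:
    """Cochran's Q and I² among the per-SNP ratios under the fixed IVW fit."""
    if len(insts) < 2:
        raise EstimationError("heterogeneity requires at least 2 instruments")
    ratios, ses = _ratios(insts)
    w = 1.0 / ses**2
    beta = np.sum(w * ratios) / np.sum(w)
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = len(insts) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityReport(
        q=q,
        df=df,
        q_pvalue=float(stats.chi2.sf(q, df)),
        i2=i2,
    )
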