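"""Fixed-effect meta-analysis, variance explained, and binary-outcome power.

Variance explained per instrument uses the summary-statistic formula
R² = 2·EAF·(1−EAF)·beta² / (2·EAF·(1−EAF)·(beta² + se²·N)), which for a
trait standardized to unit variance estimates the fraction of
phenotypic variance attributable to the SNP.

Power for a binary outcome follows the mRnd non-centrality
approximation: an odds ratio OR acting on a disease of prevalence
K = cases/N is first attenuated to the observed-scale regression
coefficient b = K·(OR/(1+K·(OR−1)) − 1); the non-centrality parameter of
the instrumented association is NCP = N·R²·b²/(K(1−K) − b²) and the
two-sided power at level alpha is Phi(sqrt(NCP) − z_{1−alpha/2}).
``detectable_or`` inverts this relation in closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EstimationError
from .estimators import HeterogeneityReport, MrEstimate, _normal_estimate
from .sumstats_io import GwasRecord


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a binary-outcome MR power calculation."""

    n_outcome: int
    n_cases: int
    r2_total: float
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self):
        if not 0 < self.n_cases < self.n_outcome:
            raise ValueError("need 0 < n_cases < n_outcome")
        if not 0 < self.r2_total < 1:
            raise ValueError("r2_total must be in (0,1)")
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise ValueError("alpha and target_power must be in (0,1)")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_outcome


def variance_explained(record: GwasRecord) -> float:
    """Fraction of trait variance explained by one SNP, in [0, 1).

    Invariant under allele relabeling (EAF → 1−EAF with beta → −beta);
    algebraically the EAF factor cancels, leaving z²/(z² + N).
    """
    pq2 = 2.0 * record.eaf * (1.0 - record.eaf)
    num = pq2 * record.beta**2
    den = pq2 * (record.beta**2 + record.se**2 * record.n)
    return num / den


def total_variance_explained(records: Sequence[GwasRecord]) -> float:
    """Summed per-SNP variance explained of an (independent) instrument set."""
    return float(sum(variance_explained(r) for r in records))


def meta_fixed(estimates: Sequence[MrEstimate]) -> MrEstimate:
    """Fixed-effect inverse-variance meta-analysis of per-cohort estimates.

    All inputs must be on the same (log-odds) scale.  A single estimate
    is returned unchanged with a warning.
    """
    if len(estimates) == 0:
        raise EstimationError("meta-analysis requires at least one estimate")
    if len(estimates) == 1:
        warnings.warn("meta_fixed called with a single estimate; returned unchanged")
        est = estimates[0]
        return MrEstimate(**{**est.__dict__, "method": "meta_fixed"})
    betas = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    n_snps = estimates[0].n_snps
    return _normal_estimate("meta_fixed", beta, se, n_snps)


def meta_heterogeneity(estimates: Sequence[MrEstimate]) -> HeterogeneityReport:
    """Cochran's Q across cohort estimates (small-df, reported descriptively)."""
    if len(estimates) < 2:
        raise EstimationError("heterogeneity requires at least 2 estimates")
    betas = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    beta = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - beta) ** 2))
    df = len(estimates) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityReport(q=q, df=df, q_pvalue=float(stats.chi2.sf(q, df)), i2=i2)


def _attenuated_b(or_value: float, k: float) -> float:
    """Observed-scale coefficient corresponding to an odds ratio at prevalence K."""
    return k * (or_value / (1.0 + k * (or_value - 1.0)) - 1.0)


def _or_from_b(b: float, k: float) -> float:
    """Invert :func:`_attenuated_b`: the odds ratio whose attenuated coefficient is b."""
    c = 1.0 + b / k
    return c * (1.0 - k) / (1.0 - c * k)


def detectable_or(spec: PowerSpec) -> tuple[float, float]:
    """Minimum detectable odds ratios (above 1, below 1) at the target power.

    Solves the mRnd non-centrality relation for the attenuated
    coefficient magnitude b with NCP = (z_{1−alpha/2} + z_{power})²,
    then maps ±b back to odds ratios.
    """
    if spec.r2_total <= 0:
        raise EstimationError("r2_total must be positive: no instrument strength")
    k = spec.case_fraction
    ncp = (stats.norm.ppf(1 - spec.alpha / 2) + stats.norm.ppf(spec.target_power)) ** 2
    b2 = ncp * k * (1 - k) / (spec.n_outcome * spec.r2_total + ncp)
    b = math.sqrt(b2)
    return _or_from_b(b, k), _or_from_b(-b, k)


def power_at_or(spec: PowerSpec, or_value: float) -> float:
    """Two-sided power to detect ``or_value`` given the spec's sample and R².

    ``or_value = 1`` has no effect to detect; the conventional value
    alpha/2 is returned with a warning.
    """
    if or_value <= 0:
        raise ValueError("or_value must be positive")
    k = spec.case_fraction
    if or_value == 1.0:
        warnings.warn("power at OR=1 is the type-I rate alpha/2 by convention")
    b = _attenuated_b(or_value, k)
    ncp = spec.n_outcome * spec.r2_total * b**2 / (k * (1 - k) - b**2)
    z_alpha = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(math.sqrt(ncp) - z_alpha))


def continuous_outcome_power(*args, **kwargs):  # pragma: no cover - stub
    """Placeholder: only the binary-outcome power branch is implemented."""
    raise NotImplementedError("continuous-outcome power is not implemented")
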