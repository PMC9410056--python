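"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the study regime the package is built for: a
continuous exposure (a circulating protein standardized to unit
variance) measured in a modest cohort, and a binary outcome from a
large case-control GWAS, with no sample overlap.  Per SNP j:

* effect-allele frequency p_j ~ Uniform(eaf_range);
* true exposure effect gamma_j > 0, scaled so the theoretical summed
  variance explained sum_j 2 p_j (1-p_j) gamma_j² equals
  ``exposure_r2_total``;
* exposure standard error from the standard GWAS relation
  se ≈ 1/sqrt(2 p (1-p) n_exposure), observed effect gamma_j + noise;
* true outcome effect theta·gamma_j + alpha_j on the log-odds scale,
  with pleiotropic effects alpha_j ~ Normal(pleiotropy_mean,
  pleiotropy_sd²) — balanced when the mean is 0, directional otherwise
  (drawn independently of gamma_j, so the InSIDE condition holds);
* outcome standard error ≈ 1/sqrt(2 p (1-p) n_outcome K (1-K)) for case
  fraction K, observed effect true + noise;
* the first ``n_outliers`` SNPs have their observed outcome effect
  shifted by ``outlier_shift_se`` outcome standard errors.

The defaults reproduce the seven-instrument, R² = 12.8% regime against
the larger CAD cohort with a modest protective causal effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import presets
from .iv_selection import LdMatrix
from .sumstats_io import GwasRecord


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of one synthetic two-sample dataset."""

    n_snps: int = presets.N_INSTRUMENTS
    theta: float = -0.03  # true causal effect, log-odds per exposure unit
    n_exposure: int = presets.EXPOSURE_N
    n_outcome: int = presets.OUTCOME_COHORTS["cardiogram_cad"].n
    case_fraction: float = presets.OUTCOME_COHORTS["cardiogram_cad"].case_fraction
    eaf_range: tuple[float, float] = (0.1, 0.9)
    exposure_r2_total: float = presets.EXPOSURE_R2_TOTAL
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_outliers: int = 0
    outlier_shift_se: float = 0.0
    palindrome_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise ValueError("eaf_range must be a sub-interval of (0,1)")
        if not 0 <= self.exposure_r2_total < 1:
            raise ValueError("exposure_r2_total must be in [0,1)")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0,1)")
        if self.n_outliers > self.n_snps:
            raise ValueError("n_outliers exceeds n_snps")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth underlying one generated dataset."""

    theta: float
    gamma: np.ndarray  # true exposure effects
    alpha: np.ndarray  # pleiotropic outcome effects
    eaf: np.ndarray
    outlier_ids: tuple[str, ...]


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    # Clip at the smallest positive float so records keep pvalue > 0.
    return np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)


def generate(config: SyntheticConfig) -> tuple[list[GwasRecord], list[GwasRecord], SyntheticTruth]:
    """Generate (exposure records, outcome records, truth) for one dataset."""
    rng = np.random.default_rng(config.seed)
    m = config.n_snps

    eaf = rng.uniform(*config.eaf_range, size=m)
    pq2 = 2.0 * eaf * (1.0 - eaf)

    # Positive raw effects bounded away from zero, then scaled so the
    # theoretical summed variance explained hits the target exactly.
    gamma_raw = rng.uniform(0.5, 1.5, size=m)
    raw_r2 = np.sum(pq2 * gamma_raw**2)
    if config.exposure_r2_total > 0:
        gamma = gamma_raw * np.sqrt(config.exposure_r2_total / raw_r2)
    else:
        gamma = np.zeros(m)

    se_x = 1.0 / np.sqrt(pq2 * config.n_exposure)
    beta_x = gamma + rng.normal(0.0, se_x)

    alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=m) if (
        config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0
    ) else np.zeros(m)

    k = config.case_fraction
    se_y = 1.0 / np.sqrt(pq2 * config.n_outcome * k * (1.0 - k))
    beta_y = config.theta * gamma + alpha + rng.normal(0.0, se_y)
    if config.n_outliers:
        beta_y[: config.n_outliers] += config.outlier_shift_se * se_y[: config.n_outliers]

    # Effect allele is the exposure-increasing allele; a configurable
    # fraction of SNPs is palindromic to exercise harmonization.
    n_pal = int(round(config.palindrome_fraction * m))
    alleles = [("A", "T") if j < n_pal else ("A", "G") for j in range(m)]

    ids = [f"snp{j + 1:03d}" for j in range(m)]
    exposure = [
        GwasRecord(ids[j], alleles[j][0], alleles[j][1], float(eaf[j]),
                   float(beta_x[j]), float(se_x[j]),
                   float(_two_sided_p(np.array(beta_x[j] / se_x[j]))),
                   config.n_exposure)
        for j in range(m)
    ]
    outcome = [
        GwasRecord(ids[j], alleles[j][0], alleles[j][1], float(eaf[j]),
                   float(beta_y[j]), float(se_y[j]),
                   float(_two_sided_p(np.array(beta_y[j] / se_y[j]))),
                   config.n_outcome)
        for j in range(m)
    ]
    truth = SyntheticTruth(
        theta=config.theta,
        gamma=gamma,
        alpha=alpha,
        eaf=eaf,
        outlier_ids=tuple(ids[: config.n_outliers]),
    )
    return exposure, outcome, truth


def generate_outcome_for_cohort(
    exposure: Sequence[GwasRecord],
    truth: SyntheticTruth,
    n_outcome: int,
    case_fraction: float,
    seed: int,
    *,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
) -> list[GwasRecord]:
    """Draw a fresh outcome sample for an existing exposure dataset.

    Lets one simulated exposure study be analysed against several
    independent outcome cohorts, as in a replication + meta-analysis
    design.  Pleiotropic effects, if any, are redrawn per cohort.
    """
    rng = np.random.default_rng(seed)
    eaf = truth.eaf
    pq2 = 2.0 * eaf * (1.0 - eaf)
    k = case_fraction
    se_y = 1.0 / np.sqrt(pq2 * n_outcome * k * (1.0 - k))
    alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, size=len(eaf)) if (
        pleiotropy_sd > 0 or pleiotropy_mean != 0
    ) else truth.alpha
    beta_y = truth.theta * truth.gamma + alpha + rng.normal(0.0, se_y)
    return [
        GwasRecord(r.snp_id, r.effect_allele, r.other_allele, float(eaf[j]),
                   float(beta_y[j]), float(se_y[j]),
                   float(_two_sided_p(np.array(beta_y[j] / se_y[j]))),
                   n_outcome)
        for j, r in enumerate(exposure)
    ]


def block_ld_matrix(
    snp_ids: Sequence[str],
    block_sizes: Sequence[int],
    r2_within: float = 0.8,
) -> LdMatrix:
    """Block-constant LD matrix for clump testing: r² = ``r2_within`` inside
    each block, 0 between blocks, 1 on the diagonal."""
    if sum(block_sizes) != len(snp_ids):
        raise ValueError("block sizes must sum to the number of SNPs")
    n = len(snp_ids)
    r2 = np.zeros((n, n))
    start = 0
    for size in block_sizes:
        r2[start:start + size, start:start + size] = r2_within
        start += size
    np.fill_diagonal(r2, 1.0)
    return LdMatrix(snp_ids=tuple(snp_ids), r2=r2)


def write_truth(truth: SyntheticTruth, ids: Sequence[str], path: str | Path, sep: str = "\t") -> None:
    """Write the per-SNP ground truth as a delimited table."""
    df = pd.DataFrame({
        "snp_id": list(ids),
        "gamma": truth.gamma,
        "alpha": truth.alpha,
        "eaf": truth.eaf,
        "theta": truth.theta,
        "is_outlier": [i in truth.outlier_ids for i in ids],
    })
    df.to_csv(path, sep=sep, index=False)
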