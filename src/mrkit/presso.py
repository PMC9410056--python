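"""MR-PRESSO: pleiotropy residual sum and outlier diagnostics.

The global test compares the observed leave-one-out weighted residual
sum of squares (RSS) of the instrument set against its simulated null
distribution; the outlier test compares each SNP's own residual
contribution against its simulated distribution (Bonferroni-adjusted);
the distortion test asks whether removing the flagged outliers changes
the causal estimate more than removing a random subset of the same
size would.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EstimationError
from .estimators import MrEstimate, ivw
from .sumstats_io import HarmonizedInstrument

DEFAULT_N_SIM = 1000
DEFAULT_OUTLIER_ALPHA = 0.05


@dataclass(frozen=True)
class PressoReport:
    """Result bundle of the MR-PRESSO global/outlier/distortion tests."""

    rss_observed: float
    global_pvalue: float
    outlier_pvalues: dict[str, float]  # Bonferroni-adjusted, capped at 1
    outliers: tuple[str, ...]
    estimate_raw: MrEstimate
    estimate_corrected: MrEstimate | None
    distortion_pvalue: float | None
    n_sim: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes of the weighted through-origin regression.

    Works on 1-D arrays or on (n_sim, k) matrices (row-wise).
    """
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def presso_global(
    insts: Sequence[HarmonizedInstrument],
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    *,
    outlier_alpha: float = DEFAULT_OUTLIER_ALPHA,
    run_distortion: bool = True,
) -> PressoReport:
    """Run the MR-PRESSO global, outlier and (conditionally) distortion tests.

    For each SNP j the leave-one-out IVW slope b_{-j} is computed and the
    observed RSS is sum_j w_j (beta_outcome_j - b_{-j} beta_exposure_j)²
    with outcome-variance weights w_j = 1/se_outcome_j².  Each of
    ``n_sim`` replicates redraws exposure effects around their observed
    values and outcome effects around the leave-one-out fitted values,
    with the reported standard errors, and recomputes the RSS the same
    way.  Empirical p-values use the (1+#)/ (n_sim+1) correction so they
    are never zero.  Per-SNP p-values are Bonferroni-multiplied by the
    instrument count; SNPs below ``outlier_alpha`` after adjustment are
    flagged and the corrected estimate is the fixed-effect IVW on the
    remainder.  Instruments are processed in sorted snp_id order, making
    the report invariant to input ordering and bit-reproducible for a
    fixed seed.
    """
    if len(insts) < 4:
        raise EstimationError("MR-PRESSO requires at least 4 instruments")
    order = sorted(range(len(insts)), key=lambda i: insts[i].snp_id)
    insts_sorted = [insts[i] for i in order]
    ids = [i.snp_id for i in insts_sorted]
    k = len(ids)

    bx = np.array([i.beta_exposure for i in insts_sorted])
    sx = np.array([i.se_exposure for i in insts_sorted])
    by = np.array([i.beta_outcome for i in insts_sorted])
    sy = np.array([i.se_outcome for i in insts_sorted])
    w = 1.0 / sy**2

    slopes_loo = _loo_slopes(bx, by, w)
    resid2_obs = w * (by - slopes_loo * bx) ** 2
    rss_obs = float(np.sum(resid2_obs))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(slopes_loo * bx, sy, size=(n_sim, k))
    w_sim = np.broadcast_to(w, (n_sim, k))
    slopes_sim = _loo_slopes(bx_sim, by_sim, w_sim)
    resid2_sim = w_sim * (by_sim - slopes_sim * bx_sim) ** 2
    rss_sim = np.sum(resid2_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    exceed = np.sum(resid2_sim >= resid2_obs, axis=0)
    p_raw = (1 + exceed) / (n_sim + 1)
    p_adj = np.minimum(p_raw * k, 1.0)
    outlier_pvalues = {ids[j]: float(p_adj[j]) for j in range(k)}
    outliers = tuple(ids[j] for j in range(k) if p_adj[j] < outlier_alpha)

    estimate_raw = ivw(insts_sorted, model="fixed")
    estimate_corrected = None
    distortion_p = None
    if outliers:
        keep = [i for i in insts_sorted if i.snp_id not in outliers]
        if len(keep) >= 1:
            estimate_corrected = ivw(keep, model="fixed")
            if run_distortion:
                distortion_p = _distortion_test(
                    insts_sorted, estimate_raw.beta, estimate_corrected.beta,
                    len(outliers), n_sim, rng,
                )
    return PressoReport(
        rss_observed=rss_obs,
        global_pvalue=global_p,
        outlier_pvalues=outlier_pvalues,
        outliers=outliers,
        estimate_raw=estimate_raw,
        estimate_corrected=estimate_corrected,
        distortion_pvalue=distortion_p,
        n_sim=n_sim,
    )


def _distortion_test(
    insts: Sequence[HarmonizedInstrument],
    beta_raw: float,
    beta_corrected: float,
    n_outliers: int,
    n_sim: int,
    rng: np.random.Generator,
) -> float:
    """Compare the observed outlier-removal distortion to random removals.

    The observed distortion is the relative change of the causal
    estimate after removing the flagged outliers; the null distribution
    removes ``n_outliers`` instruments at random.
    """
    if beta_corrected == 0:
        return float("nan")
    obs = abs((beta_raw - beta_corrected) / beta_corrected)
    k = len(insts)
    sims = np.empty(n_sim)
    for b in range(n_sim):
        drop = set(rng.choice(k, size=n_outliers, replace=False).tolist())
        keep = [insts[j] for j in range(k) if j not in drop]
        beta_b = ivw(keep, model="fixed").beta
        sims[b] = abs((beta_raw - beta_b) / beta_b) if beta_b != 0 else np.inf
    return float((1 + np.sum(sims >= obs)) / (n_sim + 1))
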