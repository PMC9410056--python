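"""Instrument quality control.

Reduces a candidate SNP list to a set of valid instrumental variables:
genome-wide significance filter (relevance assumption), greedy LD
clumping against a user-supplied r² matrix, minor-allele-frequency
screen, Steiger directionality filter (variance explained in the
exposure must exceed that in the outcome), and an optional offline
confounder-exclusion list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .sumstats_io import GwasRecord, HarmonizedInstrument, exposure_record

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.1
DEFAULT_CLUMP_KB = 10_000
DEFAULT_MAF_LIMIT = 0.01


@dataclass(frozen=True)
class LdMatrix:
    """Square symmetric matrix of pairwise LD r² values with unit diagonal."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self):
        r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if r2.shape != (n, n):
            raise DataError(f"LD matrix shape {r2.shape} does not match {n} SNP ids")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise DataError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise DataError("LD matrix diagonal is not 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise DataError("LD r² values outside [0,1]")
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))

    def lookup(self, a: str, b: str) -> float:
        try:
            i = self.snp_ids.index(a)
            j = self.snp_ids.index(b)
        except ValueError as exc:
            raise DataError(f"SNP missing from LD matrix: {exc}") from exc
        return float(self.r2[i, j])

    @classmethod
    def from_file(cls, path: str | Path) -> "LdMatrix":
        """Read a delimited square matrix with SNP ids as header row and first column."""
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if list(df.index) != list(df.columns):
            raise DataError(f"LD matrix {path}: row and column ids differ")
        return cls(snp_ids=tuple(str(s) for s in df.columns), r2=df.to_numpy(dtype=float))

    def to_file(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(self.r2, index=list(self.snp_ids), columns=list(self.snp_ids)).to_csv(path, sep=sep)


@dataclass(frozen=True)
class SteigerResult:
    """Per-SNP directionality check: variance explained in exposure vs outcome."""

    snp_id: str
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool


def filter_significance(records: Sequence[GwasRecord], threshold: float = DEFAULT_P_THRESHOLD) -> list[GwasRecord]:
    """Keep records with p-value strictly below ``threshold``; order preserved."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold {threshold} outside (0,1]")
    return [r for r in records if r.pvalue < threshold]


def filter_maf(records: Sequence[GwasRecord], maf_limit: float = DEFAULT_MAF_LIMIT) -> list[GwasRecord]:
    """Keep records whose minor-allele frequency exceeds ``maf_limit``."""
    if not 0 < maf_limit < 0.5:
        raise ValueError(f"maf_limit {maf_limit} outside (0,0.5)")
    return [r for r in records if r.maf > maf_limit]


def _position(positions: Mapping[str, object], snp: str) -> tuple[object, float]:
    """Normalize a positions entry to (chromosome, base-pair)."""
    val = positions[snp]
    if isinstance(val, (tuple, list)):
        chrom, bp = val
        return chrom, float(bp)
    return 0, float(val)  # single unnamed chromosome


def ld_clump(
    records: Sequence[GwasRecord],
    ld: LdMatrix,
    r2_limit: float = DEFAULT_CLUMP_R2,
    positions: Mapping[str, object] | None = None,
    window_kb: float = DEFAULT_CLUMP_KB,
) -> list[GwasRecord]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly takes the remaining record with the smallest p-value and
    discards every remaining record on the same chromosome within
    ``window_kb`` kilobases whose r² with it exceeds ``r2_limit``.  The
    result is ordered by ascending p-value.  Ties are broken by smaller
    base-pair position, then lexicographic SNP id, so output is
    deterministic.

    ``positions`` maps SNP id to base-pair position, or to a
    ``(chromosome, base-pair)`` pair; cross-chromosome pairs are never
    clumped.  When omitted, all records are treated as co-located (every
    pair is within the window).
    """
    missing = [r.snp_id for r in records if r.snp_id not in ld.snp_ids]
    if missing:
        raise DataError(f"SNP(s) missing from LD matrix: {missing}")
    if positions is not None:
        missing = [r.snp_id for r in records if r.snp_id not in positions]
        if missing:
            raise DataError(f"SNP(s) missing from positions map: {missing}")

    def pos(r: GwasRecord) -> tuple[object, float]:
        if positions is None:
            return 0, 0.0
        return _position(positions, r.snp_id)

    remaining = sorted(records, key=lambda r: (r.pvalue, pos(r)[1], r.snp_id))
    kept: list[GwasRecord] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        chrom_i, bp_i = pos(index)
        survivors = []
        for r in remaining:
            chrom_j, bp_j = pos(r)
            in_window = chrom_i == chrom_j and abs(bp_i - bp_j) <= window_kb * 1000.0
            if in_window and ld.lookup(index.snp_id, r.snp_id) > r2_limit:
                continue
            survivors.append(r)
        remaining = survivors
    return kept


def steiger_test(
    inst: HarmonizedInstrument,
    outcome_is_binary: bool = True,
) -> SteigerResult:
    """Directionality filter comparing variance explained on the two sides.

    The exposure-side r² comes from the standard summary-statistic
    formula (see :func:`mrkit.meta_power.variance_explained`).  For a
    binary outcome the observed-scale approximation r² = z²/(z²+N) is
    used; algebraically the exposure-side formula reduces to the same
    expression, so the ``outcome_is_binary`` flag only documents intent.
    A SNP supports the assumed causal direction when it explains more
    variance in the exposure than in the outcome.
    """
    from .meta_power import variance_explained

    if inst.n_exposure <= 2 or inst.n_outcome <= 2:
        raise ValueError("Steiger test requires sample sizes > 2 on both sides")
    r2_exp = variance_explained(exposure_record(inst))
    z_out = inst.beta_outcome / inst.se_outcome
    r2_out = z_out**2 / (z_out**2 + inst.n_outcome)
    return SteigerResult(
        snp_id=inst.snp_id,
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        correct_direction=r2_exp > r2_out,
    )


@dataclass
class SelectionReport:
    """Audit trail of the instrument-selection pipeline."""

    n_input: int = 0
    n_after_significance: int = 0
    n_after_clump: int = 0
    n_after_maf: int = 0
    n_after_harmonization: int = 0
    n_after_steiger: int = 0
    n_after_exclusion_list: int = 0
    steiger: list[SteigerResult] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)


def select_instruments(
    exposure: Sequence[GwasRecord],
    outcome: Sequence[GwasRecord],
    *,
    ld: LdMatrix | None = None,
    positions: Mapping[str, object] | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    clump_r2: float = DEFAULT_CLUMP_R2,
    clump_kb: float = DEFAULT_CLUMP_KB,
    maf_limit: float = DEFAULT_MAF_LIMIT,
    palindrome_maf_limit: float = 0.42,
    exclude_snps: Sequence[str] = (),
    apply_steiger: bool = True,
    outcome_is_binary: bool = True,
    report: SelectionReport | None = None,
) -> list[HarmonizedInstrument]:
    """Full QC pipeline: significance → clump → MAF → harmonize → Steiger → exclusion list.

    A pure filter: the returned instruments are a subset of the
    harmonizable input SNPs, and the pipeline is idempotent.
    """
    from .sumstats_io import harmonize

    rep = report if report is not None else SelectionReport()
    rep.n_input = len(exposure)

    recs = filter_significance(exposure, p_threshold)
    rep.n_after_significance = len(recs)

    if ld is not None:
        recs = ld_clump(recs, ld, clump_r2, positions, clump_kb)
    rep.n_after_clump = len(recs)

    recs = filter_maf(recs, maf_limit)
    rep.n_after_maf = len(recs)

    insts = harmonize(recs, outcome, palindrome_maf_limit)
    rep.n_after_harmonization = len(insts)

    if apply_steiger:
        keep = []
        for inst in insts:
            res = steiger_test(inst, outcome_is_binary)
            rep.steiger.append(res)
            if res.correct_direction:
                keep.append(inst)
            else:
                rep.dropped[inst.snp_id] = "steiger: reverse direction"
        insts = keep
    rep.n_after_steiger = len(insts)

    if exclude_snps:
        excluded = set(exclude_snps)
        for inst in insts:
            if inst.snp_id in excluded:
                rep.dropped[inst.snp_id] = "confounder exclusion list"
        insts = [i for i in insts if i.snp_id not in excluded]
    rep.n_after_exclusion_list = len(insts)
    return insts
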