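"""Summary-statistic I/O and allele harmonization.

A two-sample MR analysis joins per-SNP associations from two independent
GWAS — one for the exposure, one for the outcome — and must first express
both effects per the same effect allele.  This module reads delimited
GWAS tables into validated :class:`GwasRecord` objects and aligns
exposure/outcome pairs into :class:`HarmonizedInstrument` objects,
flipping the outcome effect sign when the studies report opposite
alleles and resolving or excluding strand-ambiguous (palindromic) SNPs
by allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Conventional minor-allele-frequency ceiling below which a palindromic
#: SNP can still be oriented by comparing allele frequencies.
DEFAULT_PALINDROME_MAF_LIMIT = 0.42

#: Canonical column order of the harmonized table written by
#: :func:`write_harmonized`.
HARMONIZED_COLUMNS = (
    "snp_id", "ea", "oa", "eaf",
    "beta_exp", "se_exp", "p_exp", "n_exp",
    "beta_out", "se_out", "p_out", "n_out",
)

#: Default field -> column names for plain tables written by this package.
CANONICAL_SUMSTATS_COLUMNS = {
    "snp_id": "snp_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` — on the
    log-odds scale for binary traits, in trait units otherwise.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        ea, oa = self.effect_allele.upper(), self.other_allele.upper()
        if ea not in _BASES or oa not in _BASES:
            problems.append(f"alleles must be single bases ACGT, got {ea!r}/{oa!r}")
        elif ea == oa:
            problems.append("effect and other allele are identical")
        if not (0.0 < self.eaf < 1.0):
            problems.append(f"eaf {self.eaf} outside (0,1)")
        if not self.se > 0.0:
            problems.append(f"se {self.se} not > 0")
        if not (0.0 < self.pvalue <= 1.0):
            problems.append(f"pvalue {self.pvalue} outside (0,1]")
        if not self.n > 0:
            problems.append(f"n {self.n} not positive")
        return problems

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome effect pair expressed per the same effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf_exposure: float
    beta_exposure: float
    se_exposure: float
    pvalue_exposure: float
    n_exposure: int
    beta_outcome: float
    se_outcome: float
    pvalue_outcome: float
    n_outcome: int


@dataclass(frozen=True)
class Exclusion:
    """Marker for a SNP dropped during harmonization, with the reason."""

    snp_id: str
    reason: str


@dataclass(frozen=True)
class RowIssue:
    """Per-row validation report emitted by :func:`read_sumstats`."""

    row: int
    snp_id: str
    problems: tuple[str, ...]


def _coerce_row(row: Mapping[str, object]) -> GwasRecord | list[str]:
    try:
        return GwasRecord(
            snp_id=str(row["snp_id"]),
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            eaf=float(row["eaf"]),  # type: ignore[arg-type]
            beta=float(row["beta"]),  # type: ignore[arg-type]
            se=float(row["se"]),  # type: ignore[arg-type]
            pvalue=float(row["pvalue"]),  # type: ignore[arg-type]
            n=int(float(row["n"])),  # type: ignore[arg-type]
        )
    except (TypeError, ValueError) as exc:
        return [f"non-numeric field: {exc}"]


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    issues: list[RowIssue] | None = None,
) -> list[GwasRecord]:
    """Read a delimited GWAS summary-statistics table.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row; the delimiter is
        auto-detected.
    column_map
        Mapping from file column name to record field name
        (``snp_id``, ``effect_allele``, ``other_allele``, ``eaf``,
        ``beta``, ``se``, ``pvalue``, ``n``).  Defaults to the canonical
        names, i.e. an identity mapping.
    issues
        Optional list that receives a :class:`RowIssue` for every
        rejected row; rejects are also logged as warnings.

    Returns
    -------
    One :class:`GwasRecord` per valid data row, in file order.  Rows that
    violate record invariants (se <= 0, eaf outside (0,1), indel or
    multi-allelic alleles, non-numeric effect sizes ...) are dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map is None:
        column_map = {v: k for k, v in CANONICAL_SUMSTATS_COLUMNS.items()}
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise ConfigError(
            f"mapped column(s) {missing} not present in {path}; found {list(df.columns)}"
        )
    fields = set(column_map.values())
    required = set(CANONICAL_SUMSTATS_COLUMNS)
    if fields != required:
        raise ConfigError(
            f"column_map must cover exactly the fields {sorted(required)}, got {sorted(fields)}"
        )
    sub = df[list(column_map)].rename(columns=dict(column_map))

    records: list[GwasRecord] = []
    for i, row in enumerate(sub.to_dict(orient="records")):
        rec = _coerce_row(row)
        if isinstance(rec, GwasRecord):
            problems = rec.validate()
            if not problems:
                records.append(rec)
                continue
        else:
            problems = rec
        issue = RowIssue(row=i, snp_id=str(row.get("snp_id", "?")), problems=tuple(problems))
        if issues is not None:
            issues.append(issue)
        logger.warning("rejected row %d (%s): %s", issue.row, issue.snp_id, "; ".join(problems))
    return records


def write_sumstats(records: Iterable[GwasRecord], path: str | Path, sep: str = "\t") -> None:
    """Write records as a delimited table with canonical column names."""
    rows = [
        {
            "snp_id": r.snp_id,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": r.eaf,
            "beta": r.beta,
            "se": r.se,
            "pvalue": r.pvalue,
            "n": r.n,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(CANONICAL_SUMSTATS_COLUMNS)).to_csv(path, sep=sep, index=False)


def is_palindromic(record: GwasRecord) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G, any order)."""
    pair = {record.effect_allele.upper(), record.other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def harmonize_pair(
    exposure: GwasRecord,
    outcome: GwasRecord,
    palindrome_maf_limit: float = DEFAULT_PALINDROME_MAF_LIMIT,
) -> HarmonizedInstrument | Exclusion:
    """Align one exposure/outcome record pair onto the exposure's effect allele.

    Non-palindromic pairs: if the outcome reports the same effect allele
    the effects are copied; if it reports the swapped orientation the
    outcome beta sign is flipped and its frequency complemented; any
    other allele set is excluded.  Palindromic pairs cannot be oriented
    by allele letters, so they are oriented by frequency agreement when
    the minor-allele frequency is at most ``palindrome_maf_limit`` and
    excluded otherwise (near 0.5 the frequencies carry no strand
    information).
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValueError(f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}")

    ea, oa = exposure.effect_allele.upper(), exposure.other_allele.upper()
    out_ea, out_oa = outcome.effect_allele.upper(), outcome.other_allele.upper()

    if is_palindromic(exposure):
        if {out_ea, out_oa} != {ea, oa}:
            return Exclusion(exposure.snp_id, f"incompatible alleles {out_ea}/{out_oa} vs {ea}/{oa}")
        # Both sides' frequencies must be informative to orient the strand.
        if max(min(exposure.eaf, 1 - exposure.eaf), min(outcome.eaf, 1 - outcome.eaf)) > palindrome_maf_limit:
            return Exclusion(
                exposure.snp_id,
                f"palindromic with MAF above {palindrome_maf_limit}: frequency cannot resolve strand",
            )
        # Frequencies on the same side of 0.5 indicate the same allele.
        flip = (exposure.eaf - 0.5) * (outcome.eaf - 0.5) < 0
    elif (out_ea, out_oa) == (ea, oa):
        flip = False
    elif (out_ea, out_oa) == (oa, ea):
        flip = True
    else:
        return Exclusion(exposure.snp_id, f"incompatible alleles {out_ea}/{out_oa} vs {ea}/{oa}")

    beta_out = -outcome.beta if flip else outcome.beta
    return HarmonizedInstrument(
        snp_id=exposure.snp_id,
        effect_allele=ea,
        other_allele=oa,
        eaf_exposure=exposure.eaf,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        pvalue_exposure=exposure.pvalue,
        n_exposure=exposure.n,
        beta_outcome=beta_out,
        se_outcome=outcome.se,
        pvalue_outcome=outcome.pvalue,
        n_outcome=outcome.n,
    )


def harmonize(
    exposure: Sequence[GwasRecord],
    outcome: Sequence[GwasRecord],
    palindrome_maf_limit: float = DEFAULT_PALINDROME_MAF_LIMIT,
    *,
    exclusions: list[Exclusion] | None = None,
) -> list[HarmonizedInstrument]:
    """Harmonize all exposure records that have a same-id outcome record.

    Exposure SNPs missing from the outcome table are excluded with a
    marker (no proxy lookup is attempted).  Order follows the exposure
    list.
    """
    by_id = {r.snp_id: r for r in outcome}
    out: list[HarmonizedInstrument] = []
    for exp in exposure:
        if exp.snp_id not in by_id:
            result: HarmonizedInstrument | Exclusion = Exclusion(exp.snp_id, "absent from outcome table")
        else:
            result = harmonize_pair(exp, by_id[exp.snp_id], palindrome_maf_limit)
        if isinstance(result, Exclusion):
            if exclusions is not None:
                exclusions.append(result)
            logger.info("excluded %s: %s", result.snp_id, result.reason)
        else:
            out.append(result)
    return out


def exposure_record(inst: HarmonizedInstrument) -> GwasRecord:
    """View the exposure side of a harmonized instrument as a GwasRecord."""
    return GwasRecord(
        snp_id=inst.snp_id,
        effect_allele=inst.effect_allele,
        other_allele=inst.other_allele,
        eaf=inst.eaf_exposure,
        beta=inst.beta_exposure,
        se=inst.se_exposure,
        pvalue=inst.pvalue_exposure,
        n=inst.n_exposure,
    )


def write_harmonized(insts: Iterable[HarmonizedInstrument], path: str | Path, sep: str = "\t") -> None:
    rows = [
        {
            "snp_id": h.snp_id, "ea": h.effect_allele, "oa": h.other_allele,
            "eaf": h.eaf_exposure,
            "beta_exp": h.beta_exposure, "se_exp": h.se_exposure,
            "p_exp": h.pvalue_exposure, "n_exp": h.n_exposure,
            "beta_out": h.beta_outcome, "se_out": h.se_outcome,
            "p_out": h.pvalue_outcome, "n_out": h.n_outcome,
        }
        for h in insts
    ]
    pd.DataFrame(rows, columns=list(HARMONIZED_COLUMNS)).to_csv(path, sep=sep, index=False)


def read_harmonized(path: str | Path) -> list[HarmonizedInstrument]:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in HARMONIZED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"harmonized table {path} lacks column(s) {missing}")
    return [
        HarmonizedInstrument(
            snp_id=str(r.snp_id), effect_allele=str(r.ea), other_allele=str(r.oa),
            eaf_exposure=float(r.eaf),
            beta_exposure=float(r.beta_exp), se_exposure=float(r.se_exp),
            pvalue_exposure=float(r.p_exp), n_exposure=int(r.n_exp),
            beta_outcome=float(r.beta_out), se_outcome=float(r.se_out),
            pvalue_outcome=float(r.p_out), n_outcome=int(r.n_out),
        )
        for r in df.itertuples(index=False)
    ]
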