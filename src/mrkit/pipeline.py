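"""Config-driven end-to-end study driver.

``run_study`` executes the full analysis surface on real or simulated
summary statistics: harmonization, instrument selection, the estimator
suite, heterogeneity and MR-PRESSO diagnostics, fixed-effect
meta-analysis of cohorts sharing an outcome, and variance-explained /
power tables.  Every threshold, seed and method default actually used
is recorded in a deterministic JSON manifest whose hash certifies
bit-identical reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import presets
from .errors import ConfigError, EstimationError
from .estimators import MrEstimate, egger, heterogeneity, ivw, weighted_median
from .iv_selection import LdMatrix, SelectionReport, select_instruments
from .meta_power import (
    PowerSpec,
    detectable_or,
    meta_fixed,
    meta_heterogeneity,
    total_variance_explained,
)
from .presso import PressoReport, presso_global
from .sumstats_io import (
    GwasRecord,
    HarmonizedInstrument,
    exposure_record,
    read_sumstats,
    write_harmonized,
)
from .synthetic import SyntheticConfig, generate, generate_outcome_for_cohort

logger = logging.getLogger(__name__)

KNOWN_METHODS = ("ivw_fixed", "ivw_random", "weighted_median", "egger", "presso")
DEFAULT_METHODS = list(KNOWN_METHODS)


@dataclass
class OutcomeSpec:
    """One outcome dataset: a cohort name, outcome label and its sample sizes."""

    name: str
    outcome: str
    n: int
    cases: int
    path: str | None = None  # None when simulated


@dataclass
class StudyConfig:
    """Structured configuration of one end-to-end run."""

    exposure_path: str | None = None
    exposure_column_map: Mapping[str, str] | None = None
    outcome_column_map: Mapping[str, str] | None = None
    outcomes: list[OutcomeSpec] = field(default_factory=list)
    simulate: SyntheticConfig | None = None

    ld_matrix_path: str | None = None
    positions_path: str | None = None
    exclude_snps_path: str | None = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.1
    clump_kb: float = 10_000
    maf_limit: float = 0.01
    palindrome_maf_limit: float = 0.42
    apply_steiger: bool = True

    methods: list[str] = field(default_factory=lambda: list(DEFAULT_METHODS))
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    alpha: float = 0.05
    target_power: float = 0.8
    bonferroni_alpha: float = presets.BONFERRONI_ALPHA
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "StudyConfig":
        cfg = cls()
        sim = raw.get("simulate")
        if sim is not None:
            cohorts = sim.pop("cohorts", None)
            cfg.simulate = SyntheticConfig(**sim)
            cfg.outcomes = _resolve_cohorts(cohorts)
            # Simulated instruments emulate an already-selected panel, so the
            # discovery-stage significance filter is vacuous unless the
            # config explicitly sets selection.p_threshold.
            if "p_threshold" not in raw.get("selection", {}):
                cfg.p_threshold = 1.0
        if "exposure" in raw:
            exp = raw["exposure"]
            cfg.exposure_path = exp.get("path")
            cfg.exposure_column_map = exp.get("column_map")
        for spec in raw.get("outcomes", []):
            cfg.outcomes.append(OutcomeSpec(
                name=spec["name"], outcome=spec["outcome"],
                n=int(spec["n"]), cases=int(spec["cases"]),
                path=spec.get("path"),
            ))
        sel = raw.get("selection", {})
        for key, attr in [
            ("p_threshold", "p_threshold"), ("clump_r2", "clump_r2"),
            ("clump_kb", "clump_kb"), ("maf", "maf_limit"),
            ("palindrome_maf_limit", "palindrome_maf_limit"),
            ("ld_matrix", "ld_matrix_path"), ("positions", "positions_path"),
            ("exclude_snps", "exclude_snps_path"), ("apply_steiger", "apply_steiger"),
        ]:
            if key in sel:
                setattr(cfg, attr, sel[key])
        for key in ("methods", "n_boot", "n_sim", "seed", "alpha",
                    "target_power", "bonferroni_alpha", "output_dir"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "outcome_column_map" in raw:
            cfg.outcome_column_map = raw["outcome_column_map"]
        return cfg


def _resolve_cohorts(cohorts: Sequence[Any] | None) -> list[OutcomeSpec]:
    if cohorts is None:
        cohorts = ["cardiogram_cad"]
    specs = []
    for c in cohorts:
        if isinstance(c, str):
            preset = presets.OUTCOME_COHORTS[c]
            specs.append(OutcomeSpec(preset.name, preset.outcome, preset.n, preset.cases))
        else:
            specs.append(OutcomeSpec(c["name"], c["outcome"], int(c["n"]), int(c["cases"])))
    return specs


@dataclass
class OutcomeResult:
    """All per-outcome-dataset results."""

    spec: OutcomeSpec
    instruments: list[HarmonizedInstrument]
    selection: SelectionReport
    estimates: list[MrEstimate]
    het: Any  # HeterogeneityReport | None
    presso: PressoReport | None
    egger_intercept: MrEstimate | None


@dataclass
class ResultsBundle:
    """Everything one ``run_study`` call produced."""

    config: StudyConfig
    outcome_results: list[OutcomeResult]
    meta_estimates: dict[str, MrEstimate]
    meta_het: dict[str, Any]
    r2_total: float
    power_table: pd.DataFrame
    manifest: dict[str, Any]

    def estimates_table(self) -> pd.DataFrame:
        """Numeric + formatted per-method estimates, Table-2 layout."""
        rows = []
        for res in self.outcome_results:
            for est in res.estimates:
                rows.append({
                    "data_source": res.spec.name,
                    "outcome": res.spec.outcome,
                    "n_snps": est.n_snps,
                    "method": est.method,
                    "beta": est.beta,
                    "se": est.se,
                    "or": est.odds_ratio,
                    "or_ci_low": est.or_ci_low,
                    "or_ci_high": est.or_ci_high,
                    "pvalue": est.pvalue,
                    "or_fmt": f"{est.odds_ratio:.2f}",
                    "ci_fmt": f"{est.or_ci_low:.2f}, {est.or_ci_high:.2f}",
                    "p_fmt": _fmt_p(est.pvalue),
                    "significant": est.pvalue < self.config.bonferroni_alpha,
                })
        return pd.DataFrame(rows)

    def diagnostics_table(self) -> pd.DataFrame:
        """Heterogeneity / pleiotropy diagnostics, Table-3 layout."""
        rows = []
        for res in self.outcome_results:
            rows.append({
                "data_source": res.spec.name,
                "outcome": res.spec.outcome,
                "n_snps": len(res.instruments),
                "i2": res.het.i2 if res.het else float("nan"),
                "q": res.het.q if res.het else float("nan"),
                "q_pvalue": res.het.q_pvalue if res.het else float("nan"),
                "egger_intercept": res.egger_intercept.beta if res.egger_intercept else float("nan"),
                "egger_intercept_p": res.egger_intercept.pvalue if res.egger_intercept else float("nan"),
                "presso_global_p": res.presso.global_pvalue if res.presso else float("nan"),
                "presso_n_outliers": len(res.presso.outliers) if res.presso else 0,
            })
        return pd.DataFrame(rows)

    def meta_table(self) -> pd.DataFrame:
        rows = []
        for outcome, est in self.meta_estimates.items():
            het = self.meta_het.get(outcome)
            rows.append({
                "outcome": outcome,
                "method": est.method,
                "or": est.odds_ratio,
                "or_ci_low": est.or_ci_low,
                "or_ci_high": est.or_ci_high,
                "pvalue": est.pvalue,
                "q": het.q if het else float("nan"),
                "q_pvalue": het.q_pvalue if het else float("nan"),
                "i2": het.i2 if het else float("nan"),
                "significant": est.pvalue < self.config.bonferroni_alpha,
            })
        return pd.DataFrame(rows)

    def manifest_hash(self) -> str:
        payload = json.dumps(self.manifest, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()


def _fmt_p(p: float) -> str:
    return f"{p:.3g}" if p >= 1e-3 else f"{p:.2e}"


def _load_exposure(cfg: StudyConfig) -> list[GwasRecord]:
    if cfg.exposure_path is None:
        raise ConfigError("config names neither an exposure file nor a simulate block")
    return read_sumstats(cfg.exposure_path, cfg.exposure_column_map)


def run_study(config: StudyConfig) -> ResultsBundle:
    """Execute harmonize → select → estimate → diagnose → meta → power."""
    t0 = time.monotonic()
    if not config.methods:
        raise ConfigError("method list is empty")
    unknown = [m for m in config.methods if m not in KNOWN_METHODS]
    if unknown:
        raise ConfigError(f"unknown method(s) {unknown}; known: {list(KNOWN_METHODS)}")
    if not config.outcomes:
        raise ConfigError("config names no outcome datasets")

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        exposure, first_outcome, truth = generate(config.simulate)
        outcome_tables = [first_outcome]
        for idx, spec in enumerate(config.outcomes[1:], start=1):
            child_seed = (config.simulate.seed * 1_000_003 + idx) % (2**31)
            outcome_tables.append(generate_outcome_for_cohort(
                exposure, truth, spec.n, spec.cases / spec.n, child_seed,
                pleiotropy_mean=config.simulate.pleiotropy_mean,
                pleiotropy_sd=config.simulate.pleiotropy_sd,
            ))
        # The generated first outcome uses the simulate block's sizes; keep
        # the declared cohort spec authoritative for power calculations.
    else:
        exposure = _load_exposure(config)
        outcome_tables = []
        for spec in config.outcomes:
            if spec.path is None:
                raise ConfigError(f"outcome {spec.name}/{spec.outcome} has no path")
            outcome_tables.append(read_sumstats(spec.path, config.outcome_column_map))

    ld = LdMatrix.from_file(config.ld_matrix_path) if config.ld_matrix_path else None
    positions = None
    if config.positions_path:
        pos_df = pd.read_csv(config.positions_path, sep=None, engine="python")
        positions = dict(zip(pos_df.iloc[:, 0].astype(str), pos_df.iloc[:, 1]))
    exclude: list[str] = []
    if config.exclude_snps_path:
        exclude = [ln.strip() for ln in open(config.exclude_snps_path) if ln.strip()]

    # --- per-outcome analysis --------------------------------------------
    results: list[OutcomeResult] = []
    for spec, outcome_records in zip(config.outcomes, outcome_tables):
        stage = f"{spec.name}/{spec.outcome}"
        report = SelectionReport()
        insts = select_instruments(
            exposure, outcome_records,
            ld=ld, positions=positions,
            p_threshold=config.p_threshold, clump_r2=config.clump_r2,
            clump_kb=config.clump_kb, maf_limit=config.maf_limit,
            palindrome_maf_limit=config.palindrome_maf_limit,
            exclude_snps=exclude, apply_steiger=config.apply_steiger,
            report=report,
        )
        if not insts:
            raise EstimationError(f"stage {stage}: no instruments survived selection")

        estimates: list[MrEstimate] = []
        egger_intercept = None
        presso_report = None
        try:
            for method in config.methods:
                if method == "ivw_fixed":
                    estimates.append(ivw(insts, model="fixed"))
                elif method == "ivw_random":
                    estimates.append(ivw(insts, model="random"))
                elif method == "weighted_median":
                    estimates.append(weighted_median(insts, n_boot=config.n_boot, seed=config.seed))
                elif method == "egger":
                    slope, intercept = egger(insts)
                    estimates.append(slope)
                    egger_intercept = intercept
                elif method == "presso":
                    presso_report = presso_global(insts, n_sim=config.n_sim, seed=config.seed)
                    est = presso_report.estimate_corrected or presso_report.estimate_raw
                    label = "presso_corrected" if presso_report.estimate_corrected else "presso_raw"
                    estimates.append(MrEstimate(**{**est.__dict__, "method": label}))
        except EstimationError as exc:
            raise EstimationError(
                f"stage {stage}: {exc} (instruments: {[i.snp_id for i in insts]})"
            ) from exc
        het = heterogeneity(insts) if len(insts) >= 2 else None
        results.append(OutcomeResult(spec, insts, report, estimates, het, presso_report, egger_intercept))
        logger.info("stage %s done in %.2fs (%d instruments)", stage, time.monotonic() - t0, len(insts))

    # --- meta-analysis per outcome label ---------------------------------
    primary = "ivw_fixed" if "ivw_fixed" in config.methods else config.methods[0]
    meta_estimates: dict[str, MrEstimate] = {}
    meta_het: dict[str, Any] = {}
    by_outcome: dict[str, list[MrEstimate]] = {}
    for res in results:
        est = next((e for e in res.estimates if e.method.startswith(primary)), res.estimates[0])
        by_outcome.setdefault(res.spec.outcome, []).append(est)
    for outcome, ests in by_outcome.items():
        if len(ests) >= 2:
            meta_estimates[outcome] = meta_fixed(ests)
            meta_het[outcome] = meta_heterogeneity(ests)

    # --- variance explained & power --------------------------------------
    first = results[0]
    r2_total = total_variance_explained([exposure_record(i) for i in first.instruments])
    power_rows = []
    for res in results:
        spec = res.spec
        pspec = PowerSpec(
            n_outcome=spec.n, n_cases=spec.cases, r2_total=r2_total,
            alpha=config.alpha, target_power=config.target_power,
        )
        or_up, or_down = detectable_or(pspec)
        power_rows.append({
            "data_source": spec.name, "outcome": spec.outcome,
            "n": spec.n, "cases": spec.cases,
            "case_fraction": spec.cases / spec.n,
            "r2_total": r2_total,
            "detectable_or_up": or_up, "detectable_or_down": or_down,
        })
    power_table = pd.DataFrame(power_rows)

    manifest = _build_manifest(config, results, r2_total)
    bundle = ResultsBundle(
        config=config,
        outcome_results=results,
        meta_estimates=meta_estimates,
        meta_het=meta_het,
        r2_total=r2_total,
        power_table=power_table,
        manifest=manifest,
    )
    if config.output_dir:
        _write_bundle(bundle, Path(config.output_dir))
    logger.info("run_study complete in %.2fs", time.monotonic() - t0)
    return bundle


def _build_manifest(config: StudyConfig, results: list[OutcomeResult], r2_total: float) -> dict:
    from . import __version__

    return {
        "mrkit_version": __version__,
        "thresholds": {
            "p_threshold": config.p_threshold,
            "clump_r2": config.clump_r2,
            "clump_kb": config.clump_kb,
            "maf_limit": config.maf_limit,
            "palindrome_maf_limit": config.palindrome_maf_limit,
            "bonferroni_alpha": config.bonferroni_alpha,
            "presso_outlier_alpha": 0.05,
        },
        "seeds": {"seed": config.seed,
                  "simulate_seed": config.simulate.seed if config.simulate else None},
        "methods": list(config.methods),
        "decisions": {
            "ivw_random_dispersion": "multiplicative, unfloored",
            "egger_inference": "t(k-2), instruments oriented to positive exposure effect",
            "weighted_median_bootstrap": {"n_boot": config.n_boot, "resamples": "exposure and outcome"},
            "presso": {"n_sim": config.n_sim, "empirical_p": "(1+#)/ (n_sim+1)"},
            "steiger_outcome_r2": "z^2/(z^2+N) observed scale",
            "palindrome_resolution": "frequency when both MAFs <= limit, else excluded",
        },
        "simulate": asdict(config.simulate) if config.simulate else None,
        "outcomes": [asdict(r.spec) for r in results],
        "selection_counts": [asdict(r.selection) | {"steiger": len(r.selection.steiger)} for r in results],
        "n_instruments": [len(r.instruments) for r in results],
        "r2_total": r2_total,
    }


def _write_bundle(bundle: ResultsBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.estimates_table().to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    bundle.diagnostics_table().to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
    if len(bundle.meta_estimates) > 0:
        bundle.meta_table().to_csv(outdir / "meta.tsv", sep="\t", index=False)
    bundle.power_table.to_csv(outdir / "power.tsv", sep="\t", index=False)
    for res in bundle.outcome_results:
        tag = f"{res.spec.name}_{res.spec.outcome}".replace(" ", "_")
        write_harmonized(res.instruments, outdir / f"harmonized_{tag}.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True, default=str)


def export_plot_data(bundle: ResultsBundle, outdir: str | Path) -> list[Path]:
    """Write the numeric data behind scatter and forest figures.

    Per outcome dataset: a scatter file with one row per SNP
    (beta_exposure, se_exposure, beta_outcome, se_outcome) and a slopes
    file with one fitted line per method (slope, intercept).  One forest
    file holds per-cohort and meta odds ratios with confidence bounds.
    """
    if not bundle.outcome_results or not bundle.config.methods:
        raise ConfigError("bundle contains no estimates to export")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for res in bundle.outcome_results:
        tag = f"{res.spec.name}_{res.spec.outcome}".replace(" ", "_")
        scatter = pd.DataFrame([
            {
                "snp_id": i.snp_id,
                "beta_exposure": i.beta_exposure, "se_exposure": i.se_exposure,
                "beta_outcome": i.beta_outcome, "se_outcome": i.se_outcome,
            }
            for i in res.instruments
        ])
        p = outdir / f"scatter_{tag}.tsv"
        scatter.to_csv(p, sep="\t", index=False)
        written.append(p)
        slope_rows = []
        for est in res.estimates:
            intercept = 0.0
            if est.method == "egger_slope" and res.egger_intercept is not None:
                intercept = res.egger_intercept.beta
            slope_rows.append({"method": est.method, "slope": est.beta, "intercept": intercept})
        p = outdir / f"slopes_{tag}.tsv"
        pd.DataFrame(slope_rows).to_csv(p, sep="\t", index=False)
        written.append(p)

    forest_rows = []
    primary = "ivw_fixed" if "ivw_fixed" in bundle.config.methods else bundle.config.methods[0]
    for res in bundle.outcome_results:
        est = next((e for e in res.estimates if e.method.startswith(primary)), res.estimates[0])
        forest_rows.append({
            "label": res.spec.name, "outcome": res.spec.outcome,
            "or": est.odds_ratio, "or_ci_low": est.or_ci_low, "or_ci_high": est.or_ci_high,
            "pvalue": est.pvalue,
        })
    for outcome, est in bundle.meta_estimates.items():
        forest_rows.append({
            "label": "Meta (fixed)", "outcome": outcome,
            "or": est.odds_ratio, "or_ci_low": est.or_ci_low, "or_ci_high": est.or_ci_high,
            "pvalue": est.pvalue,
        })
    p = outdir / "forest.tsv"
    pd.DataFrame(forest_rows).to_csv(p, sep="\t", index=False)
    written.append(p)
    return written
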