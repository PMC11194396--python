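"""Druggable-genome MR study orchestration.

The full cascade, per gene with at least one selectable instrument:

1. discovery MR against the discovery disease outcome (Wald ratio for a
   single instrument, IVW otherwise), Bonferroni-prioritized at
   0.05 / (number of genes with instruments);
2. Steiger directionality filtering and re-estimation on the retained
   instruments;
3. sensitivity battery (MR-Egger intercept, Cochran's Q);
4. Bayesian colocalization of the full cis region (skipped for genes whose
   instruments are trans);
5. reverse MR (disease as exposure) for the prioritized genes;
6. replication in a family of validation outcomes (same-variant or
   significant-variant strategy) with family-wise Bonferroni verdicts and
   a directional-consistency requirement;
7. an unadjusted p < 0.05 biomarker scan for the prioritized genes.

A gene is *prioritized* when its post-Steiger discovery p-value passes the
Bonferroni threshold, at least one instrument survives Steiger filtering,
and the colocalization decision is positive (trans genes, for which
colocalization is not attempted, must pass the other two filters only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coloc import Colocalization, ColocResults, RegionPair
from .instruments import InstrumentSet, LDMatrix, SelectionConfig, select_instruments
from .mr import (
    MendelianRandomization,
    MRResults,
    ReverseMRResult,
    SensitivityResult,
    SteigerResult,
    bonferroni_threshold,
    harmonize_tables,
    reverse_mr,
)
from .sumstats import (
    GeneRegion,
    SumstatsTable,
    read_gene_list,
    read_gene_regions,
    read_sumstats,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "Study",
    "TargetReport",
    "load_study",
    "run_discovery",
    "run_validation",
    "run_biomarker_scan",
    "make_report",
    "run_study",
]


@dataclass
class StudyConfig:
    """All inputs and thresholds of one study run."""

    data_dir: str = "."
    exposure: str = "exposure.tsv"
    outcome: str = "outcome_disease.tsv"
    genes: str = "genes.tsv"
    gene_list: str = "druggable_genes.txt"
    ld_dir: str = "ld"
    validation_outcomes: list[str] = field(default_factory=list)
    biomarker_outcomes: list[str] = field(default_factory=list)
    outcome_trait_type: str = "binary"
    # thresholds
    p_max: float = 5e-8
    maf_min: float = 0.01
    r2_max: float = 0.001
    window_kb: float = 10_000.0
    f_min: float = 10.0
    alpha: float = 0.05
    coloc_threshold: float = 0.8
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    reverse_alpha: float = 0.05
    biomarker_alpha: float = 0.05
    biomarker_bonferroni: bool = False
    require_directional_consistency: bool = True
    ivw_mode: str = "multiplicative_random"
    validation_strategy: str = "same_variant"
    output_dir: str = "results"
    seed: int = 0

    @property
    def selection(self) -> SelectionConfig:
        return SelectionConfig(
            p_max=self.p_max,
            maf_min=self.maf_min,
            r2_max=self.r2_max,
            window_kb=self.window_kb,
            f_min=self.f_min,
        )

    def path(self, name: str) -> Path:
        return Path(self.data_dir) / name

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class Study:
    """Loaded study inputs."""

    exposure: SumstatsTable
    outcome: SumstatsTable
    genes: list[GeneRegion]
    gene_list: list[str]
    ld: dict[str, LDMatrix]
    validation: list[SumstatsTable] = field(default_factory=list)
    biomarkers: list[SumstatsTable] = field(default_factory=list)


def load_study(config: StudyConfig) -> Study:
    """Load every table a study run references; missing files are fatal."""
    exposure = read_sumstats(config.path(config.exposure), trait_id="exposure")
    outcome = read_sumstats(
        config.path(config.outcome),
        trait_id=Path(config.outcome).stem.removeprefix("outcome_"),
        trait_type=config.outcome_trait_type,
        n_cases=0 if config.outcome_trait_type == "binary" else None,
        n_controls=0 if config.outcome_trait_type == "binary" else None,
    )
    genes = read_gene_regions(config.path(config.genes))
    gene_list = read_gene_list(config.path(config.gene_list))
    ld = {}
    for gene in genes:
        p = config.path(config.ld_dir) / f"{gene.gene_id}.tsv"
        if p.exists():
            ld[gene.gene_id] = LDMatrix.read_tsv(p)
    validation = [
        read_sumstats(
            config.path(name),
            trait_id=Path(name).stem.removeprefix("outcome_"),
            trait_type=config.outcome_trait_type,
            n_cases=0 if config.outcome_trait_type == "binary" else None,
            n_controls=0 if config.outcome_trait_type == "binary" else None,
        )
        for name in config.validation_outcomes
    ]
    biomarkers = [
        read_sumstats(config.path(name),
                      trait_id=Path(name).stem.removeprefix("outcome_"))
        for name in config.biomarker_outcomes
    ]
    return Study(exposure, outcome, genes, gene_list, ld, validation, biomarkers)


@dataclass
class TargetReport:
    """Everything the study concludes about one gene."""

    gene: GeneRegion
    instrument_set: InstrumentSet | None = None
    discovery: MRResults | None = None              # all selected instruments
    discovery_post_steiger: MRResults | None = None  # after Steiger removal
    steiger_results: list[SteigerResult] = field(default_factory=list)
    steiger_pass: bool = False
    sensitivity: SensitivityResult | None = None
    coloc: ColocResults | None = None               # None for trans genes
    reverse: ReverseMRResult | None = None
    bonferroni_m: int = 0
    bonferroni_threshold: float = float("nan")
    prioritized: bool = False
    validation: dict[str, MRResults] = field(default_factory=dict)
    validation_verdicts: dict[str, bool] = field(default_factory=dict)
    not_validatable: list[str] = field(default_factory=list)
    replicated: bool = False
    replication_count: int = 0
    biomarker: dict[str, MRResults] = field(default_factory=dict)
    biomarker_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def n_instruments(self) -> int:
        return len(self.instrument_set) if self.instrument_set else 0

    @property
    def bidirectional(self) -> bool:
        return self.reverse is not None and self.reverse.significant


def _fit_auto(insts, gene_id, outcome_id, ivw_mode) -> MRResults:
    model = MendelianRandomization(insts, gene_id=gene_id, outcome_id=outcome_id)
    if model.k == 1:
        return model.fit("wald_ratio")
    return model.fit("ivw_fe" if ivw_mode == "fixed" else "ivw_mre")


def run_discovery(study: Study, config: StudyConfig) -> list[TargetReport]:
    """Stages 1-5 of the cascade for every gene in the druggable list."""
    if not study.gene_list:
        raise ValueError("empty gene list: nothing to analyse")
    by_id = {g.gene_id: g for g in study.genes}
    reports: list[TargetReport] = []

    for gene_id in study.gene_list:
        gene = by_id.get(gene_id)
        if gene is None or gene_id not in study.ld:
            logger.warning("gene %s lacks region metadata or LD; skipped", gene_id)
            continue
        ld = study.ld[gene_id]
        region_slice = study.exposure.subset(ld.variant_ids)
        report = TargetReport(gene=gene)
        report.instrument_set = select_instruments(
            region_slice, gene, ld, config.selection
        )
        reports.append(report)
        if len(report.instrument_set) == 0:
            continue

        insts, _ = harmonize_tables(
            study.exposure, study.outcome, report.instrument_set.variant_ids
        )
        if not insts:
            report.instrument_set.instruments.clear()
            continue
        outcome_id = study.outcome.trait_id
        report.discovery = _fit_auto(insts, gene_id, outcome_id, config.ivw_mode)

        model = MendelianRandomization(insts, gene_id=gene_id, outcome_id=outcome_id)
        filtered, report.steiger_results = model.steiger_filter()
        report.steiger_pass = filtered is not None
        if filtered is not None:
            report.discovery_post_steiger = _fit_auto(
                filtered.instruments, gene_id, outcome_id, config.ivw_mode
            )
        report.sensitivity = model.sensitivity()

        if not report.instrument_set.any_trans and not gene.is_trans:
            region_insts, _ = harmonize_tables(
                study.exposure, study.outcome, ld.variant_ids
            )
            if region_insts:
                region = RegionPair(
                    variant_ids=[i.variant_id for i in region_insts],
                    beta1=np.array([i.beta_exp for i in region_insts]),
                    se1=np.array([i.se_exp for i in region_insts]),
                    beta2=np.array([i.beta_out for i in region_insts]),
                    se2=np.array([i.se_out for i in region_insts]),
                    gene=gene,
                    trait1_type="quantitative",
                    trait2_type=study.outcome.trait_type,
                    p1=config.coloc_p1,
                    p2=config.coloc_p2,
                    p12=config.coloc_p12,
                )
                report.coloc = Colocalization(region, config.coloc_threshold).fit()

    tested = [r for r in reports if r.discovery is not None]
    if not tested:
        raise ValueError("no gene has a selectable, harmonizable instrument")
    m = len(tested)
    thresh = bonferroni_threshold(config.alpha, m)
    for r in reports:
        r.bonferroni_m = m
        r.bonferroni_threshold = thresh
        est = r.discovery_post_steiger
        coloc_ok = (
            r.coloc.colocalized
            if r.coloc is not None
            else (r.instrument_set.any_trans or r.gene.is_trans
                  if r.instrument_set else False)
        )
        r.prioritized = (
            r.steiger_pass
            and est is not None
            and est.pval < thresh
            and coloc_ok
        )

    for r in reports:
        if r.prioritized:
            r.reverse = reverse_mr(
                study.outcome,
                study.exposure.subset(study.ld[r.gene.gene_id].variant_ids),
                r.gene,
                study.ld[r.gene.gene_id],
                config.selection,
                ivw_mode=config.ivw_mode,
                alpha=config.reverse_alpha,
            )
    logger.info(
        "discovery: %d genes tested, threshold %.3g, %d prioritized",
        m, thresh, sum(r.prioritized for r in reports),
    )
    return reports


def run_validation(
    reports: list[TargetReport],
    study: Study,
    config: StudyConfig,
    strategy: str | None = None,
) -> list[TargetReport]:
    """Replicate prioritized genes in the validation outcome family.

    ``same_variant`` re-estimates with exactly the discovery instruments;
    ``significant_variant`` re-runs instrument selection before estimating.
    Family-wise verdicts use 0.05 / (number of prioritized genes); the first
    validation outcome is the primary (sets ``replicated``), the rest are
    complications (counted in ``replication_count``).  A verdict additionally
    requires the validation estimate to share the discovery sign when
    ``require_directional_consistency`` is set.
    """
    strategy = strategy or config.validation_strategy
    if strategy not in ("same_variant", "significant_variant"):
        raise ValueError(f"unknown validation strategy {strategy!r}")
    if not study.validation:
        return reports
    prioritized = [r for r in reports if r.prioritized]
    if not prioritized:
        return reports
    m_family = len(prioritized)
    thresh = bonferroni_threshold(config.alpha, m_family)

    for r in prioritized:
        for idx, vtable in enumerate(study.validation):
            vid = vtable.trait_id
            if strategy == "same_variant":
                variant_ids = r.discovery_post_steiger.snp_ids \
                    if r.discovery_post_steiger else r.instrument_set.variant_ids
            else:
                iv_set = select_instruments(
                    study.exposure.subset(study.ld[r.gene.gene_id].variant_ids),
                    r.gene, study.ld[r.gene.gene_id], config.selection,
                )
                variant_ids = iv_set.variant_ids
            insts, _ = harmonize_tables(study.exposure, vtable, list(variant_ids))
            if not insts:
                r.not_validatable.append(vid)
                continue
            est = _fit_auto(insts, r.gene.gene_id, vid, config.ivw_mode)
            r.validation[vid] = est
            verdict = est.pval < thresh
            if config.require_directional_consistency and r.discovery_post_steiger:
                verdict = verdict and (
                    np.sign(est.beta) == np.sign(r.discovery_post_steiger.beta)
                )
            r.validation_verdicts[vid] = bool(verdict)
            if idx == 0:
                r.replicated = bool(verdict)
        r.replication_count = sum(
            bool(v) for k, v in r.validation_verdicts.items()
            if study.validation and k != study.validation[0].trait_id
        )
    return reports


def run_biomarker_scan(
    reports: list[TargetReport], study: Study, config: StudyConfig
) -> list[TargetReport]:
    """Prioritized gene x biomarker associations, flagged at p < 0.05.

    Unadjusted by design; set ``biomarker_bonferroni`` to divide the level
    by the number of biomarker outcomes.
    """
    if not study.biomarkers:
        return reports
    alpha = config.biomarker_alpha
    if config.biomarker_bonferroni:
        alpha = bonferroni_threshold(alpha, len(study.biomarkers))
    for r in reports:
        if not r.prioritized:
            continue
        variant_ids = r.discovery_post_steiger.snp_ids \
            if r.discovery_post_steiger else r.instrument_set.variant_ids
        for btable in study.biomarkers:
            insts, _ = harmonize_tables(study.exposure, btable, list(variant_ids))
            if not insts:
                continue
            est = _fit_auto(insts, r.gene.gene_id, btable.trait_id, config.ivw_mode)
            r.biomarker[btable.trait_id] = est
            r.biomarker_flags[btable.trait_id] = bool(est.pval < alpha)
    return reports


# ---------------------------------------------------------------------------
# reporting


def _fmt(x: float) -> str:
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.6g}"


def _discovery_rows(reports, tissue="plasma"):
    for r in reports:
        for label, est in (("all", r.discovery), ("steiger", r.discovery_post_steiger)):
            if est is None:
                continue
            pves = [i.pve for i in r.instrument_set.instruments
                    if i.variant_id in est.snp_ids]
            fs = [i.f_stat for i in r.instrument_set.instruments
                  if i.variant_id in est.snp_ids]
            yield {
                "tissue": tissue,
                "gene_id": r.gene.gene_id,
                "symbol": r.gene.symbol,
                "snps": ",".join(est.snp_ids),
                "estimate": label,
                "method": est.method,
                "n_snps": est.n_snps,
                "or": _fmt(est.or_),
                "ci_low": _fmt(est.ci_low),
                "ci_high": _fmt(est.ci_high),
                "pval": _fmt(est.pval),
                "pve": ",".join(f"{p:.6g}" for p in pves),
                "f_stat": ",".join(f"{f:.6g}" for f in fs),
                "prioritized": r.prioritized,
            }


def _sensitivity_rows(reports, tissue="plasma"):
    for r in reports:
        if r.discovery is None:
            continue
        sens = r.sensitivity or SensitivityResult()
        rev = r.reverse.results if r.reverse and r.reverse.results else None
        yield {
            "tissue": tissue,
            "gene_id": r.gene.gene_id,
            "symbol": r.gene.symbol,
            "steiger_retained": sum(s.correct_direction for s in r.steiger_results),
            "steiger_removed": sum(not s.correct_direction for s in r.steiger_results),
            "steiger_pass": r.steiger_pass,
            "egger_intercept": _fmt(sens.egger_intercept),
            "egger_pval": _fmt(sens.egger_intercept_pval),
            "cochran_q": _fmt(sens.cochran_q),
            "q_pval": _fmt(sens.q_pval),
            "reverse_or": _fmt(rev.or_) if rev else "NA",
            "reverse_pval": _fmt(rev.pval) if rev else "NA",
            "bidirectional": r.bidirectional,
            "pph3": _fmt(r.coloc.posterior.pph3) if r.coloc else "NA",
            "pph4": _fmt(r.coloc.posterior.pph4) if r.coloc else "NA",
            "pph3_plus_pph4": _fmt(r.coloc.pph3_plus_pph4) if r.coloc else "NA",
            "coloc_decision": r.coloc.colocalized if r.coloc else "NA",
        }


def _validation_rows(reports):
    for r in reports:
        for vid, est in r.validation.items():
            yield {
                "gene_id": r.gene.gene_id,
                "symbol": r.gene.symbol,
                "outcome": vid,
                "method": est.method,
                "or": _fmt(est.or_),
                "ci_low": _fmt(est.ci_low),
                "ci_high": _fmt(est.ci_high),
                "pval": _fmt(est.pval),
                "verdict": r.validation_verdicts.get(vid, False),
            }
        for vid in r.not_validatable:
            yield {
                "gene_id": r.gene.gene_id,
                "symbol": r.gene.symbol,
                "outcome": vid,
                "method": "NA", "or": "NA", "ci_low": "NA", "ci_high": "NA",
                "pval": "NA", "verdict": "not_validatable",
            }


def make_report(
    reports: list[TargetReport], config: StudyConfig, outdir=None
) -> dict[str, str]:
    """Write the tabular report bundle; returns the path map.

    Tables: discovery (per-gene estimates pre/post Steiger), sensitivity
    (Steiger, pleiotropy, heterogeneity, reverse MR, colocalization),
    validation, the gene x biomarker matrix, and a JSON manifest recording
    every threshold and interpretive rule actually applied.
    """
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    tables = {
        "discovery": pd.DataFrame(list(_discovery_rows(reports))),
        "sensitivity": pd.DataFrame(list(_sensitivity_rows(reports))),
        "validation": pd.DataFrame(list(_validation_rows(reports))),
    }
    bio_rows = []
    for r in reports:
        if r.biomarker:
            row = {"gene_id": r.gene.gene_id, "symbol": r.gene.symbol}
            for bid, est in sorted(r.biomarker.items()):
                row[f"{bid}_or"] = _fmt(est.or_)
                row[f"{bid}_pval"] = _fmt(est.pval)
                row[f"{bid}_flag"] = r.biomarker_flags[bid]
            bio_rows.append(row)
    tables["biomarkers"] = pd.DataFrame(bio_rows)

    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)

    any_report = next((r for r in reports if r.bonferroni_m), None)
    manifest = {
        "thresholds": {
            "p_max": config.p_max,
            "maf_min": config.maf_min,
            "r2_max": config.r2_max,
            "window_kb": config.window_kb,
            "f_min": config.f_min,
            "alpha": config.alpha,
            "discovery_m": any_report.bonferroni_m if any_report else 0,
            "discovery_threshold": any_report.bonferroni_threshold
            if any_report else None,
            "coloc_threshold": config.coloc_threshold,
            "coloc_priors": [config.coloc_p1, config.coloc_p2, config.coloc_p12],
            "reverse_alpha": config.reverse_alpha,
            "biomarker_alpha": config.biomarker_alpha,
            "biomarker_bonferroni": config.biomarker_bonferroni,
        },
        "rules": {
            "validation_strategy": config.validation_strategy,
            "strategy_definitions": {
                "same_variant": "discovery instruments re-estimated in the "
                                "validation outcome",
                "significant_variant": "instrument selection re-run, then "
                                       "estimated in the validation outcome",
            },
            "directional_consistency_required":
                config.require_directional_consistency,
        },
        "ivw_mode": config.ivw_mode,
        "seed": config.seed,
        "n_genes": len(reports),
        "n_prioritized": int(sum(r.prioritized for r in reports)),
        "n_replicated": int(sum(r.replicated for r in reports)),
    }
    p = outdir / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    paths["manifest"] = str(p)
    return paths


def run_study(config: StudyConfig) -> tuple[list[TargetReport], dict[str, str]]:
    """Load, run the full cascade, and write the report bundle."""
    study = load_study(config)
    reports = run_discovery(study, config)
    reports = run_validation(reports, study, config)
    reports = run_biomarker_scan(reports, study, config)
    paths = make_report(reports, config)
    return reports, paths
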