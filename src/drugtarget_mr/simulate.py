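"""Synthetic eQTL and GWAS summary statistics with known ground truth.

Summary statistics are simulated directly in z-score space from the
multivariate normal implied by the regional LD structure — no
individual-level genotypes.  For a region of m variants with AR(1)
correlation matrix Σ (Σᵢⱼ = ρ^|i−j|) and sparse joint standardized effects
λ (per genotype SD), the observed marginal z-scores are

    z ~ MVN( sqrt(n_eff) · Σ λ ,  Σ ),

with per-allele effects recovered as beta = z · se and
se = 1/sqrt(2·maf·(1−maf)·n_eff).  Quantitative traits use n_eff = n;
binary traits are generated on the log-odds scale with
n_eff = n · φ(1−φ) for case fraction φ, the usual logistic
summary-statistic regime.

Scenarios
---------
causal / shared_variant
    one causal cis-eQTL per gene; the disease inherits theta × the
    expression effects through the same LD (a shared causal variant).
null
    the eQTL signal exists but the disease is pure noise.
distinct_variant
    expression and disease each have their own causal variant, well
    separated in the region.
reverse
    the disease has its own causal variant and the *expression* signal is
    induced from it (reverse causation) — the Steiger stress test.
bidirectional
    causal, plus an independent disease locus feeding back into
    expression — a true two-way relationship.
pleiotropic
    causal, plus direct variant-to-disease effects bypassing expression.

Each gene gets its own RNG stream derived from (seed, gene index), so
per-gene output is reproducible independently of iteration order, and a
fixed seed yields byte-identical study bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDMatrix
from .sumstats import (
    COLUMNS,
    GeneRegion,
    SumstatsTable,
    write_gene_regions,
    write_sumstats,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_region", "generate_study"]

SCENARIOS = (
    "causal",
    "null",
    "reverse",
    "bidirectional",
    "shared_variant",
    "distinct_variant",
    "pleiotropic",
)

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]

# numerical floor for two-sided p-values so extreme hits survive the (0,1]
# table invariant instead of underflowing to exactly 0
_P_FLOOR = 1e-300

_VARIANT_SPACING_BP = 2_000


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the real data sources: a blood eQTL meta-analysis of
    n = 31,684, and a type-2-diabetes GWAS of 62,892 cases / 596,424
    controls (n = 659,316, case fraction 0.0954).  ``eqtl_effect_size`` is
    the per-allele effect on standardized expression (PVE ≈ 0.8% at
    MAF 0.25, F ≈ 270 at the eQTL sample size).
    """

    n_genes: int = 100
    variants_per_region: int = 50
    ld_rho: float = 0.5
    n_exp: int = 31_684
    n_out: int = 659_316
    theta: float = 0.4
    scenario: str = "causal"
    maf_range: tuple[float, float] = (0.05, 0.5)
    eqtl_effect_size: float = 0.15
    case_fraction: float = 62_892 / 659_316
    seed: int = 0
    # scenario-specific knobs
    disease_effect_size: float = 0.3   # per-allele log-OR of the reverse-scenario GWAS hit
    reverse_theta: float = 0.2         # effect of disease liability on expression
    distinct_separation: int = 20      # minimum index gap between the two causal variants
    n_pleiotropic: int = 3             # variants with direct disease effects
    pleiotropy_effect: float = 0.05    # per-allele direct log-OR offset
    outcome_trait_type: str = "binary"
    exposure_id: str = "eqtl_plasma"
    outcome_id: str = "disease"
    # optional per-gene overrides (length n_genes when given)
    scenarios: tuple[str, ...] | None = None
    thetas: tuple[float, ...] | None = None
    # study-bundle extras
    validation_family_size: int = 0    # validation outcomes (primary first)
    n_validation: int | None = None    # per-outcome sample size (default n_out // 2)
    n_biomarkers: int = 0
    n_biomarker_samples: int = 100_000
    biomarker_effect: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.scenarios is not None:
            bad = set(self.scenarios) - set(SCENARIOS)
            if bad:
                raise ValueError(f"unknown scenario(s) {sorted(bad)}")

    def scenario_for(self, gene_index: int) -> str:
        if self.scenarios is not None:
            return self.scenarios[gene_index]
        return self.scenario

    def theta_for(self, gene_index: int) -> float:
        if self.thetas is not None:
            return self.thetas[gene_index]
        return self.theta


@dataclass
class GroundTruth:
    """True causal parameters for one simulated gene region."""

    gene_id: str
    scenario: str
    theta: float
    causal_exp: list[int] = field(default_factory=list)
    causal_out: list[int] = field(default_factory=list)
    pleiotropy: dict[str, float] = field(default_factory=dict)
    biomarker_effects: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)

    @property
    def is_causal(self) -> bool:
        return self.scenario in ("causal", "shared_variant", "pleiotropic") and self.theta != 0.0


class _RegionTemplate:
    """Deterministic per-gene structure: variants, LD, and true effects.

    Built from the (seed, gene_index) stream; drawing a study's observed
    statistics consumes separate streams so outcome replicates can be
    re-noised without touching the structure.
    """

    def __init__(self, config: SimulationConfig, gene_index: int):
        self.config = config
        self.gene_index = gene_index
        m = config.variants_per_region
        rng = np.random.default_rng([config.seed, gene_index, 0])

        self.gene = GeneRegion(
            gene_id=f"GENE{gene_index:04d}",
            symbol=f"G{gene_index}",
            chrom=str(1 + gene_index % 22),
            tss=10_000_000 + (gene_index // 22) * 50_000_000,
        )
        half = (m // 2) * _VARIANT_SPACING_BP
        self.pos = self.gene.tss - half + np.arange(m) * _VARIANT_SPACING_BP
        self.variant_ids = [
            f"rs{1_000_000 + gene_index * 1_000 + j}" for j in range(m)
        ]
        self.maf = rng.uniform(*config.maf_range, size=m)
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
        self.alleles = [_ALLELE_PAIRS[i] for i in pair_idx]

        idx = np.arange(m)
        self.sigma = config.ld_rho ** np.abs(idx[:, None] - idx[None, :])
        self.chol = np.linalg.cholesky(self.sigma + 1e-12 * np.eye(m))

        scenario = config.scenario_for(gene_index)
        theta = config.theta_for(gene_index)
        sd_g = np.sqrt(2.0 * self.maf * (1.0 - self.maf))  # genotype SDs

        lam_exp = np.zeros(m)
        lam_out = np.zeros(m)
        truth = GroundTruth(self.gene.gene_id, scenario, theta)

        if scenario == "reverse":
            c_out = int(rng.integers(m))
            lam_out[c_out] = config.disease_effect_size * sd_g[c_out]
            lam_exp = config.reverse_theta * lam_out
            truth.causal_out = [c_out]
            truth.causal_exp = []          # no independent expression signal
            truth.theta = 0.0              # no forward effect
        else:
            c_exp = int(rng.integers(m))
            lam_exp[c_exp] = config.eqtl_effect_size * sd_g[c_exp]
            truth.causal_exp = [c_exp]
            if scenario in ("causal", "shared_variant", "pleiotropic"):
                lam_out = theta * lam_exp
                truth.causal_out = [c_exp] if theta != 0.0 else []
            elif scenario == "distinct_variant":
                sep = min(config.distinct_separation, max(c_exp, m - 1 - c_exp))
                far = idx[np.abs(idx - c_exp) >= sep]
                c_out = int(rng.choice(far))
                lam_out[c_out] = theta * config.eqtl_effect_size * sd_g[c_out]
                truth.causal_out = [c_out]
            elif scenario == "bidirectional":
                # forward-causal gene plus an independent disease locus whose
                # liability feeds back into expression
                sep = min(config.distinct_separation, max(c_exp, m - 1 - c_exp))
                far = idx[np.abs(idx - c_exp) >= sep]
                c_out = int(rng.choice(far))
                lam_out = theta * lam_exp
                lam_out[c_out] += config.disease_effect_size * sd_g[c_out]
                lam_exp[c_out] += (
                    config.reverse_theta * config.disease_effect_size * sd_g[c_out]
                )
                truth.causal_out = [c_exp, c_out] if theta != 0.0 else [c_out]
            elif scenario == "null":
                truth.theta = 0.0
            if scenario == "pleiotropic":
                others = idx[idx != c_exp]
                pleio = rng.choice(others, size=min(config.n_pleiotropic, len(others)),
                                   replace=False)
                for j in pleio:
                    lam_out[j] += config.pleiotropy_effect * sd_g[j]
                    truth.pleiotropy[self.variant_ids[j]] = config.pleiotropy_effect

        self.lam_exp = lam_exp
        self.lam_out = lam_out
        self.truth = truth

    # -- draws ------------------------------------------------------------

    def _draw(self, rng, lam: np.ndarray, n: float, n_eff: float,
              trait_id: str, trait_type: str, swap_prob: float = 0.0,
              n_cases: int | None = None, n_controls: int | None = None,
              n_jitter: bool = False) -> SumstatsTable:
        m = len(self.maf)
        mean = np.sqrt(n_eff) * self.sigma @ lam
        z = mean + self.chol @ rng.standard_normal(m)
        se = 1.0 / np.sqrt(2.0 * self.maf * (1.0 - self.maf) * n_eff)
        beta = z * se
        pval = np.maximum(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR)
        if n_jitter:
            # per-variant sample sizes vary in real meta-analyses
            n_var = np.floor(n * rng.uniform(0.85, 1.0, size=m))
        else:
            n_var = np.full(m, float(n))

        ea = np.array([a for a, _ in self.alleles])
        oa = np.array([b for _, b in self.alleles])
        eaf = self.maf.copy()
        if swap_prob > 0.0:
            # represent some variants on the opposite allele, exercising
            # downstream harmonization
            swap = rng.random(m) < swap_prob
            ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
            beta[swap] = -beta[swap]
            eaf[swap] = 1.0 - eaf[swap]

        df = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chrom": self.gene.chrom,
                "pos": self.pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": pval,
                "n": n_var,
            },
            columns=COLUMNS,
        )
        return SumstatsTable(df, trait_id=trait_id, trait_type=trait_type,
                             n_cases=n_cases, n_controls=n_controls)

    def draw_exposure(self) -> SumstatsTable:
        rng = np.random.default_rng([self.config.seed, self.gene_index, 1])
        return self._draw(rng, self.lam_exp, self.config.n_exp, self.config.n_exp,
                          self.config.exposure_id, "quantitative", n_jitter=True)

    def draw_outcome(self, stream: int = 2, n_out: int | None = None,
                     trait_id: str | None = None, lam: np.ndarray | None = None,
                     trait_type: str | None = None) -> SumstatsTable:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, self.gene_index, stream])
        n = n_out if n_out is not None else cfg.n_out
        trait_type = trait_type or cfg.outcome_trait_type
        if trait_type == "binary":
            phi = cfg.case_fraction
            n_eff = n * phi * (1.0 - phi)
            n_cases = int(round(phi * n))
            n_controls = n - n_cases
        else:
            n_eff = n
            n_cases = n_controls = None
        return self._draw(
            rng, self.lam_out if lam is None else lam, n, n_eff,
            trait_id or cfg.outcome_id, trait_type,
            swap_prob=0.1, n_cases=n_cases, n_controls=n_controls,
        )

    def ld_matrix(self) -> LDMatrix:
        return LDMatrix(self.variant_ids, self.sigma**2)


def simulate_region(
    config: SimulationConfig, gene_index: int
) -> tuple[SumstatsTable, SumstatsTable, LDMatrix, GroundTruth]:
    """One gene region: exposure stats, outcome stats, LD, and the truth."""
    tpl = _RegionTemplate(config, gene_index)
    return tpl.draw_exposure(), tpl.draw_outcome(), tpl.ld_matrix(), tpl.truth


def _concat(tables: list[SumstatsTable]) -> SumstatsTable:
    first = tables[0]
    df = pd.concat([t.df for t in tables], ignore_index=True)
    return SumstatsTable(df, trait_id=first.trait_id, trait_type=first.trait_type,
                         n_cases=first.n_cases, n_controls=first.n_controls)


def generate_study(config: SimulationConfig, outdir) -> dict:
    """Write a complete on-disk study bundle and return its manifest.

    The bundle is exactly what the pipeline consumes: ``exposure.tsv`` (all
    genes), ``outcome_<id>.tsv`` (discovery), optional validation outcomes
    (same truth, fresh noise, validation sample size) and quantitative
    biomarker outcomes, per-gene LD matrices under ``ld/``, ``genes.tsv``,
    ``druggable_genes.txt`` and ``truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "ld").mkdir(parents=True, exist_ok=True)

    templates = [_RegionTemplate(config, g) for g in range(config.n_genes)]
    genes = [tpl.gene for tpl in templates]

    exposure = _concat([tpl.draw_exposure() for tpl in templates])
    write_sumstats(exposure, outdir / "exposure.tsv")

    outcome = _concat([tpl.draw_outcome() for tpl in templates])
    outcome_path = outdir / f"outcome_{config.outcome_id}.tsv"
    write_sumstats(outcome, outcome_path)

    manifest: dict = {
        "exposure": "exposure.tsv",
        "outcome": outcome_path.name,
        "genes": "genes.tsv",
        "gene_list": "druggable_genes.txt",
        "truth": "truth.json",
        "ld_dir": "ld",
        "validation": [],
        "biomarkers": [],
        "seed": config.seed,
    }

    n_val = config.n_validation or config.n_out // 2
    for k in range(config.validation_family_size):
        vid = f"{config.outcome_id}_validation{k}"
        table = _concat(
            [tpl.draw_outcome(stream=10 + k, n_out=n_val, trait_id=vid)
             for tpl in templates]
        )
        write_sumstats(table, outdir / f"outcome_{vid}.tsv")
        manifest["validation"].append(f"outcome_{vid}.tsv")

    # biomarkers: quantitative traits; the first causal gene drives the first
    # biomarker through its eQTL, all other pairs are null
    first_causal = next((tpl for tpl in templates if tpl.truth.is_causal), None)
    for b in range(config.n_biomarkers):
        bid = f"biomarker{b}"
        slices = []
        for tpl in templates:
            if b == 0 and first_causal is not None and tpl is first_causal:
                # mediated through expression: per-SD-expression effect
                lam = config.biomarker_effect * tpl.lam_exp
                tpl.truth.biomarker_effects[bid] = config.biomarker_effect
            else:
                lam = np.zeros_like(tpl.lam_out)
            slices.append(
                tpl.draw_outcome(stream=100 + b, n_out=config.n_biomarker_samples,
                                 trait_id=bid, lam=lam, trait_type="quantitative")
            )
        write_sumstats(_concat(slices), outdir / f"outcome_{bid}.tsv")
        manifest["biomarkers"].append(f"outcome_{bid}.tsv")

    for tpl in templates:
        tpl.ld_matrix().write_tsv(outdir / "ld" / f"{tpl.gene.gene_id}.tsv")

    write_gene_regions(genes, outdir / "genes.tsv")
    with open(outdir / "druggable_genes.txt", "w") as fh:
        fh.write("\n".join(g.gene_id for g in genes) + "\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump([tpl.truth.to_dict() for tpl in templates], fh, indent=1,
                  sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
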