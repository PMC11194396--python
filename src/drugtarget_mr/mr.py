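"""Two-sample summary-data Mendelian randomization.

The central object is :class:`MendelianRandomization`, a model built from a
set of harmonized instruments (per-variant exposure and outcome effects and
standard errors).  ``fit()`` returns an :class:`MRResults` carrying the
causal estimate — the Wald ratio for a single instrument, inverse-variance
weighting (fixed or multiplicative-random-effects) otherwise — its standard
error, p-value and odds-ratio confidence interval, plus Cochran's Q.
Sensitivity analyses (MR-Egger intercept for directional pleiotropy,
Steiger directionality filtering) hang off the model.

Per-instrument Wald ratios use the first-order delta method,
``se(r_i) = se_out,i / |beta_exp,i|``: instruments pass F > 10, so exposure
uncertainty is second-order.  A second-order correction is available via
``second_order=True``.  All p-values are two-sided normal (summary-data
regime, large n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
import statsmodels.api as sm

from .instruments import (
    InstrumentSet,
    LDMatrix,
    SelectionConfig,
    compute_pve,
    select_instruments,
)
from .sumstats import GeneRegion, HarmonizationResult, SumstatsTable, harmonize_pair

__all__ = [
    "HarmonizedInstrument",
    "MendelianRandomization",
    "MRResults",
    "SteigerResult",
    "SensitivityResult",
    "ReverseMRResult",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger_intercept",
    "steiger_filter",
    "bonferroni_threshold",
    "harmonize_tables",
    "reverse_mr",
]

#: 97.5% standard-normal quantile used for all 95% intervals
Z_95 = 1.959964


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Per-variant exposure and outcome summary effects on a shared allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float = float("nan")
    eaf_out: float = float("nan")
    n_exp: float = float("nan")
    n_out: float = float("nan")

    def __post_init__(self) -> None:
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError(f"{self.variant_id}: standard errors must be > 0")


def _ratios(
    insts: Sequence[HarmonizedInstrument], second_order: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument Wald ratios and their delta-method SEs."""
    bx = np.array([i.beta_exp for i in insts])
    by = np.array([i.beta_out for i in insts])
    sy = np.array([i.se_out for i in insts])
    if np.any(bx == 0):
        bad = insts[int(np.argmax(bx == 0))].variant_id
        raise ZeroDivisionError(f"undefined Wald ratio: beta_exp = 0 for {bad}")
    r = by / bx
    se = sy / np.abs(bx)
    if second_order:
        sx = np.array([i.se_exp for i in insts])
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return r, se


def _normal_p(z: float) -> float:
    # floored so extreme z-scores keep p inside (0, 1]
    return float(max(2.0 * stats.norm.sf(abs(z)), 1e-300))


@dataclass
class MRResults:
    """A gene-to-outcome causal estimate with its uncertainty.

    ``beta`` is the causal effect per SD of exposure (log-odds for binary
    outcomes); ``or_`` and the 95% CI bounds are on the odds-ratio scale.
    """

    beta: float
    se: float
    pval: float
    method: Literal["wald_ratio", "ivw_fe", "ivw_mre"]
    n_snps: int
    gene_id: str = ""
    outcome_id: str = ""
    snp_ids: tuple[str, ...] = ()
    q: float = float("nan")
    q_df: int = 0
    q_pval: float = float("nan")

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z_95 * self.se)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1 − alpha) interval on the log-odds scale."""
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return (self.beta - z * self.se, self.beta + z * self.se)

    def summary(self) -> str:
        lines = [
            "Mendelian randomization results",
            "=" * 46,
            f"{'gene':<14}{self.gene_id}",
            f"{'outcome':<14}{self.outcome_id}",
            f"{'method':<14}{self.method}",
            f"{'n SNPs':<14}{self.n_snps}",
            f"{'beta (logOR)':<14}{self.beta:.6g}",
            f"{'se':<14}{self.se:.6g}",
            f"{'p-value':<14}{self.pval:.4g}",
            f"{'OR (95% CI)':<14}{self.or_:.3f} ({self.ci_low:.3f}, {self.ci_high:.3f})",
        ]
        if self.n_snps >= 2 and not math.isnan(self.q):
            lines.append(
                f"{'Cochran Q':<14}{self.q:.4g} (df {self.q_df}, p {self.q_pval:.4g})"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MRResults {self.method} {self.gene_id or '?'}→{self.outcome_id or '?'} "
            f"OR={self.or_:.3f} p={self.pval:.3g} k={self.n_snps}>"
        )


def wald_ratio(
    inst: HarmonizedInstrument, second_order: bool = False, **ids
) -> MRResults:
    """Single-instrument causal estimate, ``beta_out / beta_exp``."""
    r, se = _ratios([inst], second_order=second_order)
    beta, s = float(r[0]), float(se[0])
    return MRResults(
        beta=beta,
        se=s,
        pval=_normal_p(beta / s),
        method="wald_ratio",
        n_snps=1,
        snp_ids=(inst.variant_id,),
        **ids,
    )


def cochran_q(
    insts: Sequence[HarmonizedInstrument], second_order: bool = False
) -> tuple[float, int, float]:
    """Heterogeneity of the per-instrument ratios: Q, df, chi-square p."""
    if len(insts) < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    r, se = _ratios(insts, second_order=second_order)
    w = 1.0 / se**2
    est = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - est) ** 2))
    df = len(insts) - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(
    insts: Sequence[HarmonizedInstrument],
    mode: Literal["fixed", "multiplicative_random"] = "multiplicative_random",
    second_order: bool = False,
    **ids,
) -> MRResults:
    """Inverse-variance-weighted combination of per-instrument Wald ratios.

    Fixed-effect SE is ``sqrt(1/Σw)``; the multiplicative-random-effects
    model inflates it by ``sqrt(max(1, Q/(k−1)))`` to absorb heterogeneity.
    """
    if len(insts) < 2:
        raise ValueError("IVW requires >= 2 instruments; use wald_ratio for 1")
    r, se = _ratios(insts, second_order=second_order)
    w = 1.0 / se**2
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    q, df, q_p = cochran_q(insts, second_order=second_order)
    if mode == "fixed":
        s, method = se_fixed, "ivw_fe"
    elif mode == "multiplicative_random":
        s = se_fixed * math.sqrt(max(1.0, q / df))
        method = "ivw_mre"
    else:
        raise ValueError(f"unknown IVW mode {mode!r}")
    return MRResults(
        beta=beta,
        se=s,
        pval=_normal_p(beta / s),
        method=method,  # type: ignore[arg-type]
        n_snps=len(insts),
        snp_ids=tuple(i.variant_id for i in insts),
        q=q,
        q_df=df,
        q_pval=q_p,
        **ids,
    )


@dataclass(frozen=True)
class SteigerResult:
    """Directionality check for one instrument.

    ``correct_direction`` is true iff the instrument explains strictly more
    variance in the exposure than in the outcome.
    """

    variant_id: str
    r2_exp: float
    r2_out: float
    correct_direction: bool
    steiger_pval: float


def _steiger_one(inst: HarmonizedInstrument) -> SteigerResult:
    # exposure-side variance explained: same algebra as instrument PVE
    zx = inst.beta_exp / inst.se_exp
    r2_exp = zx**2 / (zx**2 + inst.n_exp)
    # outcome side: observed-scale approximation from the association z-score
    zy = inst.beta_out / inst.se_out
    r2_out = zy**2 / (zy**2 + inst.n_out)
    # Fisher-z test for the difference of the two correlations, studies
    # independent (two-sample design)
    fz = math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))
    denom = math.sqrt(1.0 / (inst.n_exp - 3.0) + 1.0 / (inst.n_out - 3.0))
    p = _normal_p(fz / denom)
    return SteigerResult(
        variant_id=inst.variant_id,
        r2_exp=float(r2_exp),
        r2_out=float(r2_out),
        correct_direction=bool(r2_exp > r2_out),
        steiger_pval=p,
    )


def steiger_filter(
    insts: Sequence[HarmonizedInstrument],
) -> tuple[list[HarmonizedInstrument], list[SteigerResult]]:
    """Drop instruments explaining no more variance in exposure than outcome.

    Returns the retained instruments and the per-instrument diagnostics.
    An empty retention is allowed.
    """
    results = [_steiger_one(i) for i in insts]
    retained = [i for i, res in zip(insts, results) if res.correct_direction]
    return retained, results


@dataclass
class SensitivityResult:
    """Pleiotropy and heterogeneity diagnostics for one gene-outcome pair."""

    gene_id: str = ""
    outcome_id: str = ""
    egger_intercept: float = float("nan")
    egger_intercept_se: float = float("nan")
    egger_intercept_pval: float = float("nan")
    egger_computable: bool = False
    cochran_q: float = float("nan")
    q_df: int = 0
    q_pval: float = float("nan")


def egger_intercept(insts: Sequence[HarmonizedInstrument]) -> SensitivityResult:
    """MR-Egger intercept test for directional pleiotropy.

    Weighted least squares of the outcome effects on the exposure effects
    with a free intercept, weights 1/se_out²; instruments are first
    oriented so every exposure effect is positive.  With fewer than three
    instruments the test is flagged not-computable rather than fatal.
    """
    res = SensitivityResult()
    if len(insts) < 3:
        return res
    sign = np.array([1.0 if i.beta_exp > 0 else -1.0 for i in insts])
    bx = sign * np.array([i.beta_exp for i in insts])
    by = sign * np.array([i.beta_out for i in insts])
    w = 1.0 / np.array([i.se_out for i in insts]) ** 2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    res.egger_intercept = float(fit.params[0])
    res.egger_intercept_se = float(fit.bse[0])
    res.egger_intercept_pval = _normal_p(fit.params[0] / fit.bse[0])
    res.egger_computable = True
    return res


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold ``alpha / m``."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


# ---------------------------------------------------------------------------
# the model object


class MendelianRandomization:
    """Two-sample MR model for one gene-outcome pair.

    Parameters
    ----------
    instruments
        Harmonized per-variant effects.  At least one.
    gene_id, outcome_id
        Labels carried through to the results.
    second_order
        Use the second-order delta-method SE for per-instrument ratios.

    Examples
    --------
    >>> model = MendelianRandomization(insts, gene_id="ENSG...", outcome_id="T2DM")
    >>> res = model.fit()            # Wald ratio if k = 1, IVW-MRE otherwise
    >>> print(res.summary())
    """

    def __init__(
        self,
        instruments: Sequence[HarmonizedInstrument],
        gene_id: str = "",
        outcome_id: str = "",
        second_order: bool = False,
    ):
        if len(instruments) == 0:
            raise ValueError("at least one harmonized instrument is required")
        self.instruments = list(instruments)
        self.gene_id = gene_id
        self.outcome_id = outcome_id
        self.second_order = second_order

    @classmethod
    def from_tables(
        cls,
        exposure: SumstatsTable,
        outcome: SumstatsTable,
        variant_ids: Sequence[str] | None = None,
        palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
        gene_id: str = "",
        **kwargs,
    ) -> "MendelianRandomization":
        """Harmonize two summary tables over shared variants and build a model."""
        insts, _ = harmonize_tables(
            exposure, outcome, variant_ids, palindrome_eaf_band
        )
        if not insts:
            raise ValueError("no harmonizable shared variants")
        return cls(insts, gene_id=gene_id, outcome_id=outcome.trait_id, **kwargs)

    @property
    def k(self) -> int:
        return len(self.instruments)

    def fit(
        self,
        method: Literal["auto", "wald_ratio", "ivw_fe", "ivw_mre"] = "auto",
    ) -> MRResults:
        ids = {"gene_id": self.gene_id, "outcome_id": self.outcome_id}
        if method == "auto":
            method = "wald_ratio" if self.k == 1 else "ivw_mre"
        if method == "wald_ratio":
            if self.k != 1:
                raise ValueError("wald_ratio requires exactly one instrument")
            return wald_ratio(self.instruments[0], self.second_order, **ids)
        mode = "fixed" if method == "ivw_fe" else "multiplicative_random"
        return ivw(self.instruments, mode, self.second_order, **ids)

    def cochran_q(self) -> tuple[float, int, float]:
        return cochran_q(self.instruments, self.second_order)

    def egger_intercept(self) -> SensitivityResult:
        res = egger_intercept(self.instruments)
        res.gene_id, res.outcome_id = self.gene_id, self.outcome_id
        return res

    def sensitivity(self) -> SensitivityResult:
        """Egger intercept plus Cochran's Q in one record."""
        res = self.egger_intercept()
        if self.k >= 2:
            res.cochran_q, res.q_df, res.q_pval = self.cochran_q()
        return res

    def steiger_filter(
        self,
    ) -> tuple["MendelianRandomization | None", list[SteigerResult]]:
        """Directionality-filtered copy of the model (None if nothing survives)."""
        retained, results = steiger_filter(self.instruments)
        if not retained:
            return None, results
        model = MendelianRandomization(
            retained, self.gene_id, self.outcome_id, self.second_order
        )
        return model, results


# ---------------------------------------------------------------------------
# harmonization across tables, and reverse MR


def harmonize_tables(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    variant_ids: Sequence[str] | None = None,
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> tuple[list[HarmonizedInstrument], list[HarmonizationResult]]:
    """Pair exposure and outcome records by variant_id and align alleles.

    Variants absent from the outcome table are silently skipped (they are
    not harmonization failures); allele-irreconcilable or strand-ambiguous
    pairs appear in the report with their rejection reason.
    """
    if variant_ids is None:
        variant_ids = list(exposure.df["variant_id"])
    insts: list[HarmonizedInstrument] = []
    report: list[HarmonizationResult] = []
    for vid in variant_ids:
        exp = exposure.get(vid)
        out = outcome.get(vid)
        if exp is None or out is None:
            continue
        res = harmonize_pair(exp, out, palindrome_eaf_band)
        report.append(res)
        if not res.ok:
            continue
        aligned = res.outcome
        insts.append(
            HarmonizedInstrument(
                variant_id=vid,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=aligned.beta,
                se_out=aligned.se,
                eaf_exp=exp.eaf,
                eaf_out=aligned.eaf,
                n_exp=exp.n,
                n_out=aligned.n,
            )
        )
    return insts, report


@dataclass
class ReverseMRResult:
    """Disease-to-expression MR for one gene (the bidirectionality check)."""

    gene_id: str
    outcome_id: str
    testable: bool
    reason: str = ""
    results: MRResults | None = None
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.testable and self.results is not None and self.results.pval < self.alpha


def reverse_mr(
    disease: SumstatsTable,
    eqtl: SumstatsTable,
    gene: GeneRegion,
    ld: LDMatrix,
    config: SelectionConfig | None = None,
    ivw_mode: Literal["fixed", "multiplicative_random"] = "multiplicative_random",
    alpha: float = 0.05,
    steiger: bool = True,
) -> ReverseMRResult:
    """Bidirectional check: disease as exposure, the gene's eQTLs as outcome.

    Disease instruments are selected under the same cascade as forward
    instruments and (by default) Steiger-filtered in the reverse
    orientation, so a disease hit that is merely the mediated shadow of the
    gene's own eQTL — explaining more variance in expression than in the
    disease — cannot pose as a reverse effect.  With no usable instrument
    the gene is flagged not-testable.  Significance of a reverse effect is
    declared at ``alpha`` (0.05).
    """
    iv_set = select_instruments(disease.subset(ld.variant_ids), gene, ld, config)
    if len(iv_set) == 0:
        return ReverseMRResult(
            gene.gene_id, eqtl.trait_id, testable=False,
            reason="no genome-wide-significant disease instruments",
        )
    insts, _ = harmonize_tables(disease, eqtl, iv_set.variant_ids)
    if not insts:
        return ReverseMRResult(
            gene.gene_id, eqtl.trait_id, testable=False,
            reason="disease instruments absent from eQTL table",
        )
    if steiger:
        insts, _ = steiger_filter(insts)
        if not insts:
            return ReverseMRResult(
                gene.gene_id, eqtl.trait_id, testable=False,
                reason="all disease instruments removed by directionality filter",
            )
    model = MendelianRandomization(insts, gene_id=gene.gene_id, outcome_id=eqtl.trait_id)
    res = model.fit("wald_ratio" if model.k == 1 else
                    ("ivw_fe" if ivw_mode == "fixed" else "ivw_mre"))
    return ReverseMRResult(
        gene.gene_id, eqtl.trait_id, testable=True, results=res, alpha=alpha
    )
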