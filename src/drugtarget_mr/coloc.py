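"""Bayesian colocalization of two association signals in one region.

Under the single-causal-variant assumption per trait, the evidence for
each of the five hypotheses —

- H0: neither trait associated in the region,
- H1: only trait 1 (expression) associated,
- H2: only trait 2 (disease) associated,
- H3: both associated, distinct causal variants,
- H4: both associated, one shared causal variant —

is accumulated from per-variant Wald summary statistics through the
approximate Bayes factor

    log ABF = 0.5 * (log(1 - r) + r * z**2),   r = w / (se**2 + w),

where ``w`` is the prior variance of the true effect (0.15**2 for
quantitative traits, 0.2**2 for binary-trait log-odds).  Per-configuration
prior weights are p1, p2 (single-trait causal) and p12 (shared causal);
all sums run in log space so large z-scores cannot overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .sumstats import GeneRegion

__all__ = [
    "log_abf",
    "RegionPair",
    "ColocPosterior",
    "Colocalization",
    "coloc_posteriors",
    "coloc_decision",
    "W_QUANT",
    "W_BINARY",
]

#: default prior effect variances: sd 0.15 for quantitative traits,
#: sd 0.2 for binary-trait log odds-ratios
W_QUANT = 0.15**2
W_BINARY = 0.2**2


def log_abf(beta, se, w: float):
    """Log approximate Bayes factor for association at one variant.

    Vectorised over ``beta``/``se``.  ``w`` is the prior variance of the
    true effect; ``r = w/(se² + w)`` is the shrinkage weight.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if w <= 0:
        raise ValueError("prior variance w must be > 0")
    v = se**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


@dataclass
class RegionPair:
    """Aligned per-variant statistics for two traits over one region."""

    variant_ids: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    gene: GeneRegion | None = None
    trait1_type: str = "quantitative"
    trait2_type: str = "binary"
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w_quant: float = W_QUANT
    w_binary: float = W_BINARY

    def __post_init__(self) -> None:
        m = len(self.variant_ids)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.se1 = np.asarray(self.se1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.se2 = np.asarray(self.se2, dtype=float)
        for arr in (self.beta1, self.se1, self.beta2, self.se2):
            if arr.shape != (m,):
                raise ValueError("per-variant arrays must match variant_ids")
        for p in (self.p1, self.p2, self.p12):
            if not 0.0 < p < 1.0:
                raise ValueError("priors must lie in (0, 1)")
        if self.p1 + self.p2 + self.p12 >= 1.0:
            raise ValueError("p1 + p2 + p12 must be < 1")

    def _w(self, trait_type: str) -> float:
        return self.w_quant if trait_type == "quantitative" else self.w_binary


@dataclass(frozen=True)
class ColocPosterior:
    """The five posterior hypothesis probabilities for a region."""

    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    colocalized: bool = False

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.pph0, self.pph1, self.pph2, self.pph3, self.pph4)


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference vanishes."""
    if b == -math.inf:
        return a
    d = b - a
    if d >= 0.0:
        return -math.inf
    return a + math.log1p(-math.exp(d))


def coloc_posteriors(region: RegionPair, threshold: float = 0.8) -> ColocPosterior:
    """Posterior probabilities of H0-H4 for one region pair.

    Unnormalized hypothesis weights (S1 = Σᵢ ABF1ᵢ, S2 = Σⱼ ABF2ⱼ,
    S12 = Σᵢ ABF1ᵢ·ABF2ᵢ):

        H0: 1,  H1: p1·S1,  H2: p2·S2,
        H3: p1·p2·(S1·S2 − S12),  H4: p12·S12,

    all evaluated in log space.  With a single shared variant H3 has no
    admissible configuration and its weight is exactly zero.
    """
    m = len(region.variant_ids)
    if m == 0:
        raise ValueError("empty region")
    lbf1 = np.atleast_1d(log_abf(region.beta1, region.se1, region._w(region.trait1_type)))
    lbf2 = np.atleast_1d(log_abf(region.beta2, region.se2, region._w(region.trait2_type)))

    ls1 = float(logsumexp(lbf1))
    ls2 = float(logsumexp(lbf2))
    ls12 = float(logsumexp(lbf1 + lbf2))

    lh = np.array(
        [
            0.0,
            math.log(region.p1) + ls1,
            math.log(region.p2) + ls2,
            math.log(region.p1) + math.log(region.p2) + _log_diff_exp(ls1 + ls2, ls12),
            math.log(region.p12) + ls12,
        ]
    )
    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()
    pp = ColocPosterior(*(float(x) for x in post))
    return ColocPosterior(*pp.as_tuple(), colocalized=coloc_decision(pp, threshold))


def coloc_decision(post: ColocPosterior, threshold: float = 0.8) -> bool:
    """Shared-or-distinct evidence rule: PPH3 + PPH4 >= threshold (inclusive)."""
    return post.pph3 + post.pph4 >= threshold


class Colocalization:
    """Model object wrapping :func:`coloc_posteriors`.

    Build from a :class:`RegionPair` (or two aligned stat vectors) and call
    :meth:`fit` to obtain a :class:`ColocResults` with the posterior
    probabilities, the evidence decision and a ``summary()`` table.
    """

    def __init__(self, region: RegionPair, threshold: float = 0.8):
        self.region = region
        self.threshold = threshold

    @classmethod
    def from_arrays(
        cls,
        variant_ids: Sequence[str],
        beta1,
        se1,
        beta2,
        se2,
        threshold: float = 0.8,
        **region_kwargs,
    ) -> "Colocalization":
        region = RegionPair(
            variant_ids=list(variant_ids),
            beta1=np.asarray(beta1, float),
            se1=np.asarray(se1, float),
            beta2=np.asarray(beta2, float),
            se2=np.asarray(se2, float),
            **region_kwargs,
        )
        return cls(region, threshold)

    def fit(self) -> "ColocResults":
        post = coloc_posteriors(self.region, self.threshold)
        return ColocResults(
            posterior=post,
            threshold=self.threshold,
            n_variants=len(self.region.variant_ids),
            gene_id=self.region.gene.gene_id if self.region.gene else "",
        )


@dataclass
class ColocResults:
    posterior: ColocPosterior
    threshold: float
    n_variants: int
    gene_id: str = ""

    @property
    def colocalized(self) -> bool:
        return self.posterior.colocalized

    @property
    def pph3_plus_pph4(self) -> float:
        return self.posterior.pph3 + self.posterior.pph4

    def summary(self) -> str:
        p = self.posterior
        rows = [
            "Bayesian colocalization results",
            "=" * 42,
            f"{'gene':<12}{self.gene_id}",
            f"{'variants':<12}{self.n_variants}",
            f"{'PPH0':<12}{p.pph0:.4f}   (no association)",
            f"{'PPH1':<12}{p.pph1:.4f}   (trait 1 only)",
            f"{'PPH2':<12}{p.pph2:.4f}   (trait 2 only)",
            f"{'PPH3':<12}{p.pph3:.4f}   (distinct causal variants)",
            f"{'PPH4':<12}{p.pph4:.4f}   (shared causal variant)",
            f"{'PPH3+PPH4':<12}{self.pph3_plus_pph4:.4f}   "
            f"({'>=' if self.colocalized else '<'} {self.threshold})",
        ]
        return "\n".join(rows)
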