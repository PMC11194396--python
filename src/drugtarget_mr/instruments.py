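"""Genetic-instrument selection for cis-eQTL Mendelian randomization.

Instruments for a gene are its eQTL variants surviving, in order:

1. genome-wide significance (p < 5e-8),
2. minor-allele frequency > 1%,
3. greedy LD clumping (r² < 0.001 within a 10,000 kb window), and
4. instrument strength F > 10,

with per-variant variance explained computed as

    R² = (2·EAF·(1−EAF)·beta²) / (2·EAF·(1−EAF)·beta² + 2·EAF·(1−EAF)·N·SE²)
       = beta² / (beta² + N·SE²)

(the allele-frequency factor cancels) and F = R²(N−2)/(1−R²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import GeneRegion, SumstatsTable, VariantAssociation

__all__ = [
    "Instrument",
    "LDMatrix",
    "InstrumentSet",
    "SelectionConfig",
    "compute_pve",
    "compute_f",
    "greedy_clump",
    "select_instruments",
]


def compute_pve(assoc: VariantAssociation) -> float:
    """Proportion of exposure variance explained by one variant.

    Equals ``beta² / (beta² + n·se²)``; identical to the unsimplified
    frequency-weighted form for any EAF in (0, 1).
    """
    if assoc.se <= 0:
        raise ValueError(f"{assoc.variant_id}: se must be > 0")
    if assoc.n <= 0:
        raise ValueError(f"{assoc.variant_id}: n must be > 0")
    b2 = assoc.beta**2
    return b2 / (b2 + assoc.n * assoc.se**2)


def compute_f(pve: float, n: float) -> float:
    """Instrument-strength F-statistic, ``pve·(n−2)/(1−pve)``."""
    if not 0.0 <= pve < 1.0:
        raise ValueError(f"pve must be in [0, 1), got {pve}")
    if n <= 2:
        raise ValueError(f"n must be > 2, got {n}")
    return pve * (n - 2.0) / (1.0 - pve)


@dataclass(frozen=True)
class Instrument:
    """A selected variant with variance explained and strength attached."""

    assoc: VariantAssociation
    pve: float
    f_stat: float
    is_trans: bool = False

    @classmethod
    def from_association(
        cls, assoc: VariantAssociation, gene: GeneRegion | None = None
    ) -> "Instrument":
        pve = compute_pve(assoc)
        f = compute_f(pve, assoc.n)
        is_trans = (
            not gene.contains(assoc.chrom, assoc.pos) if gene is not None else False
        )
        return cls(assoc=assoc, pve=pve, f_stat=f, is_trans=is_trans)

    @property
    def variant_id(self) -> str:
        return self.assoc.variant_id


class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered set of variants."""

    def __init__(self, variant_ids: Sequence[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        k = len(variant_ids)
        if r2.shape != (k, k):
            raise ValueError(f"r2 shape {r2.shape} != ({k}, {k})")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if k and (r2.min() < -1e-12 or r2.max() > 1 + 1e-12):
            raise ValueError("r2 entries must lie in [0, 1]")
        self.variant_ids = list(variant_ids)
        self.r2 = np.clip(r2, 0.0, 1.0)
        np.fill_diagonal(self.r2, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]} not in LD matrix") from exc

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


@dataclass
class SelectionConfig:
    """Thresholds of the instrument-selection cascade."""

    p_max: float = 5e-8
    maf_min: float = 0.01
    r2_max: float = 0.001
    window_kb: float = 10_000.0
    f_min: float = 10.0


@dataclass
class InstrumentSet:
    """Instruments retained for one gene, with per-stage removal counts."""

    gene: GeneRegion
    instruments: list[Instrument]
    selection_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def variant_ids(self) -> list[str]:
        return [inst.variant_id for inst in self.instruments]

    @property
    def any_trans(self) -> bool:
        return any(inst.is_trans for inst in self.instruments)


def _clump_sort_key(assoc: VariantAssociation):
    # ties on pval break by position then lexicographic id, so output is
    # deterministic regardless of input order
    return (assoc.pval, assoc.pos, assoc.variant_id)


def greedy_clump(
    candidates: Sequence[Instrument],
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
) -> list[Instrument]:
    """Greedy LD clumping: keep the most significant variant, drop its
    correlated neighbours, repeat.

    A candidate is dropped when it lies within ``window_kb`` of an already
    retained index variant on the same chromosome and has r² >= ``r2_max``
    with it.  Output is in retention order (ascending p-value, ties by
    position then variant id).
    """
    for inst in candidates:
        if inst.variant_id not in ld:
            raise KeyError(f"candidate {inst.variant_id} missing from LD matrix")
    window_bp = window_kb * 1000.0
    pool = sorted(candidates, key=lambda inst: _clump_sort_key(inst.assoc))
    retained: list[Instrument] = []
    while pool:
        index = pool.pop(0)
        retained.append(index)
        pool = [
            inst
            for inst in pool
            if not (
                inst.assoc.chrom == index.assoc.chrom
                and abs(inst.assoc.pos - index.assoc.pos) <= window_bp
                and ld.get(inst.variant_id, index.variant_id) >= r2_max
            )
        ]
    return retained


def select_instruments(
    exposure: SumstatsTable,
    gene: GeneRegion,
    ld: LDMatrix,
    config: SelectionConfig | None = None,
) -> InstrumentSet:
    """Apply the full selection cascade to one gene's exposure associations.

    Filters in order: genome-wide significance, MAF, greedy clumping,
    F-statistic.  ``selection_log`` records input size and the count removed
    at each stage.  An empty surviving set is not an error — the gene is
    simply skipped downstream.
    """
    config = config or SelectionConfig()
    records = exposure.records()
    log = {"input": len(records)}

    sig = [r for r in records if r.pval < config.p_max]
    log["removed_significance"] = len(records) - len(sig)

    # "minor-allele frequency > maf_min"; records with missing EAF cannot be
    # frequency-filtered and are dropped here
    common = [r for r in sig if not math.isnan(r.maf) and r.maf > config.maf_min]
    log["removed_maf"] = len(sig) - len(common)

    candidates = [Instrument.from_association(r, gene) for r in common]
    clumped = greedy_clump(candidates, ld, config.r2_max, config.window_kb)
    log["removed_clump"] = len(candidates) - len(clumped)

    strong = [inst for inst in clumped if inst.f_stat > config.f_min]
    log["removed_weak"] = len(clumped) - len(strong)
    log["retained"] = len(strong)

    return InstrumentSet(gene=gene, instruments=strong, selection_log=log)
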