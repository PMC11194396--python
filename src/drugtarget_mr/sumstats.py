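"""Summary-statistics containers, TSV I/O, and allele harmonization.

The atom of everything downstream is a per-variant summary association:
variant identifier, position, effect/other allele, effect-allele frequency
(EAF), effect size (log-odds for binary traits, SD units for quantitative
traits), its standard error, p-value and sample size.  Tables of such
records are read from tab-separated files with a configurable column map,
validated row-wise, and harmonized pairwise so that the outcome study's
effect refers to the same effect allele as the exposure study's.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantAssociation",
    "GeneRegion",
    "SumstatsTable",
    "HarmonizationResult",
    "read_sumstats",
    "write_sumstats",
    "harmonize_pair",
    "read_gene_regions",
    "write_gene_regions",
    "read_gene_list",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order used on disk
COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association in one study.

    Positions are 1-based on GRCh37.  ``eaf`` may be NaN when the source
    study did not report allele frequencies.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def validate(self) -> None:
        """Raise ``ValueError`` if any type invariant is violated."""
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: bad effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: bad other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: alleles identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not math.isnan(self.eaf) and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.variant_id}: eaf outside [0,1]")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.variant_id}: pval outside (0,1]")
        if not self.n > 0:
            raise ValueError(f"{self.variant_id}: n must be > 0")
        if not self.pos >= 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or G/C variants, whose strand is unresolvable."""
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}

    @property
    def maf(self) -> float:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``; NaN if eaf missing."""
        if math.isnan(self.eaf):
            return float("nan")
        return min(self.eaf, 1.0 - self.eaf)


@dataclass(frozen=True)
class GeneRegion:
    """A gene with its transcription start site and cis window."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int
    cis_window_bp: int = 1_000_000
    is_trans: bool = False

    def __post_init__(self) -> None:
        if self.cis_window_bp <= 0:
            raise ValueError("cis_window_bp must be > 0")

    def contains(self, chrom: str, pos: int) -> bool:
        """Is (chrom, pos) inside this gene's cis window?"""
        return chrom == self.chrom and abs(pos - self.tss) <= self.cis_window_bp


class SumstatsTable:
    """An ordered collection of :class:`VariantAssociation` for one trait.

    Backed by a :class:`pandas.DataFrame` with the canonical columns; rows
    keep their file order and ``variant_id`` is unique.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        trait_id: str = "trait",
        trait_type: str = "quantitative",
        n_cases: int | None = None,
        n_controls: int | None = None,
    ):
        if trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {trait_type!r}")
        if trait_type == "binary" and (n_cases is None or n_controls is None):
            raise ValueError("binary traits require n_cases and n_controls")
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if df["variant_id"].duplicated().any():
            dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
            raise ValueError(f"duplicate variant_id(s): {dups[:5]}")
        self.df = df.loc[:, COLUMNS].reset_index(drop=True)
        self.trait_id = trait_id
        self.trait_type = trait_type
        self.n_cases = n_cases
        self.n_controls = n_controls
        self._index: dict[str, int] = {
            v: i for i, v in enumerate(self.df["variant_id"])
        }

    @classmethod
    def from_records(
        cls, records: Iterable[VariantAssociation], **kwargs
    ) -> "SumstatsTable":
        rows = [
            {c: getattr(r, c) for c in COLUMNS}
            for r in records
        ]
        df = pd.DataFrame(rows, columns=COLUMNS)
        return cls(df, **kwargs)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records())

    def get(self, variant_id: str) -> VariantAssociation | None:
        i = self._index.get(variant_id)
        if i is None:
            return None
        return self._row_to_record(self.df.iloc[i])

    @staticmethod
    def _row_to_record(row: pd.Series) -> VariantAssociation:
        return VariantAssociation(
            variant_id=str(row["variant_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=str(row["other_allele"]),
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            n=float(row["n"]),
        )

    def records(self) -> list[VariantAssociation]:
        return [self._row_to_record(row) for _, row in self.df.iterrows()]

    def subset(self, variant_ids: Sequence[str]) -> "SumstatsTable":
        """Rows for ``variant_ids`` (present ones only), in table order."""
        keep = self.df["variant_id"].isin(set(variant_ids))
        return SumstatsTable(
            self.df.loc[keep],
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )

    def in_region(self, gene: GeneRegion) -> "SumstatsTable":
        """Rows within ``gene``'s cis window."""
        keep = (self.df["chrom"].astype(str) == gene.chrom) & (
            (self.df["pos"] - gene.tss).abs() <= gene.cis_window_bp
        )
        return SumstatsTable(
            self.df.loc[keep],
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Coerce dtypes and drop rows violating the record invariants."""
    df = df.copy()
    for col, typ in [
        ("pos", "Int64"),
        ("eaf", float),
        ("beta", float),
        ("se", float),
        ("pval", float),
        ("n", float),
    ]:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(typ)
    for col in ("variant_id", "chrom", "effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()

    ok = (
        df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["se"] > 0)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["n"] > 0)
        & df["beta"].notna()
        & df["pos"].notna()
        & (df["pos"] >= 1)
    )
    n_dropped = int((~ok).sum())
    df = df.loc[ok].copy()
    df["pos"] = df["pos"].astype(int)
    df["eaf"] = df["eaf"].astype(float)
    return df, n_dropped


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "trait",
    trait_type: str = "quantitative",
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SumstatsTable:
    """Read a tab-separated summary-statistics file.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Mapping from canonical field name (``variant_id`` ... ``n``) to the
        column name in the file.  Defaults to the canonical names.

    Rows violating the per-record invariants (se <= 0, eaf outside [0,1],
    identical alleles, ...) are dropped and counted; the count is stored on
    the returned table as ``n_dropped`` and logged.  A missing mandatory
    column or an empty table after validation is fatal.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep="\t", dtype=str)
    rename = {column_map.get(c, c): c for c in COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    df = raw.rename(columns=rename)
    df, n_dropped = _validate_frame(df)
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path, n_dropped)
    if df.empty:
        raise ValueError(f"{path}: no valid rows after validation")
    table = SumstatsTable(
        df, trait_id=trait_id, trait_type=trait_type,
        n_cases=n_cases, n_controls=n_controls,
    )
    table.n_dropped = n_dropped  # type: ignore[attr-defined]
    return table


def write_sumstats(table: SumstatsTable, path) -> None:
    """Write a table as TSV with the canonical columns.

    Floats are written at 10 significant digits so a read/write round trip
    is the identity to that precision.
    """
    table.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# harmonization


@dataclass(frozen=True)
class HarmonizationResult:
    """Outcome of aligning one outcome record to the exposure's alleles.

    ``action`` is one of ``kept``, ``flipped``, ``complemented``,
    ``complemented_flipped`` or ``rejected:<reason>``; ``outcome`` is the
    aligned record (None on rejection).
    """

    variant_id: str
    action: str
    outcome: VariantAssociation | None = None

    @property
    def ok(self) -> bool:
        return self.outcome is not None


def _swap(rec: VariantAssociation) -> VariantAssociation:
    """Swap effect/other alleles, negating beta and reflecting eaf."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=1.0 - rec.eaf if not math.isnan(rec.eaf) else float("nan"),
    )


def _complement(rec: VariantAssociation) -> VariantAssociation:
    """Flip both alleles to the other strand; effect direction unchanged."""
    return replace(
        rec,
        effect_allele=_COMPLEMENT[rec.effect_allele],
        other_allele=_COMPLEMENT[rec.other_allele],
    )


def harmonize_pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizationResult:
    """Align an outcome record to the exposure's effect allele.

    Rules, applied in order:

    1. Palindromic variants (A/T or G/C) whose exposure EAF lies strictly
       inside ``palindrome_eaf_band`` are rejected as strand-ambiguous;
       outside the band they are aligned by frequency (effect alleles match
       when both EAFs sit on the same side of 0.5).  A palindromic variant
       with missing outcome EAF is rejected.
    2. Matching allele pairs are kept as-is; swapped pairs have the outcome
       beta negated and EAF reflected.
    3. Otherwise the outcome alleles are strand-complemented and step 2 is
       retried.  Irreconcilable allele sets are rejected.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    vid = exposure.variant_id
    ea, oa = exposure.effect_allele, exposure.other_allele

    if exposure.is_palindromic:
        lo, hi = palindrome_eaf_band
        if math.isnan(exposure.eaf) or lo < exposure.eaf < hi:
            return HarmonizationResult(vid, "rejected:palindromic-ambiguous")
        if {outcome.effect_allele, outcome.other_allele} != {ea, oa} and {
            _COMPLEMENT[outcome.effect_allele],
            _COMPLEMENT[outcome.other_allele],
        } != {ea, oa}:
            return HarmonizationResult(vid, "rejected:allele-mismatch")
        if math.isnan(outcome.eaf) or lo < outcome.eaf < hi:
            return HarmonizationResult(vid, "rejected:palindromic-ambiguous")
        # align by frequency: same side of 0.5 means same allele
        same_side = (exposure.eaf < 0.5) == (outcome.eaf < 0.5)
        aligned = outcome if same_side else _swap(outcome)
        # label the alleles with the exposure's strand representation
        aligned = replace(aligned, effect_allele=ea, other_allele=oa)
        return HarmonizationResult(vid, "kept" if same_side else "flipped", aligned)

    if (outcome.effect_allele, outcome.other_allele) == (ea, oa):
        return HarmonizationResult(vid, "kept", outcome)
    if (outcome.effect_allele, outcome.other_allele) == (oa, ea):
        return HarmonizationResult(vid, "flipped", _swap(outcome))

    comp = _complement(outcome)
    if (comp.effect_allele, comp.other_allele) == (ea, oa):
        return HarmonizationResult(vid, "complemented", comp)
    if (comp.effect_allele, comp.other_allele) == (oa, ea):
        return HarmonizationResult(vid, "complemented_flipped", _swap(comp))

    return HarmonizationResult(vid, "rejected:allele-mismatch")


def write_harmonization_report(results: Iterable[HarmonizationResult], path) -> None:
    pd.DataFrame(
        [{"variant_id": r.variant_id, "action": r.action} for r in results]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene metadata


def read_gene_regions(path) -> list[GeneRegion]:
    """Read gene regions from TSV: gene_id, symbol, chrom, tss, cis_window_bp[, is_trans]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = []
    for _, row in df.iterrows():
        genes.append(
            GeneRegion(
                gene_id=str(row["gene_id"]),
                symbol=str(row["symbol"]),
                chrom=str(row["chrom"]),
                tss=int(row["tss"]),
                cis_window_bp=int(row.get("cis_window_bp", 1_000_000)),
                is_trans=bool(row.get("is_trans", False)),
            )
        )
    return genes


def write_gene_regions(genes: Sequence[GeneRegion], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.chrom,
                "tss": g.tss,
                "cis_window_bp": g.cis_window_bp,
                "is_trans": g.is_trans,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One gene identifier per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [
            line.strip()
            for line in fh
            if line.strip() and not line.startswith("#")
        ]
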