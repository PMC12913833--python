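"""Data model, validation and text I/O for GWAS/QTL summary statistics.

The universal currency of the pipeline is a table of per-variant
associations for one trait: identifier, genomic location, effect and
other allele, effect-allele frequency, effect size (log-odds for binary
traits, SD units for quantitative ones), its standard error, p-value and
sample size.  ``SumStats`` wraps such a table after validation;
``LDMatrix`` holds a square matrix of pairwise allelic correlations (r);
``DERecord`` rows carry tumor-vs-normal differential expression.

All files are UTF-8 tab-separated text with a header row and '.' decimal
separator.  Column names are configurable through a schema mapping; the
default dialect is ``variant, chrom, pos, ea, oa, eaf, beta, se, p, n``.
Positions are 1-based on a single genome build treated as metadata only.
Missing effect-allele frequency is permitted on input, but any operation
that needs it fails loudly rather than imputing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateVariantError,
    LDMatrixError,
    SchemaError,
    SumStatsValidationError,
)

_NUCLEOTIDES = frozenset("ACGT")

#: canonical internal column order for a summary-statistics table
COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

#: default file dialect: canonical field -> column header in the file
DEFAULT_SCHEMA: Mapping[str, str] = {
    "variant_id": "variant",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "p",
    "n": "n",
}


class TraitType(str, Enum):
    EQTL = "eqtl"
    PQTL = "pqtl"
    IMMUNE_CELL = "immune_cell"
    OUTCOME = "outcome"


@dataclass(frozen=True)
class AssocRecord:
    """One variant's association with one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: float

    def __post_init__(self):
        problems = _record_problems(
            self.effect_allele, self.other_allele, self.eaf, self.se,
            self.pvalue, self.n, self.pos,
        )
        if problems:
            raise SumStatsValidationError(
                f"variant {self.variant_id!r}: " + "; ".join(problems)
            )


def _record_problems(ea, oa, eaf, se, pvalue, n, pos) -> list[str]:
    out = []
    if ea not in _NUCLEOTIDES:
        out.append(f"effect allele {ea!r} is not a single uppercase nucleotide")
    if oa not in _NUCLEOTIDES:
        out.append(f"other allele {oa!r} is not a single uppercase nucleotide")
    if ea in _NUCLEOTIDES and ea == oa:
        out.append("effect allele equals other allele")
    if eaf is not None and not np.isnan(eaf) and not (0.0 <= eaf <= 1.0):
        out.append(f"eaf {eaf} outside [0, 1]")
    if not (se > 0):
        out.append(f"se {se} is not positive")
    if not (0.0 < pvalue <= 1.0):
        out.append(f"p-value {pvalue} outside (0, 1]")
    if not (n > 0):
        out.append(f"sample size {n} is not positive")
    if not (pos >= 1):
        out.append(f"position {pos} is not 1-based positive")
    return out


@dataclass
class SumStats:
    """Validated per-variant summary statistics for a single trait.

    ``df`` holds one row per variant in input order with the canonical
    columns of :data:`COLUMNS`; ``eaf`` may be NaN (missing).
    """

    trait_id: str
    trait_type: TraitType
    df: pd.DataFrame
    is_binary: bool = False
    case_fraction: float | None = None

    def __post_init__(self):
        self.trait_type = TraitType(self.trait_type)
        if self.is_binary:
            if self.case_fraction is None or not (0 < self.case_fraction < 1):
                raise SumStatsValidationError(
                    f"trait {self.trait_id!r}: binary traits require "
                    "case_fraction in (0, 1)"
                )
        elif self.case_fraction is not None:
            raise SumStatsValidationError(
                f"trait {self.trait_id!r}: case_fraction given for a "
                "non-binary trait"
            )
        self.df = validate_frame(self.df)

    @property
    def n_variants(self) -> int:
        return len(self.df)

    @property
    def records(self) -> tuple[AssocRecord, ...]:
        return tuple(
            AssocRecord(
                variant_id=r.variant_id, chrom=r.chrom, pos=int(r.pos),
                effect_allele=r.effect_allele, other_allele=r.other_allele,
                eaf=None if pd.isna(r.eaf) else float(r.eaf),
                beta=float(r.beta), se=float(r.se),
                pvalue=float(r.pvalue), n=float(r.n),
            )
            for r in self.df.itertuples(index=False)
        )

    def subset(self, variant_ids: Iterable[str]) -> pd.DataFrame:
        """Rows for the given variants, in the given order."""
        idx = self.df.set_index("variant_id")
        return idx.loc[list(variant_ids)].reset_index()


def validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a canonical-column frame row by row.

    Returns a typed copy; raises with 1-based row numbers on the first
    batch of violations, never silently coercing bad rows.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = df.loc[:, list(COLUMNS)].copy().reset_index(drop=True)
    out["variant_id"] = out["variant_id"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    for c in ("effect_allele", "other_allele"):
        out[c] = out[c].astype(str).str.upper()
    try:
        out["pos"] = out["pos"].astype(np.int64)
        for c in ("eaf", "beta", "se", "pvalue", "n"):
            out[c] = pd.to_numeric(out[c], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise SumStatsValidationError(f"non-numeric value: {exc}") from exc

    dup = out["variant_id"][out["variant_id"].duplicated()]
    if len(dup):
        raise DuplicateVariantError(
            "duplicate variant_id(s): " + ", ".join(sorted(set(dup)))
        )
    errors = []
    for i, r in enumerate(out.itertuples(index=False)):
        eaf = None if np.isnan(r.eaf) else r.eaf
        for msg in _record_problems(
            r.effect_allele, r.other_allele, eaf, r.se, r.pvalue, r.n, r.pos
        ):
            errors.append(f"row {i + 1} ({r.variant_id}): {msg}")
    if errors:
        raise SumStatsValidationError("; ".join(errors))
    return out


def read_sumstats(
    path: str | Path,
    *,
    trait_id: str,
    trait_type: TraitType | str,
    schema: Mapping[str, str] | None = None,
    is_binary: bool = False,
    case_fraction: float | None = None,
) -> SumStats:
    """Read one trait's summary statistics from a TSV file.

    ``schema`` maps canonical field names to the file's column headers;
    omitted entries fall back to :data:`DEFAULT_SCHEMA`. Row order is
    preserved and every row is validated.
    """
    effective = dict(DEFAULT_SCHEMA)
    if schema:
        effective.update(schema)
    raw = pd.read_csv(path, sep="\t", dtype={effective["chrom"]: str})
    # eaf is the one column some sources (eQTLGen-style) omit entirely
    missing = [
        col for field_, col in effective.items()
        if col not in raw.columns and field_ != "eaf"
    ]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    df = raw.rename(columns={v: k for k, v in effective.items()})
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    return SumStats(
        trait_id=trait_id,
        trait_type=TraitType(trait_type),
        df=df,
        is_binary=is_binary,
        case_fraction=case_fraction,
    )


def write_sumstats(stats: SumStats, path: str | Path) -> Path:
    """Write to TSV in the default dialect; inverse of :func:`read_sumstats`."""
    path = Path(path)
    out = stats.df.rename(columns=dict(DEFAULT_SCHEMA))
    out.to_csv(path, sep="\t", index=False, na_rep="nan",
               float_format="%.17g")
    return path


@dataclass
class LDMatrix:
    """Square symmetric matrix of pairwise allelic correlations (r)."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise LDMatrixError(
                f"matrix shape {self.r.shape} does not match "
                f"{k} variant ids"
            )
        if np.abs(self.r).max(initial=0.0) > 1 + 1e-8:
            raise LDMatrixError("entries with |r| > 1")
        asym = np.abs(self.r - self.r.T).max(initial=0.0)
        if asym > 1e-6:
            raise LDMatrixError(f"asymmetry {asym:.3g} exceeds 1e-6")
        # symmetrize tiny numerical asymmetry by averaging
        self.r = 0.5 * (self.r + self.r.T)
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise LDMatrixError("diagonal entries must equal 1")

    def r2(self, a: str, b: str) -> float:
        i = self.variant_ids.index(a)
        j = self.variant_ids.index(b)
        return float(self.r[i, j] ** 2)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.variant_ids


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square LD (r) matrix: id header row, ids in first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids_row = [str(c) for c in df.columns]
    ids_col = [str(i) for i in df.index]
    if len(ids_row) != len(ids_col) or ids_row != ids_col:
        raise LDMatrixError(
            "matrix is not square with matching row/column identifiers"
        )
    return LDMatrix(variant_ids=ids_row, r=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )
    return path


@dataclass(frozen=True)
class DERecord:
    """Tumor-vs-normal differential expression for one gene."""

    gene_id: str
    log2fc: float
    qvalue: float

    def __post_init__(self):
        if not (0.0 <= self.qvalue <= 1.0):
            raise SumStatsValidationError(
                f"gene {self.gene_id!r}: q-value {self.qvalue} outside [0, 1]"
            )


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a (gene_id, log2fc, qvalue) TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene_id", "log2fc", "qvalue") if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return [
        DERecord(str(r.gene_id), float(r.log2fc), float(r.qvalue))
        for r in df.itertuples(index=False)
    ]


def write_de_table(records: Sequence[DERecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(r.gene_id, r.log2fc, r.qvalue) for r in records],
        columns=["gene_id", "log2fc", "qvalue"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path
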