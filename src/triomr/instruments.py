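"""Instrument selection, LD clumping, strength filtering and harmonization.

A valid genetic instrument must be robustly associated with the exposure,
approximately independent of the other instruments, strong enough to
avoid weak-instrument bias, and carried on alleles that can be aligned
between the exposure and outcome studies.  The four operations here
implement that screen:

* :func:`select_by_pvalue` — genome-wide significance filter (default
  p < 5e-8).
* :func:`ld_clump` — greedy pruning within a 10,000 kb window at
  r² < 0.001, keeping the lowest-p variant of each correlated clump.
* :func:`compute_f_stats` — per-SNP F = (beta/se)², retaining F > 10,
  plus the 2·eaf·(1−eaf)·beta² variance-explained approximation that
  feeds the power calculation.
* :func:`harmonize` — aligns outcome effects to the exposure's effect
  allele, flipping swapped alleles, dropping palindromic (A/T, C/G) and
  irreconcilable variants, and applying a caller-supplied confounder
  exclusion list (the stand-in for external trait-catalog screens).

Every variant dropped anywhere is counted in exactly one provenance
category so the final instrument table is fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LDCoverageError, NoInstrumentsError
from .sumstats import LDMatrix, SumStats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: provenance categories, in filter order
PROVENANCE_KEYS = (
    "below_p_threshold",
    "clumped",
    "low_f",
    "not_in_outcome",
    "palindromic",
    "allele_mismatch",
    "confounder_excluded",
)

INSTRUMENT_COLUMNS = (
    "variant_id", "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "f_stat", "flipped",
)


@dataclass
class InstrumentSet:
    """Harmonized exposure-outcome instrument table.

    ``table`` has one row per retained SNP with columns
    ``variant_id, beta_exp, se_exp, beta_out, se_out, eaf_exp, f_stat,
    flipped``; ``provenance`` counts variants dropped at each filter.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in INSTRUMENT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"instrument table missing columns: {missing}")
        self.table = self.table.loc[:, list(INSTRUMENT_COLUMNS)].reset_index(
            drop=True
        )
        if (self.table["se_exp"] <= 0).any() or (self.table["se_out"] <= 0).any():
            raise ValueError("instrument standard errors must be positive")
        if (self.table["f_stat"] < 0).any():
            raise ValueError("F statistics must be non-negative")
        self.provenance = {k: int(self.provenance.get(k, 0))
                           for k in PROVENANCE_KEYS}

    @property
    def n_snp(self) -> int:
        return len(self.table)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.table["beta_exp"].to_numpy()

    @property
    def se_exp(self) -> np.ndarray:
        return self.table["se_exp"].to_numpy()

    @property
    def beta_out(self) -> np.ndarray:
        return self.table["beta_out"].to_numpy()

    @property
    def se_out(self) -> np.ndarray:
        return self.table["se_out"].to_numpy()

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def select_by_pvalue(stats: SumStats, p_threshold: float = 5e-8) -> list[str]:
    """Variants with p strictly below the threshold, ascending p order.

    Raises :class:`NoInstrumentsError` when none qualify; the caller
    decides whether that is fatal.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold {p_threshold} outside (0, 1]")
    hits = stats.df[stats.df["pvalue"] < p_threshold]
    if hits.empty:
        raise NoInstrumentsError(
            f"no variant of {stats.trait_id!r} reaches p < {p_threshold:g}"
        )
    return hits.sort_values(
        ["pvalue", "chrom", "pos", "variant_id"], kind="mergesort"
    )["variant_id"].tolist()


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix | None,
    window_kb: float = 10_000.0,
    r2_max: float = 0.001,
    assume_independent: bool = False,
) -> list[str]:
    """Greedy LD clumping.

    ``candidates`` needs columns ``variant_id, chrom, pos, pvalue``.
    Repeatedly the lowest-p unclaimed variant becomes an index and
    claims (removes) every unclaimed variant on the same chromosome
    within ``window_kb`` of it with r² ≥ ``r2_max``.  Ties on p are
    broken by (chrom, pos, variant_id) so the result is deterministic.
    Returns the retained index variants sorted by (chrom, pos).

    With ``assume_independent`` the LD matrix may be None/partial and
    uncovered pairs are treated as r = 0; otherwise a candidate missing
    from ``ld`` is a coverage error.
    """
    cand = candidates.reset_index(drop=True)
    if not assume_independent:
        if ld is None:
            raise LDCoverageError("no LD matrix and independence not asserted")
        missing = [v for v in cand["variant_id"] if v not in ld]
        if missing:
            raise LDCoverageError(
                "candidates absent from LD matrix: " + ", ".join(missing)
            )
    order = cand.sort_values(
        ["pvalue", "chrom", "pos", "variant_id"], kind="mergesort"
    )
    claimed: set[str] = set()
    retained: list[tuple[str, int, str]] = []
    rows = list(order.itertuples(index=False))
    for idx_row in rows:
        if idx_row.variant_id in claimed:
            continue
        retained.append((idx_row.chrom, int(idx_row.pos), idx_row.variant_id))
        claimed.add(idx_row.variant_id)
        for other in rows:
            if other.variant_id in claimed:
                continue
            if other.chrom != idx_row.chrom:
                continue
            if abs(int(other.pos) - int(idx_row.pos)) > window_kb * 1000:
                continue
            if ld is not None and other.variant_id in ld and idx_row.variant_id in ld:
                r2 = ld.r2(idx_row.variant_id, other.variant_id)
            else:
                r2 = 0.0
            if r2 >= r2_max:
                claimed.add(other.variant_id)
    retained.sort()
    return [v for _, _, v in retained]


@dataclass
class FStatReport:
    """Per-SNP instrument strength and variance explained."""

    table: pd.DataFrame  # variant_id, f_stat, r2
    retained: list[str]
    mean_f: float
    sum_r2: float | None  # None when any eaf is missing


def compute_f_stats(
    stats: SumStats, variants: list[str], f_min: float = 10.0
) -> FStatReport:
    """Per-SNP F = (beta/se)²; retain variants with F strictly > f_min.

    Also reports per-SNP R² = 2·eaf·(1−eaf)·beta² (the standardized-trait
    approximation) and their sum for the power hand-off; R² is left as
    NaN — and the sum as None — when eaf is missing, which never blocks
    the F filter itself.
    """
    sub = stats.subset(variants)
    f = (sub["beta"] / sub["se"]) ** 2
    r2 = 2.0 * sub["eaf"] * (1.0 - sub["eaf"]) * sub["beta"] ** 2
    table = pd.DataFrame(
        {"variant_id": sub["variant_id"], "f_stat": f, "r2": r2}
    )
    retained = table.loc[table["f_stat"] > f_min, "variant_id"].tolist()
    sum_r2 = None if r2.isna().any() else float(r2.sum())
    return FStatReport(
        table=table,
        retained=retained,
        mean_f=float(f.mean()),
        sum_r2=sum_r2,
    )


def is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(
    exposure: SumStats,
    outcome: SumStats,
    variants: list[str],
    exclusion_list: list[str] | tuple[str, ...] = (),
    provenance: dict | None = None,
) -> InstrumentSet:
    """Align outcome effects to the exposure's effect allele.

    For each variant: identical allele pairs are kept as-is; swapped
    pairs (effect and other allele exchanged) keep the variant with the
    outcome beta negated and ``flipped`` set; palindromic (A/T or C/G)
    pairs are dropped unconditionally; any other combination is an
    allele mismatch and dropped.  Variants on ``exclusion_list``
    (known-confounder associations, normally compiled from external
    trait catalogs) are dropped first.  Variants absent from either
    trait are counted as dropped, never errors.

    ``provenance`` carries counts from earlier filter stages forward
    into the returned :class:`InstrumentSet`.
    """
    prov = {k: 0 for k in PROVENANCE_KEYS}
    if provenance:
        for k, v in provenance.items():
            prov[k] = prov.get(k, 0) + int(v)
    excl = set(exclusion_list)
    exp_idx = exposure.df.set_index("variant_id")
    out_idx = outcome.df.set_index("variant_id")
    rows = []
    for v in variants:
        if v in excl:
            prov["confounder_excluded"] += 1
            continue
        if v not in exp_idx.index or v not in out_idx.index:
            prov["not_in_outcome"] += 1
            continue
        e = exp_idx.loc[v]
        o = out_idx.loc[v]
        if is_palindromic(e.effect_allele, e.other_allele) or is_palindromic(
            o.effect_allele, o.other_allele
        ):
            prov["palindromic"] += 1
            continue
        if (o.effect_allele, o.other_allele) == (
            e.effect_allele, e.other_allele,
        ):
            beta_out, flipped = o.beta, False
        elif (o.effect_allele, o.other_allele) == (
            e.other_allele, e.effect_allele,
        ):
            beta_out, flipped = -o.beta, True
        else:
            prov["allele_mismatch"] += 1
            continue
        rows.append(
            dict(
                variant_id=v,
                beta_exp=float(e.beta),
                se_exp=float(e.se),
                beta_out=float(beta_out),
                se_out=float(o.se),
                eaf_exp=float(e.eaf) if pd.notna(e.eaf) else np.nan,
                f_stat=float((e.beta / e.se) ** 2),
                flipped=flipped,
            )
        )
    table = pd.DataFrame(rows, columns=list(INSTRUMENT_COLUMNS))
    instr = InstrumentSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        table=table,
        provenance=prov,
    )
    if instr.n_snp == 0:
        raise NoInstrumentsError(
            f"harmonization of {exposure.trait_id!r} vs "
            f"{outcome.trait_id!r} left no instruments "
            f"(provenance: {prov})"
        )
    return instr
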