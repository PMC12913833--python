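"""Cross-omics candidate-gene prioritization.

A gene is a credible candidate when three independent lines of evidence
converge: an expression-level MR association (eQTL instruments), a
protein-level MR association (pQTL instruments), and tumor-vs-normal
differential expression.  Genes in the triple intersection are
classified by direction concordance:

* protective MR effects (negative betas at both omic levels) combined
  with down-regulation in tumors → ``suppressive_candidate``;
* risk-increasing MR effects with up-regulation → ``oncogenic_candidate``;
* mixed signs → ``discordant``;
* any missing stage → ``incomplete``.

Stage-level significance is the nominal p < 0.05 screen; Bonferroni and
Benjamini-Hochberg adjusted values are carried alongside for reporting
rather than used as the gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DuplicateVariantError
from .sumstats import DERecord


@dataclass(frozen=True)
class GeneEvidence:
    gene_id: str
    eqtl_beta: float | None
    eqtl_p: float | None
    pqtl_beta: float | None
    pqtl_p: float | None
    log2fc: float | None
    de_q: float | None
    bonferroni_p: float | None
    bh_q: float | None
    gene_class: str  # oncogenic_candidate | suppressive_candidate |
    #                  discordant | incomplete


def filter_de_table(
    table: Sequence[DERecord], lfc_min: float = 1.0, q_max: float = 0.05
) -> pd.DataFrame:
    """Retain genes with |log2FC| strictly above ``lfc_min`` and q
    strictly below ``q_max``; label direction by the sign of log2FC.

    Boundary values (|log2FC| == lfc_min, q == q_max) are dropped: the
    thresholds are strict on both sides.
    """
    rows = [
        dict(gene_id=r.gene_id, log2fc=r.log2fc, qvalue=r.qvalue,
             direction="up" if r.log2fc > 0 else "down")
        for r in table
        if abs(r.log2fc) > lfc_min and r.qvalue < q_max
    ]
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "qvalue",
                                       "direction"])


def adjust_pvalues(
    pvalues: Sequence[float], method: str = "bh"
) -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni`` gives min(1, m·p); ``bh`` gives Benjamini-Hochberg
    step-up adjusted values (monotone, capped at 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def _check_unique(df: pd.DataFrame, stage: str) -> None:
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise DuplicateVariantError(
            f"duplicate gene id(s) in {stage} stage: "
            + ", ".join(sorted(set(dup)))
        )


def intersect_and_classify(
    eqtl_hits: pd.DataFrame,
    pqtl_hits: pd.DataFrame,
    de_hits: pd.DataFrame,
    n_tests_bonferroni: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full join of the three evidence stages with direction classes.

    Inputs: ``eqtl_hits``/``pqtl_hits`` with columns
    ``gene_id, beta, pvalue``; ``de_hits`` with
    ``gene_id, log2fc, qvalue``.  Gene ids are matched exactly after
    case folding.  Returns the evidence table plus Venn counts of the
    three stages and their intersections.

    ``n_tests_bonferroni`` overrides the Bonferroni multiplier for the
    eQTL p-values (e.g. the full transcriptome-wide test count); the
    default is the number of eQTL hits supplied.
    """
    frames = []
    for df, stage, cols in (
        (eqtl_hits, "eqtl", {"beta": "eqtl_beta", "pvalue": "eqtl_p"}),
        (pqtl_hits, "pqtl", {"beta": "pqtl_beta", "pvalue": "pqtl_p"}),
        (de_hits, "de", {"log2fc": "log2fc", "qvalue": "de_q"}),
    ):
        d = df.copy()
        d["gene_id"] = d["gene_id"].astype(str).str.casefold()
        _check_unique(d, stage)
        frames.append(d.rename(columns=cols).set_index("gene_id"))
    merged = frames[0].join(frames[1], how="outer").join(
        frames[2], how="outer"
    ).reset_index()

    # adjusted values for the eQTL screen, carried for reporting
    has_eqtl = merged["eqtl_p"].notna()
    merged["bonferroni_p"] = np.nan
    merged["bh_q"] = np.nan
    if has_eqtl.any():
        p = merged.loc[has_eqtl, "eqtl_p"].to_numpy()
        m = n_tests_bonferroni if n_tests_bonferroni else p.size
        merged.loc[has_eqtl, "bonferroni_p"] = np.minimum(1.0, p * m)
        merged.loc[has_eqtl, "bh_q"] = adjust_pvalues(p, "bh")

    def classify(row) -> str:
        if (
            pd.isna(row.eqtl_beta)
            or pd.isna(row.pqtl_beta)
            or pd.isna(row.log2fc)
        ):
            return "incomplete"
        protective = row.eqtl_beta < 0 and row.pqtl_beta < 0
        risk = row.eqtl_beta > 0 and row.pqtl_beta > 0
        if protective and row.log2fc < 0:
            return "suppressive_candidate"
        if risk and row.log2fc > 0:
            return "oncogenic_candidate"
        return "discordant"

    merged["gene_class"] = [
        classify(r) for r in merged.itertuples(index=False)
    ]
    in_e = merged["eqtl_beta"].notna()
    in_p = merged["pqtl_beta"].notna()
    in_d = merged["log2fc"].notna()
    venn = {
        "eqtl": int(in_e.sum()),
        "pqtl": int(in_p.sum()),
        "de": int(in_d.sum()),
        "eqtl_pqtl": int((in_e & in_p).sum()),
        "eqtl_de": int((in_e & in_d).sum()),
        "pqtl_de": int((in_p & in_d).sum()),
        "triple": int((in_e & in_p & in_d).sum()),
    }
    return merged, venn
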