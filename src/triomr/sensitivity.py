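"""Heterogeneity, pleiotropy and influence diagnostics.

Three checks probe the instrumental-variable assumptions after
estimation: Cochran's Q (heterogeneity of the per-SNP ratio estimates
around the IVW pooled estimate — large Q suggests invalid instruments
or multiple causal pathways), the MR-Egger intercept (directional
pleiotropy), and leave-one-out re-estimation (single-variant influence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientInstrumentsError
from .estimators import ivw, mr_egger
from .instruments import InstrumentSet


@dataclass
class SensitivityReport:
    q_stat: float
    q_df: int
    q_pvalue: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_p: float | None
    loo_table: pd.DataFrame | None  # variant_id, beta, se, ci_low, ci_high
    influential_flags: list[str]

    def to_dict(self) -> dict:
        return {
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pvalue": self.q_pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
            "loo_table": (
                None if self.loo_table is None
                else self.loo_table.to_dict(orient="records")
            ),
            "influential_flags": self.influential_flags,
        }


def cochran_q(instr: InstrumentSet) -> tuple[float, int, float]:
    """Q = Σ wⱼ(β̂ⱼ − β_IVW)², wⱼ = beta_expⱼ²/se_outⱼ², df = k − 1.

    β̂ⱼ is the per-SNP ratio and β_IVW the fixed-effect pooled estimate;
    under homogeneity Q is chi-square with k − 1 degrees of freedom.
    """
    k = instr.n_snp
    if k < 2:
        raise InsufficientInstrumentsError(
            f"Cochran's Q needs ≥ 2 instruments, got {k}"
        )
    fe, _ = ivw(instr)
    ratios = instr.beta_out / instr.beta_exp
    w = instr.beta_exp**2 / instr.se_out**2
    q = float(np.sum(w * (ratios - fe.beta) ** 2))
    df = k - 1
    p = float(sps.chi2.sf(q, df))
    return q, df, min(max(p, 1e-300), 1.0)


def leave_one_out(instr: InstrumentSet) -> tuple[pd.DataFrame, list[str]]:
    """Fixed-effect IVW with each SNP excluded in turn.

    A SNP is flagged influential when its exclusion moves the point
    estimate outside the all-SNP 95% confidence interval.
    """
    k = instr.n_snp
    if k < 3:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs ≥ 3 instruments, got {k}"
        )
    full_fe, _ = ivw(instr)
    rows = []
    flags = []
    for i in range(k):
        sub = InstrumentSet(
            exposure_id=instr.exposure_id,
            outcome_id=instr.outcome_id,
            table=instr.table.drop(index=i),
            provenance=instr.provenance,
        )
        est, _ = ivw(sub)
        vid = instr.table.iloc[i]["variant_id"]
        rows.append(
            dict(variant_id=vid, beta=est.beta, se=est.se,
                 ci_low=est.ci_low, ci_high=est.ci_high)
        )
        if not (full_fe.ci_low <= est.beta <= full_fe.ci_high):
            flags.append(vid)
    return pd.DataFrame(rows), flags


def sensitivity_report(instr: InstrumentSet) -> SensitivityReport:
    """Full diagnostic battery; Egger/LOO are None below their minima."""
    q, df, p = cochran_q(instr)
    egger_int = egger_se = egger_p = None
    loo = None
    flags: list[str] = []
    if instr.n_snp >= 3:
        eg = mr_egger(instr)
        egger_int = eg.extra["intercept"]
        egger_se = eg.extra["intercept_se"]
        egger_p = eg.extra["intercept_p"]
        loo, flags = leave_one_out(instr)
    return SensitivityReport(
        q_stat=q, q_df=df, q_pvalue=p,
        egger_intercept=egger_int,
        egger_intercept_se=egger_se,
        egger_intercept_p=egger_p,
        loo_table=loo,
        influential_flags=flags,
    )
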