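"""Three-step mediation on Mendelian-randomization estimates.

The model decomposes the total genetically-predicted effect of an
exposure (gene expression) on a binary outcome (disease log-odds) into
a path through a mediator (an immune-cell trait) and a residual direct
path:

    step 1   exposure → outcome          β_total
    step 2   mediator → outcome          β₂  (mediator's own instruments)
    step 3   exposure → mediator         β₁

    indirect effect      β_indirect = β₁ · β₂
    direct effect        β_direct   = β_total − β_indirect
    proportion mediated  100 · β_indirect / β_total  (%)

The indirect-effect standard error is the first-order (Sobel-type)
delta approximation sqrt(β₁²·se₂² + β₂²·se₁²).  The proportion is
reported unclipped — it can exceed 100% or go negative when path signs
are inconsistent — with an explicit flag, because clipping would hide a
model violation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .estimators import MREstimate, Z95


@dataclass(frozen=True)
class MediationResult:
    beta_total: float
    beta_xm: float           # β₁, exposure → mediator
    beta_my: float           # β₂, mediator → outcome (log-odds)
    beta_indirect: float     # β₁·β₂
    se_indirect: float
    ci_indirect: tuple[float, float]
    beta_direct: float
    proportion_mediated_pct: float | None
    proportion_outside_0_100: bool
    or_total: float
    or_indirect: float

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci_indirect"] = list(self.ci_indirect)
        return d


def three_step_mediation(
    est_total: MREstimate, est_xm: MREstimate, est_my: MREstimate
) -> MediationResult:
    """Product-of-coefficients mediation from three MR estimates.

    ``est_total`` and ``est_my`` must be on the outcome log-odds scale;
    ``est_xm`` is in mediator SD units per exposure SD.  When the total
    effect is zero the proportion mediated is undefined and reported as
    None with a warning; all other fields are still returned.
    """
    b1, se1 = est_xm.beta, est_xm.se
    b2, se2 = est_my.beta, est_my.se
    total = est_total.beta
    indirect = b1 * b2
    se_ind = math.sqrt(b1**2 * se2**2 + b2**2 * se1**2)
    ci = (indirect - Z95 * se_ind, indirect + Z95 * se_ind)
    if total == 0:
        warnings.warn(
            "total effect is zero: proportion mediated undefined",
            stacklevel=2,
        )
        prop = None
        outside = False
    else:
        prop = 100.0 * indirect / total
        outside = not (0.0 <= prop <= 100.0)
    return MediationResult(
        beta_total=total,
        beta_xm=b1,
        beta_my=b2,
        beta_indirect=indirect,
        se_indirect=se_ind,
        ci_indirect=ci,
        beta_direct=total - indirect,
        proportion_mediated_pct=prop,
        proportion_outside_0_100=outside,
        or_total=math.exp(total),
        or_indirect=math.exp(indirect),
    )


def beta_or_convert(beta: float, se: float) -> tuple[float, float, float]:
    """Log-odds effect with SE → odds ratio with 95% CI."""
    if not (se > 0):
        raise ValueError("se must be positive")
    return (
        math.exp(beta),
        math.exp(beta - Z95 * se),
        math.exp(beta + Z95 * se),
    )


def or_ci_to_beta(or_: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Inverse conversion for OR-scale inputs: β = ln(OR), SE from the CI.

    se = (ln(ci_high) − ln(ci_low)) / (2·1.96); useful when a path
    estimate is only available as a printed odds ratio with its CI.
    """
    if not (0 < ci_low <= or_ <= ci_high):
        raise ValueError("CI must bracket the odds ratio and be positive")
    return math.log(or_), (math.log(ci_high) - math.log(ci_low)) / (2 * Z95)
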