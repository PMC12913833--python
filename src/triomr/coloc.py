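"""Approximate-Bayes-factor colocalization of two association signals.

Given per-SNP effect estimates for two traits over the same region, the
method asks whether the two signals are driven by one shared causal
variant.  Each SNP's evidence is summarized by Wakefield's approximate
Bayes factor

    log ABF = 0.5 · [ ln(V/(V+W)) + z²·W/(V+W) ]

with V = se², z = beta/se and W the prior variance of true effects
(defaults: 0.15² for quantitative traits, 0.2² on the log-odds scale for
binary traits).  Assuming at most one causal variant per trait, the
posterior mass is split across five hypotheses:

    H0 no association with either trait
    H1 / H2 association with trait 1 / trait 2 only
    H3 both traits, two distinct causal variants
    H4 both traits, one shared causal variant

with per-SNP priors p1, p2 (single-trait causal) and p12 (shared).
All sums are accumulated in log space with max-subtraction; naive
likelihood sums overflow once |z| exceeds roughly 40.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError

#: default prior effect standard deviations
SD_QUANTITATIVE = 0.15
SD_BINARY = 0.2


@dataclass(frozen=True)
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_snp: int
    p1: float
    p2: float
    p12: float

    def __post_init__(self):
        pps = np.array([self.pp_h0, self.pp_h1, self.pp_h2,
                        self.pp_h3, self.pp_h4])
        if (pps < 0).any() or abs(pps.sum() - 1.0) > 1e-9:
            raise ValueError("posteriors must be non-negative and sum to 1")

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def wakefield_abf(
    beta: float | np.ndarray, se: float | np.ndarray, w: float
) -> float | np.ndarray:
    """Log approximate Bayes factor for one association estimate.

    ``w`` is the prior *variance* of the true effect; must be positive,
    as must ``se``.
    """
    se = np.asarray(se, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if w <= 0:
        raise ValueError("prior variance w must be positive")
    v = se**2
    z2 = (beta / se) ** 2
    labf = 0.5 * (np.log(v / (v + w)) + z2 * w / (v + w))
    return float(labf) if labf.ndim == 0 else labf


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    if np.isneginf(m):
        return -np.inf
    return float(m + np.log(np.sum(np.exp(x - m))))


def coloc_abf(
    trait1: "pd.DataFrame",  # noqa: F821 - columns variant_id?, beta, se
    trait2: "pd.DataFrame",
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    w1: float = SD_QUANTITATIVE**2,
    w2: float = SD_BINARY**2,
) -> ColocResult:
    """Five-hypothesis colocalization over a shared variant set.

    ``trait1``/``trait2`` are per-SNP tables with ``beta`` and ``se``
    columns, aligned row-for-row (and checked by ``variant_id`` when the
    column is present on both).  Default prior variances treat trait 1
    as quantitative (eQTL) and trait 2 as binary (GWAS log-odds).
    """
    if len(trait1) != len(trait2):
        raise AlignmentError(
            f"variant lists differ in length: {len(trait1)} vs {len(trait2)}"
        )
    if "variant_id" in trait1.columns and "variant_id" in trait2.columns:
        v1 = trait1["variant_id"].tolist()
        v2 = trait2["variant_id"].tolist()
        if v1 != v2:
            raise AlignmentError("variant lists are not identical in order")
    n = len(trait1)
    if n == 0:
        raise AlignmentError("empty variant set")
    l1 = wakefield_abf(trait1["beta"].to_numpy(), trait1["se"].to_numpy(), w1)
    l2 = wakefield_abf(trait2["beta"].to_numpy(), trait2["se"].to_numpy(), w2)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)

    s1 = _logsumexp(l1)                 # log Σ ABF1
    s2 = _logsumexp(l2)                 # log Σ ABF2
    s12 = _logsumexp(l1 + l2)           # log Σ ABF1·ABF2 (same SNP)
    # H3 sums ABF1_i·ABF2_j over ordered pairs i ≠ j:
    #   (Σ1)(Σ2) − Σ_same, computed stably in log space
    both = s1 + s2
    if both > s12:
        s3 = both + np.log1p(-np.exp(s12 - both))
    else:
        # all cross-mass on the diagonal (single shared SNP): no H3 mass
        s3 = -np.inf
    logs = np.array([
        0.0,                       # H0
        np.log(p1) + s1,           # H1
        np.log(p2) + s2,           # H2
        np.log(p1) + np.log(p2) + s3,   # H3
        np.log(p12) + s12,         # H4
    ])
    denom = _logsumexp(logs)
    pp = np.exp(logs - denom)
    pp = pp / pp.sum()  # remove residual float error so Σ = 1
    return ColocResult(
        pp_h0=float(pp[0]), pp_h1=float(pp[1]), pp_h2=float(pp[2]),
        pp_h3=float(pp[3]), pp_h4=float(pp[4]),
        n_snp=n, p1=p1, p2=p2, p12=p12,
    )
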