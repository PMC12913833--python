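"""Causal-effect estimators on a harmonized instrument set.

All estimators treat the per-SNP ratio beta_out/beta_exp as the unit of
causal information and differ in how they combine ratios under different
pleiotropy assumptions:

* Wald ratio — single instrument, first-order delta standard error.
* IVW — inverse-variance weighted combination, algebraically the
  weighted least-squares slope through the origin with weights
  1/se_out².  Both the fixed-effect and the multiplicative
  random-effects variant (SE inflated by max(1, sqrt(Q/(k−1)))) are
  reported; the headline pick is random-effects when overdispersed.
* MR-Egger — WLS of beta_out on beta_exp *with* an intercept after
  orienting all instruments to beta_exp ≥ 0; a nonzero intercept is the
  signature of directional pleiotropy, the slope remains consistent
  under the InSIDE assumption.
* Weighted median — consistent when instruments carrying ≥ 50% of the
  weight are valid; SE by seeded parametric bootstrap.
* Simple / weighted mode — the most common ratio under kernel
  smoothing (ZEMPA assumption); SE by seeded parametric bootstrap.

P-values use the normal reference except MR-Egger, which uses t with
k − 2 degrees of freedom.  95% CIs are beta ± 1.96·se throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    RankDeficiencyError,
)
from .instruments import InstrumentSet

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class MREstimate:
    """One method's causal-effect estimate."""

    method: str  # wald | ivw_fe | ivw_re | egger | weighted_median |
    #              simple_mode | weighted_mode
    beta: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float
    n_snp: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.se > 0):
            raise ValueError(f"{self.method}: se must be positive")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError(f"{self.method}: CI does not bracket beta")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


@dataclass(frozen=True)
class MRFailure:
    """Recorded per-method failure inside a batch run."""

    method: str
    error: str


def _normal_p(beta: float, se: float) -> float:
    return float(max(2.0 * sps.norm.sf(abs(beta) / se), 1e-300))


def _ci(beta: float, se: float) -> tuple[float, float]:
    return beta - Z95 * se, beta + Z95 * se


def wald_ratio(
    beta_exp: float, se_exp: float, beta_out: float, se_out: float,
    variant_id: str = "",
) -> MREstimate:
    """Single-instrument ratio estimate with first-order delta SE."""
    if beta_exp == 0:
        raise DegenerateInstrumentError(
            f"variant {variant_id!r}: exposure effect is zero"
        )
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    lo, hi = _ci(beta, se)
    return MREstimate(
        method="wald", beta=beta, se=se, pvalue=_normal_p(beta, se),
        ci_low=lo, ci_high=hi, n_snp=1,
        extra={"variant_id": variant_id} if variant_id else {},
    )


def ivw(instr: InstrumentSet) -> tuple[MREstimate, MREstimate]:
    """Fixed- and multiplicative-random-effects IVW estimates.

    beta = Σ(bx·by/se_y²) / Σ(bx²/se_y²); FE se = sqrt(1/Σ(bx²/se_y²));
    RE se = FE se · max(1, sqrt(Q/(k−1))).
    """
    k = instr.n_snp
    if k < 2:
        raise InsufficientInstrumentsError(
            f"IVW needs ≥ 2 instruments, got {k}"
        )
    bx, by, sy = instr.beta_exp, instr.beta_out, instr.se_out
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se_fe = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (by / bx - beta) ** 2))
    scale = max(1.0, np.sqrt(q / (k - 1)))
    se_re = se_fe * scale
    lo_fe, hi_fe = _ci(beta, se_fe)
    lo_re, hi_re = _ci(beta, se_re)
    fe = MREstimate(
        method="ivw_fe", beta=beta, se=se_fe, pvalue=_normal_p(beta, se_fe),
        ci_low=lo_fe, ci_high=hi_fe, n_snp=k, extra={"q_stat": q},
    )
    re = MREstimate(
        method="ivw_re", beta=beta, se=se_re, pvalue=_normal_p(beta, se_re),
        ci_low=lo_re, ci_high=hi_re, n_snp=k,
        extra={"q_stat": q, "re_scale": scale},
    )
    return fe, re


def ivw_headline(instr: InstrumentSet) -> MREstimate:
    """The reported IVW estimate: random-effects when Q/(k−1) > 1."""
    fe, re = ivw(instr)
    return re if re.extra["re_scale"] > 1.0 else fe


def mr_egger(instr: InstrumentSet) -> MREstimate:
    """Weighted Egger regression: slope is the causal estimate.

    Instruments are first oriented so every beta_exp ≥ 0 (beta_out sign
    flipped with it); weights 1/se_out².  Slope and intercept use the
    t reference with k − 2 degrees of freedom.  Coefficient covariance
    carries the estimated residual variance directly (standard WLS
    inference), so the intercept test is exactly t-calibrated when the
    outcome SEs are correct and pleiotropy is absent.
    """
    k = instr.n_snp
    if k < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs ≥ 3 instruments, got {k}"
        )
    sign = np.where(instr.beta_exp < 0, -1.0, 1.0)
    bx = instr.beta_exp * sign
    by = instr.beta_out * sign
    sy = instr.se_out
    if np.ptp(bx) == 0:
        raise RankDeficiencyError(
            "all exposure effects identical after orientation"
        )
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    xtwx = XtW @ X
    coef = np.linalg.solve(xtwx, XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(xtwx) * sigma2
    # an exactly collinear fit has zero residual variance; keep se > 0
    se_int, se_slope = np.maximum(np.sqrt(np.diag(cov)), 1e-15)
    intercept, slope = coef
    p_slope = float(2.0 * sps.t.sf(abs(slope) / se_slope, df=k - 2))
    p_int = float(2.0 * sps.t.sf(abs(intercept) / se_int, df=k - 2))
    lo, hi = _ci(float(slope), float(se_slope))
    return MREstimate(
        method="egger", beta=float(slope), se=float(se_slope),
        pvalue=max(p_slope, 1e-300), ci_low=lo, ci_high=hi, n_snp=k,
        extra={
            "intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_p": max(p_int, 1e-300),
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w)
    p = s - w / 2.0  # standardized cumulative weight at each ratio
    return float(np.interp(0.5, p, r))


def weighted_median(
    instr: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Per-SNP weights are beta_exp²/se_out² (inverse variance of the
    ratio, first order); the estimate linearly interpolates the sorted
    ratios at cumulative weight 0.5.  The bootstrap resamples beta_exp
    and beta_out from their normal sampling distributions.
    """
    k = instr.n_snp
    if k < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs ≥ 3 instruments, got {k}"
        )
    bx, sx = instr.beta_exp, instr.se_exp
    by, sy = instr.beta_out, instr.se_out
    weights = bx**2 / sy**2
    beta = _weighted_median_point(by / bx, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        boots[b] = _weighted_median_point(bys / bxs, bxs**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    se = max(se, 1e-12)
    lo, hi = _ci(beta, se)
    return MREstimate(
        method="weighted_median", beta=beta, se=se,
        pvalue=_normal_p(beta, se), ci_low=lo, ci_high=hi, n_snp=k,
        extra={"n_boot": n_boot, "seed": seed},
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    s = np.std(ratios, ddof=1) if len(ratios) > 1 else 0.0
    mad = sps.median_abs_deviation(ratios, scale="normal")
    spread = min(s, mad) if mad > 0 else s
    return phi * 0.9 * spread * len(ratios) ** (-1 / 5)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    """Argmax of the Gaussian-kernel weighted density on a dense grid."""
    if h <= 0:
        # all ratios identical: the mode is that ratio
        return float(ratios[0])
    pad = 3.0 * h
    grid = np.linspace(ratios.min() - pad, ratios.max() + pad, 512)
    z = (grid[:, None] - ratios[None, :]) / h
    dens = (np.exp(-0.5 * z**2) * weights[None, :]).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimators(
    instr: InstrumentSet, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> tuple[MREstimate, MREstimate]:
    """Simple (unweighted) and weighted mode of the per-SNP ratios.

    Bandwidth is the modified Silverman rule 0.9·min(sd, MAD)·k^(−1/5)
    scaled by ``phi``; weighted density uses inverse-variance weights
    beta_exp²/se_out².  SEs from the same seeded parametric bootstrap as
    the weighted median.  When all ratios coincide the bandwidth is zero
    and that ratio is returned, not an error.
    """
    k = instr.n_snp
    if k < 3:
        raise InsufficientInstrumentsError(
            f"mode estimators need ≥ 3 instruments, got {k}"
        )
    bx, sx = instr.beta_exp, instr.se_exp
    by, sy = instr.beta_out, instr.se_out

    def both(bx_, by_):
        ratios = by_ / bx_
        w_inv = bx_**2 / sy**2
        h = _mode_bandwidth(ratios, phi)
        simple = _kde_mode(ratios, np.ones(k) / k, h)
        weighted = _kde_mode(ratios, w_inv / w_inv.sum(), h)
        return simple, weighted

    b_simple, b_weighted = both(bx, by)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        boots[b] = both(rng.normal(bx, sx), rng.normal(by, sy))
    se_s, se_w = np.maximum(np.std(boots, axis=0, ddof=1), 1e-12)
    out = []
    for method, beta, se in (
        ("simple_mode", b_simple, float(se_s)),
        ("weighted_mode", b_weighted, float(se_w)),
    ):
        lo, hi = _ci(beta, se)
        out.append(
            MREstimate(
                method=method, beta=beta, se=se, pvalue=_normal_p(beta, se),
                ci_low=lo, ci_high=hi, n_snp=k,
                extra={"phi": phi, "n_boot": n_boot, "seed": seed},
            )
        )
    return out[0], out[1]


def estimate_all(
    instr: InstrumentSet, seed: int = 0, n_boot: int = 1000
) -> list[MREstimate | MRFailure]:
    """Run every estimator whose minimum instrument count is met.

    A single-SNP set dispatches to the Wald ratio alone; two SNPs allow
    only IVW; three or more run the full battery.  Per-method errors are
    recorded as :class:`MRFailure` entries, never aborting the batch.
    """
    k = instr.n_snp
    if k < 1:
        raise InsufficientInstrumentsError("empty instrument set")
    results: list[MREstimate | MRFailure] = []
    if k == 1:
        row = instr.table.iloc[0]
        try:
            results.append(
                wald_ratio(
                    row.beta_exp, row.se_exp, row.beta_out, row.se_out,
                    variant_id=row.variant_id,
                )
            )
        except Exception as exc:  # noqa: BLE001 - recorded, not raised
            results.append(MRFailure("wald", str(exc)))
        return results
    try:
        results.extend(ivw(instr))
    except Exception as exc:  # noqa: BLE001
        results.append(MRFailure("ivw", str(exc)))
    if k >= 3:
        try:
            results.append(mr_egger(instr))
        except Exception as exc:  # noqa: BLE001
            results.append(MRFailure("egger", str(exc)))
        try:
            results.append(weighted_median(instr, n_boot=n_boot, seed=seed))
        except Exception as exc:  # noqa: BLE001
            results.append(MRFailure("weighted_median", str(exc)))
        try:
            results.extend(mode_estimators(instr, n_boot=n_boot, seed=seed))
        except Exception as exc:  # noqa: BLE001
            results.append(MRFailure("mode", str(exc)))
    return results
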