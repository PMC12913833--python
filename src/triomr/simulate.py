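"""Synthetic summary statistics with a known mediated causal chain.

The generator emulates the data the pipeline consumes — three traits'
GWAS/QTL summary statistics, an LD matrix and a differential-expression
table — with recorded ground truth, so every stage is testable without
external downloads.

Generative model (summary-statistic level).  Two disjoint instrument
panels are drawn: exposure instruments with per-allele effects γⱼ on a
quantitative exposure (gene expression, SD units) and mediator
instruments with effects δₖ on a quantitative mediator (an immune-cell
trait, SD units).  The structural chain is

    exposure --a--> mediator --b--> outcome (log-odds)
    exposure --c′-> outcome  (direct path)

so true marginal effects are: on the exposure γⱼ (exposure SNPs) and 0
(mediator SNPs); on the mediator a·γⱼ and δₖ; on the binary outcome
(a·b + c′)·γⱼ + αⱼ and b·δₖ, with αⱼ an optional directional-pleiotropy
term drawn N(pleiotropy_mean, pleiotropy_sd²).

Observed effects add normal noise at the analytic standard error
1/sqrt(2·maf·(1−maf)·N), inflated by 1/sqrt(φ(1−φ)) for the binary
outcome with case fraction φ.  This reproduces exactly the sampling
distribution the two-sample MR estimators assume, at desk scale;
individual-level genotype simulation is deliberately out of scope.

Default parameters mirror the studied regime: outcome N = 66,756 with
case fraction 0.1689, total effect a·b + c′ = −0.030 log-odds per
exposure SD, mediated share ≈ 22.6%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import LDMatrix, SumStats, TraitType

_A_DEFAULT = math.log(1.082)       # exposure → mediator, SD per SD
_B_DEFAULT = -0.086                # mediator → outcome, log-odds per SD
_TOTAL_DEFAULT = -0.030            # total exposure → outcome log-odds


@dataclass
class SimConfig:
    """Parameters of the synthetic mediated-chain generative model."""

    n_snp_per_gene: int = 30
    n_exposure: int = 31_684
    n_mediator: int = 3_757
    n_outcome: int = 66_756
    case_fraction: float = 0.1689
    a: float = _A_DEFAULT
    b: float = _B_DEFAULT
    c_prime: float = _TOTAL_DEFAULT - _A_DEFAULT * _B_DEFAULT
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    ld_rho: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.4)
    gamma_range: tuple[float, float] = (0.1, 0.25)
    seed: int = 0

    def __post_init__(self):
        if self.n_snp_per_gene < 1:
            raise ValueError("need at least one SNP per instrument panel")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be ≥ 100")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")
        if not (abs(self.ld_rho) < 1):
            raise ValueError("|ld_rho| must be < 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    true_total: float
    true_indirect: float
    true_direct: float
    true_proportion_pct: float
    gamma: np.ndarray = field(repr=False)  # exposure-instrument effects
    delta: np.ndarray = field(repr=False)  # mediator-instrument effects
    exposure_snps: list[str] = field(default_factory=list)
    mediator_snps: list[str] = field(default_factory=list)


def simulate_ld_block(
    n_snp: int, rho: float, variant_ids: list[str] | None = None
) -> LDMatrix:
    """AR(1) LD block: r(i, j) = rho^|i−j|, positive definite for |rho|<1."""
    if not (abs(rho) < 1):
        raise ValueError(f"|rho| must be < 1, got {rho}")
    idx = np.arange(n_snp)
    r = rho ** np.abs(idx[:, None] - idx[None, :]).astype(float)
    if variant_ids is None:
        variant_ids = [f"rs{i + 1}" for i in range(n_snp)]
    return LDMatrix(variant_ids=variant_ids, r=r)


def _panel_frame(ids, chrom, positions, alleles, maf, beta, se, n):
    z = beta / se
    p = np.clip(2.0 * sps.norm.sf(np.abs(z)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": positions,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pvalue": p,
            "n": float(n),
        }
    )


def simulate_mediation_sumstats(
    cfg: SimConfig,
) -> tuple[SumStats, SumStats, SumStats, LDMatrix, SimTruth]:
    """Draw one dataset (exposure, mediator, outcome stats + LD + truth).

    Exposure instruments sit on chromosome 1, mediator instruments on
    chromosome 2, 50 kb apart within a panel; within-panel LD is AR(1)
    with ``cfg.ld_rho`` and zero between panels.  All randomness flows
    from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snp_per_gene

    exp_ids = [f"rsE{i + 1}" for i in range(k)]
    med_ids = [f"rsM{i + 1}" for i in range(k)]
    ids = exp_ids + med_ids
    chrom = ["1"] * k + ["2"] * k
    positions = np.concatenate(
        [1_000_000 + 50_000 * np.arange(k)] * 2
    ).astype(np.int64)
    # non-palindromic allele pairs only, so harmonization keeps all SNPs
    pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
    alleles = [pairs[int(x)] for x in rng.integers(0, len(pairs), 2 * k)]

    maf = rng.uniform(*cfg.maf_range, size=2 * k)
    gamma = rng.uniform(*cfg.gamma_range, size=k)
    delta = rng.uniform(*cfg.gamma_range, size=k)
    alpha = (
        rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=k)
        if (cfg.pleiotropy_mean != 0 or cfg.pleiotropy_sd > 0)
        else np.zeros(k)
    )

    var_g = 2.0 * maf * (1.0 - maf)
    cf = cfg.case_fraction
    se_exp = 1.0 / np.sqrt(var_g * cfg.n_exposure)
    se_med = 1.0 / np.sqrt(var_g * cfg.n_mediator)
    se_out = 1.0 / np.sqrt(var_g * cfg.n_outcome * cf * (1.0 - cf))

    total = cfg.a * cfg.b + cfg.c_prime
    true_exp = np.concatenate([gamma, np.zeros(k)])
    true_med = np.concatenate([cfg.a * gamma, delta])
    true_out = np.concatenate([total * gamma + alpha, cfg.b * delta])

    beta_exp = rng.normal(true_exp, se_exp)
    beta_med = rng.normal(true_med, se_med)
    beta_out = rng.normal(true_out, se_out)

    exposure = SumStats(
        trait_id="sim_expression",
        trait_type=TraitType.EQTL,
        df=_panel_frame(ids, chrom, positions, alleles, maf,
                        beta_exp, se_exp, cfg.n_exposure),
    )
    mediator = SumStats(
        trait_id="sim_immune_trait",
        trait_type=TraitType.IMMUNE_CELL,
        df=_panel_frame(ids, chrom, positions, alleles, maf,
                        beta_med, se_med, cfg.n_mediator),
    )
    outcome = SumStats(
        trait_id="sim_disease",
        trait_type=TraitType.OUTCOME,
        df=_panel_frame(ids, chrom, positions, alleles, maf,
                        beta_out, se_out, cfg.n_outcome),
        is_binary=True,
        case_fraction=cf,
    )

    r = np.eye(2 * k)
    block = simulate_ld_block(k, cfg.ld_rho).r
    r[:k, :k] = block
    r[k:, k:] = block
    ld = LDMatrix(variant_ids=ids, r=r)

    indirect = cfg.a * cfg.b
    truth = SimTruth(
        true_total=total,
        true_indirect=indirect,
        true_direct=cfg.c_prime,
        true_proportion_pct=(
            100.0 * indirect / total if total != 0 else float("nan")
        ),
        gamma=gamma,
        delta=delta,
        exposure_snps=exp_ids,
        mediator_snps=med_ids,
    )
    return exposure, mediator, outcome, ld, truth


def simulate_de_table(
    n_gene: int,
    frac_signal: float,
    effect_sd: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Differential-expression table with known signal labels.

    Signal genes get log2FC centered at ±``effect_sd`` (random sign)
    and very small p-values; null genes get log2FC near zero and
    uniform p-values.  q-values come from one Benjamini-Hochberg pass
    over the combined p-values.  Returns (table, is_signal labels).
    """
    if not (0.0 <= frac_signal <= 1.0):
        raise ValueError("frac_signal must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sig = int(round(frac_signal * n_gene))
    is_signal = np.zeros(n_gene, dtype=bool)
    is_signal[rng.permutation(n_gene)[:n_sig]] = True

    log2fc = rng.normal(0.0, 0.2, size=n_gene)
    sign = rng.choice([-1.0, 1.0], size=n_gene)
    log2fc[is_signal] = sign[is_signal] * rng.normal(
        effect_sd, 0.3 * effect_sd, size=n_sig
    )
    p = rng.uniform(0.0, 1.0, size=n_gene)
    p = np.clip(p, 1e-300, 1.0)
    p[is_signal] = 10.0 ** rng.uniform(-80.0, -5.0, size=n_sig)
    from .prioritize import adjust_pvalues

    q = adjust_pvalues(p, "bh") if n_gene else np.array([])
    table = pd.DataFrame(
        {
            "gene_id": [f"GENE{i + 1}" for i in range(n_gene)],
            "log2fc": log2fc,
            "qvalue": q,
        }
    )
    return table, is_signal
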