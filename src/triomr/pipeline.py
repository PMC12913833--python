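"""End-to-end orchestration: simulate/ingest → QC → MR → diagnostics →
mediation → colocalization → power → prioritization.

``run_pipeline`` executes the stages in order, writes one artifact per
stage under the output directory, and assembles a single machine-
readable report.  Reruns with the same config and seed reproduce the
report bit-for-bit; all floats are serialized at 10 significant digits
to make that checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coloc as coloc_mod
from .errors import NoInstrumentsError, PipelineStageError
from .estimators import (
    MREstimate,
    MRFailure,
    estimate_all,
    ivw_headline,
    wald_ratio,
)
from .instruments import (
    compute_f_stats,
    harmonize,
    ld_clump,
    select_by_pvalue,
)
from .mediation import three_step_mediation
from .power import mr_power_binary
from .prioritize import filter_de_table, intersect_and_classify
from .sensitivity import sensitivity_report
from .simulate import SimConfig, simulate_de_table, simulate_mediation_sumstats
from .sumstats import (
    DERecord,
    SumStats,
    read_de_table,
    read_ld_matrix,
    read_sumstats,
    write_ld_matrix,
    write_sumstats,
)


@dataclass
class Thresholds:
    p: float = 5e-8
    window_kb: float = 10_000.0
    r2: float = 0.001
    f_min: float = 10.0
    lfc_min: float = 1.0
    q_max: float = 0.05
    alpha: float = 0.05

    def __post_init__(self):
        if not (0 < self.p <= 1):
            raise ValueError("p threshold outside (0, 1]")
        if not (0 < self.r2 <= 1):
            raise ValueError("r2 threshold outside (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha outside (0, 1)")
        if not (0 < self.q_max <= 1):
            raise ValueError("q_max outside (0, 1]")
        if self.window_kb <= 0 or self.f_min < 0 or self.lfc_min < 0:
            raise ValueError("window_kb must be positive; f_min, lfc_min ≥ 0")


@dataclass
class PipelineConfig:
    """Inputs (paths or simulation settings), thresholds and seed."""

    seed: int = 0
    out_dir: str = "triomr_out"
    sim: dict | None = None          # SimConfig overrides; None = file mode
    n_de_genes: int = 500
    de_frac_signal: float = 0.1
    inputs: dict = field(default_factory=dict)  # file-mode paths
    thresholds: Thresholds = field(default_factory=Thresholds)
    priors: dict = field(
        default_factory=lambda: {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5}
    )
    exclusion_list: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sigfig(x: float, digits: int = 10) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{digits}g}")


def _round_floats(obj):
    if isinstance(obj, float):
        return _sigfig(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def _estimate_to_dict(est: MREstimate | MRFailure) -> dict:
    if isinstance(est, MRFailure):
        return {"method": est.method, "error": est.error}
    d = {
        "method": est.method,
        "n_snp": est.n_snp,
        "beta": est.beta,
        "se": est.se,
        "pvalue": est.pvalue,
        "or": est.odds_ratio,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
    }
    d.update({k: v for k, v in est.extra.items() if k != "variant_id"})
    return d


def _select_instruments(stats: SumStats, ld, thr: Thresholds):
    """p-value screen → LD clumping → F filter; returns ids + provenance."""
    n0 = stats.n_variants
    candidates = select_by_pvalue(stats, thr.p)
    cand_df = stats.subset(candidates)[["variant_id", "chrom", "pos",
                                        "pvalue"]]
    clumped = ld_clump(
        cand_df, ld, window_kb=thr.window_kb, r2_max=thr.r2,
        assume_independent=ld is None,
    )
    freport = compute_f_stats(stats, clumped, thr.f_min)
    prov = {
        "below_p_threshold": n0 - len(candidates),
        "clumped": len(candidates) - len(clumped),
        "low_f": len(clumped) - len(freport.retained),
    }
    return freport.retained, freport, prov


def _headline(instr) -> MREstimate:
    if instr.n_snp == 1:
        row = instr.table.iloc[0]
        return wald_ratio(row.beta_exp, row.se_exp, row.beta_out,
                          row.se_out, variant_id=row.variant_id)
    return ivw_headline(instr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the report dict (also written to
    ``<out_dir>/report.json``).

    A "no instruments" condition on a path downgrades that path to a
    recorded skip; any other stage error halts with a stage-named
    message.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    report["config_hash"] = hashlib.sha256(
        json.dumps(report["config"], sort_keys=True, default=str).encode()
    ).hexdigest()
    thr = config.thresholds

    # ingest or simulate
    try:
        if config.sim is not None:
            sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
            exposure, mediator, outcome, ld, truth = (
                simulate_mediation_sumstats(sim_cfg)
            )
            de_table, _ = simulate_de_table(
                config.n_de_genes, config.de_frac_signal,
                seed=config.seed + 1,
            )
            de_records = [
                DERecord(r.gene_id, float(r.log2fc), float(r.qvalue))
                for r in de_table.itertuples(index=False)
            ]
            for st, name in (
                (exposure, "exposure"), (mediator, "mediator"),
                (outcome, "outcome"),
            ):
                write_sumstats(st, out_dir / f"{name}.tsv")
            write_ld_matrix(ld, out_dir / "ld.tsv")
            report["stages"]["simulate"] = {
                "true_total": truth.true_total,
                "true_indirect": truth.true_indirect,
                "true_direct": truth.true_direct,
                "true_proportion_pct": truth.true_proportion_pct,
            }
        else:
            paths = config.inputs
            exposure = read_sumstats(
                paths["exposure"], trait_id="exposure", trait_type="eqtl"
            )
            outcome = read_sumstats(
                paths["outcome"], trait_id="outcome", trait_type="outcome",
                is_binary=True,
                case_fraction=paths.get("case_fraction", 0.5),
            )
            mediator = (
                read_sumstats(paths["mediator"], trait_id="mediator",
                              trait_type="immune_cell")
                if "mediator" in paths else None
            )
            ld = read_ld_matrix(paths["ld"]) if "ld" in paths else None
            de_records = (
                read_de_table(paths["de"]) if "de" in paths else []
            )
    except Exception as exc:
        raise PipelineStageError("ingest", exc) from exc

    # instrument selection + harmonization, exposure → outcome
    try:
        ids, freport, prov = _select_instruments(exposure, ld, thr)
        instr = harmonize(exposure, outcome, ids,
                          exclusion_list=config.exclusion_list,
                          provenance=prov)
        instr.to_tsv(out_dir / "instruments.tsv")
        report["stages"]["select"] = {
            "n_instruments": instr.n_snp,
            "provenance": instr.provenance,
            "mean_f": freport.mean_f,
            "sum_r2": freport.sum_r2,
        }
    except NoInstrumentsError as exc:
        report["stages"]["select"] = {"skipped": str(exc)}
        _write_report(report, out_dir)
        return report
    except Exception as exc:
        raise PipelineStageError("select", exc) from exc

    # MR estimates
    try:
        estimates = estimate_all(instr, seed=config.seed)
        report["stages"]["mr"] = [_estimate_to_dict(e) for e in estimates]
    except Exception as exc:
        raise PipelineStageError("mr", exc) from exc

    # sensitivity diagnostics
    try:
        if instr.n_snp >= 2:
            sens = sensitivity_report(instr)
            report["stages"]["sensitivity"] = sens.to_dict()
        else:
            report["stages"]["sensitivity"] = {
                "skipped": "single instrument"
            }
    except Exception as exc:
        raise PipelineStageError("sensitivity", exc) from exc

    # three-step mediation
    try:
        if mediator is not None:
            est_total = _headline(instr)
            instr_xm = harmonize(exposure, mediator, instr.variant_ids)
            med_ids, _, med_prov = _select_instruments(mediator, ld, thr)
            instr_my = harmonize(mediator, outcome, med_ids,
                                 exclusion_list=config.exclusion_list,
                                 provenance=med_prov)
            med = three_step_mediation(
                est_total, _headline(instr_xm), _headline(instr_my)
            )
            report["stages"]["mediation"] = med.to_dict()
        else:
            report["stages"]["mediation"] = {"skipped": "no mediator trait"}
    except NoInstrumentsError as exc:
        report["stages"]["mediation"] = {"skipped": str(exc)}
    except Exception as exc:
        raise PipelineStageError("mediation", exc) from exc

    # colocalization of exposure vs outcome over the shared variant set
    try:
        shared = [
            v for v in exposure.df["variant_id"]
            if v in set(outcome.df["variant_id"])
        ]
        t1 = exposure.subset(shared)[["variant_id", "beta", "se"]]
        t2 = outcome.subset(shared)[["variant_id", "beta", "se"]]
        cres = coloc_mod.coloc_abf(t1, t2, **config.priors)
        report["stages"]["coloc"] = cres.to_dict()
    except Exception as exc:
        raise PipelineStageError("coloc", exc) from exc

    # post-hoc power at the observed effect and instrument strength
    try:
        if outcome.is_binary and freport.sum_r2 and 0 < freport.sum_r2 < 1:
            headline = _headline(instr)
            pres = mr_power_binary(
                n=float(outcome.df["n"].iloc[0]),
                case_fraction=outcome.case_fraction,
                r2=freport.sum_r2,
                or_per_sd=headline.odds_ratio,
                alpha=thr.alpha,
            )
            report["stages"]["power"] = pres.to_dict()
        else:
            report["stages"]["power"] = {
                "skipped": "needs binary outcome and instrument R²"
            }
    except Exception as exc:
        raise PipelineStageError("power", exc) from exc

    # DE filter + evidence classification
    try:
        if de_records:
            de_hits = filter_de_table(de_records, thr.lfc_min, thr.q_max)
            report["stages"]["de_filter"] = {
                "n_input": len(de_records),
                "n_retained": len(de_hits),
                "n_up": int((de_hits["direction"] == "up").sum()),
                "n_down": int((de_hits["direction"] == "down").sum()),
            }
            headline = _headline(instr)
            eqtl_hits = pd.DataFrame(
                [{"gene_id": exposure.trait_id, "beta": headline.beta,
                  "pvalue": headline.pvalue}]
            )
            pqtl_hits = pd.DataFrame(columns=["gene_id", "beta", "pvalue"])
            evidence, venn = intersect_and_classify(
                eqtl_hits, pqtl_hits,
                de_hits[["gene_id", "log2fc", "qvalue"]],
            )
            evidence.to_csv(out_dir / "gene_evidence.tsv", sep="\t",
                            index=False)
            report["stages"]["prioritize"] = {"venn": venn}
        else:
            report["stages"]["de_filter"] = {"skipped": "no DE table"}
    except Exception as exc:
        raise PipelineStageError("prioritize", exc) from exc

    _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    payload = _round_floats(report)
    (out_dir / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n"
    )
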