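"""End-to-end orchestration: instruments -> MR suite -> FDR -> coloc -> replication.

For every cytokine x outcome x instrument-definition combination the pipeline
selects cis instruments, harmonizes them against the outcome GWAS, runs the
primary IVW (Wald ratio when a single SNP is available) with strength and
power diagnostics, runs every applicable sensitivity estimator (Egger,
weighted median and ConMix need >= 3 SNPs, MR-PRESSO >= 4; skips are logged
with their reason), applies Benjamini-Hochberg FDR per definition, and runs
Bayesian colocalization plus trans-exclusion and LD-adjusted re-estimation
for the FDR-significant pairs. Per-pair failures are recorded, never fatal.

All randomness derives from the single config seed through per-task seed
derivation, so re-running any subset of the pipeline is stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coloc as coloc_mod
from .errors import CytomrError
from .estimators import (
    ConMixConfig,
    MRResult,
    PressoConfig,
    contamination_mixture,
    egger,
    ivw,
    ivw_correlated,
    mr_presso,
    weighted_median,
)
from .instruments import (
    PowerConfig,
    power_binary_outcome,
    read_gene_regions,
    select_eqtl_instruments,
    select_pqtl_instruments,
    trans_exclusion_filter,
)
from .multiplicity import bh_qvalues, flag_significant
from .simulate import derive_seed
from .sumstats import harmonize_pair, read_ld_matrix, read_sumstats

logger = logging.getLogger(__name__)

PRIMARY_METHODS = ("ivw_re", "wald_ratio")


@dataclass
class RunConfig:
    """All paths and thresholds of one pipeline run; round-trips through YAML."""

    regions: str = ""
    exposure_dir: str = ""
    outcome_dir: str = ""
    ld_dir: str | None = None
    expression_dir: str | None = None
    trans_table: str | None = None
    replication_outcome: str | None = None
    flank: int = 500_000
    maf_min: float = 0.05
    p_pqtl: float = 1e-4
    p_expr: float = 1e-4
    p_cyto: float = 0.05
    clump_r2: float = 0.1
    q_max: float = 0.10
    p_trans: float = 5e-8
    coloc_window: int = 25_000
    pp_min: float = 0.8
    power_or: float = 1.2
    alpha: float = 0.05
    case_fraction: float = 0.5
    palindrome_eaf_limit: float = 0.42
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything one run produced: long results table, coloc table, logs."""

    results: pd.DataFrame
    coloc: pd.DataFrame
    matrix: pd.DataFrame
    instruments: dict = field(default_factory=dict)  # (cytokine, definition) -> InstrumentSet
    harmonized: dict = field(default_factory=dict)  # (cytokine, outcome, definition) -> dataset
    run_log: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _result_row(cytokine, outcome, definition, res: MRResult | None, status="ok", notes="",
                **extra) -> dict:
    row = {
        "cytokine": cytokine,
        "outcome": outcome,
        "definition": definition,
        "method": res.method if res else "",
        "n_snps": res.n_snps if res else 0,
        "theta": res.theta if res else float("nan"),
        "se": res.se if res else float("nan"),
        "or": res.odds_ratio if res else float("nan"),
        "or_l95": res.or_ci[0] if res else float("nan"),
        "or_u95": res.or_ci[1] if res else float("nan"),
        "p": res.pvalue if res else float("nan"),
        "q_stat": res.q_stat if res else None,
        "q_df": res.q_df if res else None,
        "q_p": res.q_pvalue if res else None,
        "egger_intercept": res.egger_intercept if res else None,
        "egger_intercept_p": res.egger_intercept_p if res else None,
        "q": float("nan"),
        "significant": False,
        "status": status,
        "notes": notes or (res.notes if res else ""),
    }
    row.update(extra)
    return row


def _sensitivity_rows(cytokine, outcome, definition, hd, cfg) -> list[dict]:
    rows = []
    j = hd.n_snps
    base = derive_seed(cfg.seed, cytokine, outcome, definition)
    if j >= 3:
        for name, fn in (
            ("egger", lambda: egger(hd)),
            ("weighted_median",
             lambda: weighted_median(hd, n_boot=cfg.n_boot,
                                     seed=derive_seed(base, "wm"))),
            ("conmix", lambda: contamination_mixture(hd, ConMixConfig())),
        ):
            try:
                rows.append(_result_row(cytokine, outcome, definition, fn()))
            except CytomrError as exc:
                rows.append(_result_row(cytokine, outcome, definition, None,
                                        status="failed", notes=f"{name}: {exc}"))
    else:
        for name in ("egger", "weighted_median", "conmix"):
            rows.append(_result_row(cytokine, outcome, definition, None,
                                    status="skipped", notes=f"{name}: needs >= 3 SNPs, have {j}"))
    if j >= 4:
        try:
            global_p, flags, corrected = mr_presso(
                hd, PressoConfig(n_sim=cfg.presso_n_sim, seed=derive_seed(base, "presso"))
            )
            rows.append(_result_row(
                cytokine, outcome, definition, corrected,
                notes=f"global p {global_p:.4g}; {corrected.notes}",
                presso_global_p=global_p,
            ))
        except CytomrError as exc:
            rows.append(_result_row(cytokine, outcome, definition, None,
                                    status="failed", notes=f"presso: {exc}"))
    else:
        rows.append(_result_row(cytokine, outcome, definition, None, status="skipped",
                                notes=f"presso: needs >= 4 SNPs, have {j}"))
    return rows


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full analysis grid defined by ``cfg``; see the module docstring."""
    regions = read_gene_regions(cfg.regions)
    exposure_dir = Path(cfg.exposure_dir)
    outcome_dir = Path(cfg.outcome_dir)
    run_log: list[str] = []

    outcome_files = sorted(outcome_dir.glob("*.tsv"))
    outcomes = {p.stem: read_sumstats(p, trait_type="binary", trait_id=p.stem)
                for p in outcome_files}

    trans = pd.read_csv(cfg.trans_table, sep="\t") if cfg.trans_table else None

    definitions = ["cis_pQTL"] + (["cis_eQTL"] if cfg.expression_dir else [])
    instruments: dict = {}
    exposures: dict = {}
    lds: dict = {}
    for region in regions:
        cyt = region.cytokine_id
        epath = exposure_dir / f"{cyt}.tsv"
        if not epath.exists():
            run_log.append(f"{cyt}: no exposure summary statistics; skipped")
            continue
        exposures[cyt] = read_sumstats(epath, trait_type="quantitative", trait_id=cyt)
        ld = None
        if cfg.ld_dir:
            lpath = Path(cfg.ld_dir) / f"{cyt}.tsv"
            if lpath.exists():
                ld = read_ld_matrix(lpath)
        lds[cyt] = ld
        instruments[(cyt, "cis_pQTL")] = select_pqtl_instruments(
            exposures[cyt], region, ld, p_max=cfg.p_pqtl, maf_min=cfg.maf_min,
            r2_max=cfg.clump_r2, flank=cfg.flank,
        )
        if cfg.expression_dir:
            xpath = Path(cfg.expression_dir) / f"{cyt}.tsv"
            if xpath.exists():
                expr = read_sumstats(xpath, trait_type="quantitative",
                                     trait_id=f"{cyt}_expression")
                instruments[(cyt, "cis_eQTL")] = select_eqtl_instruments(
                    expr, exposures[cyt], region, ld, p_expr=cfg.p_expr,
                    p_cyto=cfg.p_cyto, maf_min=cfg.maf_min, r2_max=cfg.clump_r2,
                    flank=cfg.flank,
                )
            else:
                run_log.append(f"{cyt}: no expression summary statistics; cis_eQTL skipped")

    rows: list[dict] = []
    harmonized: dict = {}
    region_by_cyt = {r.cytokine_id: r for r in regions}
    for definition in definitions:
        for region in regions:
            cyt = region.cytokine_id
            inst = instruments.get((cyt, definition))
            if inst is None:
                continue
            if trans is not None:
                other = trans[trans.get("other_trait_id", pd.Series(dtype=str)) != cyt] \
                    if "other_trait_id" in trans.columns else trans
                inst = trans_exclusion_filter(inst, other, cfg.p_trans)
                instruments[(cyt, definition)] = inst
            for out_name, out_assocs in outcomes.items():
                if inst.n_variants == 0:
                    rows.append(_result_row(cyt, out_name, definition, None,
                                            status="no_instrument"))
                    continue
                try:
                    hd = harmonize_pair(inst.variants, out_assocs,
                                        palindrome_eaf_limit=cfg.palindrome_eaf_limit,
                                        ld=lds.get(cyt))
                except CytomrError as exc:
                    rows.append(_result_row(cyt, out_name, definition, None,
                                            status="failed", notes=str(exc)))
                    run_log.append(f"{cyt} x {out_name} [{definition}]: {exc}")
                    continue
                if hd.n_snps == 0:
                    rows.append(_result_row(cyt, out_name, definition, None,
                                            status="no_instrument",
                                            notes="all instruments lost in harmonization"))
                    continue
                harmonized[(cyt, out_name, definition)] = hd
                n_out = next((a.n for a in out_assocs if a.n), None)
                phi = cfg.case_fraction
                power = None
                if n_out:
                    power = power_binary_outcome(
                        PowerConfig(n=n_out, case_fraction=phi, or_alt=cfg.power_or,
                                    alpha=cfg.alpha),
                        min(inst.total_r2, 0.999),
                    )
                try:
                    primary = ivw(hd)
                except CytomrError as exc:
                    rows.append(_result_row(cyt, out_name, definition, None,
                                            status="failed", notes=str(exc)))
                    continue
                rows.append(_result_row(
                    cyt, out_name, definition, primary,
                    total_r2=inst.total_r2, mean_F=inst.mean_F, power=power,
                ))
                rows.extend(_sensitivity_rows(cyt, out_name, definition, hd, cfg))

    for definition in definitions:
        idx = [i for i, row in enumerate(rows)
               if row["method"] in PRIMARY_METHODS and row["definition"] == definition]
        if not idx:
            continue
        p = [min(max(rows[i]["p"], 1e-300), 1.0) for i in idx]
        q = bh_qvalues(p)
        sig = flag_significant(q, cfg.q_max)
        for i, qi, si in zip(idx, q, sig):
            rows[i]["q"] = qi
            rows[i]["significant"] = si

    coloc_rows = []
    ccfg = coloc_mod.ColocConfig(window_bp=cfg.coloc_window)
    for row in [r for r in rows if r["significant"] and r["method"] in PRIMARY_METHODS]:
        cyt, out_name, definition = row["cytokine"], row["outcome"], row["definition"]
        try:
            res = coloc_mod.coloc_posteriors(exposures[cyt], outcomes[out_name], ccfg)
            region = region_by_cyt[cyt]
            lead = next(a for a in exposures[cyt] if a.variant_id == res.lead_variant_id)
            coloc_rows.append({
                "cytokine": cyt,
                "outcome": out_name,
                "definition": definition,
                "n_snps": res.n_snps,
                "pp_none": res.pp[0], "pp_t1": res.pp[1], "pp_t2": res.pp[2],
                "pp_distinct": res.pp[3], "pp_shared": res.pp[4],
                "lead_variant": res.lead_variant_id,
                "lead_in_gene": bool(region.start <= lead.position <= region.end),
                "shared_call": coloc_mod.call_shared(res, cfg.pp_min),
            })
        except CytomrError as exc:
            run_log.append(f"coloc {cyt} x {out_name} [{definition}]: {exc}")
        # LD-adjusted re-estimation for the significant pair
        hd = harmonized.get((cyt, out_name, definition))
        if hd is not None and hd.ld is not None and hd.n_snps > 1:
            try:
                rows.append(_result_row(
                    cyt, out_name, definition, ivw_correlated(hd),
                    notes="LD-adjusted re-estimation of FDR-significant pair"))
            except CytomrError as exc:
                run_log.append(f"ivw_ld {cyt} x {out_name} [{definition}]: {exc}")

    results = pd.DataFrame(rows)

    coloc_df = pd.DataFrame(coloc_rows, columns=[
        "cytokine", "outcome", "definition", "n_snps", "pp_none", "pp_t1", "pp_t2",
        "pp_distinct", "pp_shared", "lead_variant", "lead_in_gene", "shared_call"])
    matrix = summarize_matrix(results)
    manifest = {"seed": cfg.seed, "config_hash": cfg.config_hash(), "config": asdict(cfg),
                "n_results": int(len(results)), "n_coloc": int(len(coloc_df))}
    return PipelineResult(results=results, coloc=coloc_df, matrix=matrix,
                          instruments=instruments, harmonized=harmonized,
                          run_log=run_log, manifest=manifest)


def summarize_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Long-format cytokine x outcome grid of primary estimates with flag layers.

    One row per pair and definition: the IVW/Wald beta, a nominal flag
    (p < 0.05), an FDR flag (q <= threshold) and an explicit ``no_instrument``
    state for untestable pairs. Consumable by any plotting layer.
    """
    cols = ["cytokine", "outcome", "definition", "theta", "nominal", "fdr", "state"]
    if results.empty:
        return pd.DataFrame(columns=cols)
    keep = results[results["method"].isin(PRIMARY_METHODS) |
                   (results["status"] == "no_instrument")]
    rows = []
    for r in keep.itertuples(index=False):
        ok = r.status == "ok"
        rows.append({
            "cytokine": r.cytokine,
            "outcome": r.outcome,
            "definition": r.definition,
            "theta": r.theta if ok else float("nan"),
            "nominal": bool(ok and r.p < 0.05),
            "fdr": bool(ok and r.significant),
            "state": r.status,
        })
    return pd.DataFrame(rows, columns=cols)


def replication_check(
    result: PipelineResult,
    replication_outcome,
    palindrome_eaf_limit: float = 0.42,
) -> pd.DataFrame:
    """Re-estimate FDR-significant pairs against independent outcome data.

    ``replication_outcome`` is a list of outcome VariantAssociations (or a
    path readable by read_sumstats). A pair replicates iff the re-estimated
    effect has the same direction as the discovery estimate and two-sided
    p < 0.05; pairs whose instruments are absent from the replication data are
    marked not-evaluable.
    """
    if not isinstance(replication_outcome, list):
        replication_outcome = read_sumstats(replication_outcome, trait_type="binary",
                                            trait_id="replication")
    res = result.results
    sig = res[res["significant"] & res["method"].isin(PRIMARY_METHODS)]
    rows = []
    for r in sig.itertuples(index=False):
        inst = result.instruments[(r.cytokine, r.definition)]
        row = {"cytokine": r.cytokine, "outcome": r.outcome, "definition": r.definition,
               "discovery_theta": r.theta, "replication_theta": float("nan"),
               "replication_p": float("nan"), "evaluable": False, "replicated": False}
        try:
            hd = harmonize_pair(inst.variants, replication_outcome,
                                palindrome_eaf_limit=palindrome_eaf_limit)
            rep = ivw(hd)
        except CytomrError:
            rows.append(row)
            continue
        row.update(evaluable=True, replication_theta=rep.theta, replication_p=rep.pvalue,
                   replicated=bool((rep.theta * r.theta > 0) and rep.pvalue < 0.05))
        rows.append(row)
    return pd.DataFrame(rows, columns=["cytokine", "outcome", "definition",
                                       "discovery_theta", "replication_theta",
                                       "replication_p", "evaluable", "replicated"])


def write_outputs(result: PipelineResult, out_dir) -> dict[str, Path]:
    """Write results/coloc/matrix TSVs and the JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out / "mr_results.tsv",
        "coloc": out / "coloc_results.tsv",
        "matrix": out / "summary_matrix.tsv",
        "manifest": out / "run_manifest.json",
    }
    result.results.to_csv(paths["results"], sep="\t", index=False)
    result.coloc.to_csv(paths["coloc"], sep="\t", index=False)
    result.matrix.to_csv(paths["matrix"], sep="\t", index=False)
    paths["manifest"].write_text(json.dumps(result.manifest, indent=2, default=str))
    if result.run_log:
        (out / "run_log.txt").write_text("\n".join(result.run_log) + "\n")
    return paths
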