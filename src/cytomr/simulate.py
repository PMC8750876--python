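"""Synthetic two-sample GWAS summary statistics with known ground truth.

Emulates the structure of the study's inputs — per-region SNP-cytokine betas
on an SD scale and SNP-cancer log-OR betas with LD — under configurable causal
effects and pleiotropy, so every pipeline stage is testable without any
download.

Model
-----
For a region of m variants with AR(1) LD correlation R (r_jk = rho^|j-k|),
``n_causal_exposure`` variants carry standardized causal exposure effects of
fixed explained variance each (sign random). Marginal standardized effects
are the LD propagation R @ b; per-allele betas divide by sqrt(2*eaf*(1-eaf))
with EAFs uniform on [0.05, 0.95]. Exposure sampling noise is multivariate
normal with correlation R and per-variant SE 1/sqrt(2*eaf*(1-eaf)*n_exposure).
Marginal outcome log-ORs are theta times the noise-free exposure effect plus
a per-variant pleiotropy term (none / balanced zero-mean normal / directional
half-normal) plus independent case-control noise with SE
1/sqrt(2*eaf*(1-eaf)*n_outcome*phi*(1-phi)). The two samples are independent.

Defaults mirror the study conditions: exposure GWAS n = 13,365 (the Finnish
cytokine GWAS), outcome n = 85,716 with case fraction 0.3415 (the lung cancer
GWAS, 29,266 cases / 56,450 controls), 1% explained variance per causal
variant (the per-cytokine summed r2 of the instrument catalog is a few
percent over a handful of variants).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .instruments import GeneRegion
from .sumstats import LDMatrix, VariantAssociation, normal_p_from_z

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def derive_seed(base_seed: int, *keys) -> int:
    """Stable per-task seed below 2^31 derived from a base seed and string keys."""
    h = hashlib.sha256(":".join([str(base_seed), *map(str, keys)]).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth recorded alongside every simulated dataset."""

    theta: float = 0.0  # true causal log-OR per SD of the exposure
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    n_causal_exposure: int = 3
    ld_rho: float = 0.8
    n_exposure: int = 13_365
    n_outcome: int = 85_716
    case_fraction: float = 0.3415
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.ld_rho < 1.0):
            raise DomainError("ld_rho must lie in [0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise DomainError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if not (0.0 < self.case_fraction < 1.0):
            raise DomainError("case_fraction must lie in (0,1)")


def simulate_ld(m: int, rho: float) -> LDMatrix:
    """AR(1) LD: r_jk = rho^|j-k|; positive definite for 0 <= rho < 1."""
    if m < 1:
        raise DomainError("m must be >= 1")
    if not (0.0 <= rho < 1.0):
        raise DomainError("rho must lie in [0, 1)")
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    ids = [f"rs{j + 1:05d}" for j in idx]
    return LDMatrix(ids, r)


def _assoc_list(gen, beta, se, n, trait_id, trait_type, n_cases=None):
    out = []
    for j, vid in enumerate(gen["ids"]):
        out.append(
            VariantAssociation(
                variant_id=vid,
                chromosome=gen["chrom"],
                position=int(gen["positions"][j]),
                effect_allele=gen["eas"][j],
                other_allele=gen["oas"][j],
                beta=float(beta[j]),
                se=float(se[j]),
                pvalue=normal_p_from_z(beta[j] / se[j]),
                eaf=float(gen["eaf"][j]),
                n=float(n),
                n_cases=n_cases,
                trait_id=trait_id,
                trait_type=trait_type,
            )
        )
    return out


def _simulate_region_genetics(rng, truth: SimulationTruth, region: GeneRegion,
                              m: int, causal_r2: float) -> dict:
    """Region layout, LD, true effects and the exposure-GWAS realization."""
    r = simulate_ld(m, truth.ld_rho).r
    ids = [f"{region.cytokine_id}_snp{j + 1:04d}" for j in range(m)]
    span = region.end - region.start + 1
    if span >= m:
        positions = np.sort(rng.choice(np.arange(region.start, region.end + 1),
                                       size=m, replace=False))
    else:
        positions = np.sort(rng.integers(region.start, region.end + 1, size=m))
    eaf = rng.uniform(0.05, 0.95, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    scale = np.sqrt(2.0 * eaf * (1.0 - eaf))

    n_causal = min(truth.n_causal_exposure, m)
    b_std = np.zeros(m)
    if n_causal > 0:
        causal = rng.choice(m, size=n_causal, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_causal)
        b_std[causal] = signs * np.sqrt(causal_r2)
    beta_true = (r @ b_std) / scale
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))

    se_x = 1.0 / (scale * np.sqrt(truth.n_exposure))
    beta_x = beta_true + se_x * (chol @ rng.standard_normal(m))
    return {
        "ids": ids,
        "chrom": region.chromosome,
        "positions": positions,
        "eaf": eaf,
        "eas": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "oas": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "scale": scale,
        "beta_true": beta_true,
        "chol": chol,
        "se_x": se_x,
        "beta_x": beta_x,
        "ld": LDMatrix(ids, r),
    }


def _simulate_outcome(rng, truth: SimulationTruth, gen: dict, outcome_id: str):
    m = len(gen["ids"])
    if truth.pleiotropy_mode == "none" or truth.pleiotropy_sd == 0:
        alpha = np.zeros(m)
    elif truth.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, truth.pleiotropy_sd, size=m)
    else:  # directional: one-signed half-normal direct effects
        alpha = np.abs(rng.normal(0.0, truth.pleiotropy_sd, size=m))
    phi = truth.case_fraction
    se_y = 1.0 / (gen["scale"] * np.sqrt(truth.n_outcome * phi * (1.0 - phi)))
    beta_y = truth.theta * gen["beta_true"] + alpha + se_y * (gen["chol"] @ rng.standard_normal(m))
    return _assoc_list(gen, beta_y, se_y, truth.n_outcome, outcome_id, "binary",
                       n_cases=truth.n_outcome * phi)


def _simulate_expression(rng, gen: dict, trait_id: str, n_expression: int):
    # expression shares the causal variants; aggregated-tissue estimates with
    # their own sample size and noise, effects on the expression SD scale
    m = len(gen["ids"])
    se_e = 1.0 / (gen["scale"] * np.sqrt(n_expression))
    beta_e = 3.0 * gen["beta_true"] + se_e * (gen["chol"] @ rng.standard_normal(m))
    return _assoc_list(gen, beta_e, se_e, n_expression, trait_id, "quantitative")


def simulate_two_sample_region(
    truth: SimulationTruth,
    region: GeneRegion,
    m: int = 150,
    causal_r2: float = 0.01,
    outcome_id: str = "outcome",
    expression: bool = False,
    n_expression: int = 1000,
) -> dict:
    """Simulate exposure and outcome summary statistics for one cis region.

    Returns a dict with keys ``exposure``, ``outcome``, ``ld``, ``truth`` and
    (when ``expression=True``) ``expression``: association lists sharing
    variant IDs, positions, alleles and EAFs. Byte-identical across calls with
    the same truth (the seed lives in ``truth.seed``).
    """
    rng = np.random.default_rng(truth.seed)
    gen = _simulate_region_genetics(rng, truth, region, m, causal_r2)
    out = {
        "exposure": _assoc_list(gen, gen["beta_x"], gen["se_x"], truth.n_exposure,
                                region.cytokine_id, "quantitative"),
        "outcome": _simulate_outcome(rng, truth, gen, outcome_id),
        "ld": gen["ld"],
        "truth": truth,
    }
    if expression:
        out["expression"] = _simulate_expression(
            rng, gen, f"{region.cytokine_id}_expression", n_expression)
    return out


def simulate_coloc_region(
    shared: bool,
    z_scale: float,
    m: int = 50,
    rho: float = 0.8,
    seed: int = 0,
    chrom: str = "1",
    start: int = 1_000_000,
    spacing: int = 500,
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Simulate a pair of association signals for colocalization testing.

    One causal variant per trait: the same index when ``shared``, otherwise
    two indices half the region apart (negligible AR(1) LD). Z-scores
    propagate through the LD correlation; trait 1 is quantitative (se 0.02)
    and trait 2 binary (se 0.03).
    """
    if m < 10:
        raise DomainError("m must be >= 10")
    rng = np.random.default_rng(seed)
    r = simulate_ld(m, rho).r
    gen = {
        "ids": [f"coloc_snp{j + 1:04d}" for j in range(m)],
        "chrom": chrom,
        "positions": start + spacing * np.arange(m),
        "eaf": rng.uniform(0.05, 0.95, size=m),
    }
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    gen["eas"] = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    gen["oas"] = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))

    i1 = m // 4
    i2 = i1 if shared else (i1 + m // 2) % m
    z1 = z_scale * r[:, i1] + chol @ rng.standard_normal(m)
    z2 = z_scale * r[:, i2] + chol @ rng.standard_normal(m)
    se1 = np.full(m, 0.02)
    se2 = np.full(m, 0.03)
    t1 = _assoc_list(gen, z1 * se1, se1, 10_000, "trait1", "quantitative")
    t2 = _assoc_list(gen, z2 * se2, se2, 50_000, "trait2", "binary")
    return t1, t2


@dataclass
class CatalogPaths:
    """File layout of a simulated input bundle, consumable by the pipeline."""

    root: object
    regions: object
    exposure: dict = field(default_factory=dict)  # cytokine -> path
    expression: dict = field(default_factory=dict)
    outcome: dict = field(default_factory=dict)  # outcome -> path
    ld: dict = field(default_factory=dict)  # cytokine -> path
    truth: object = None


def simulate_catalog(
    out_dir,
    n_cytokines: int = 3,
    n_outcomes: int = 2,
    truth_grid: dict[tuple[str, str], SimulationTruth] | None = None,
    seed: int = 0,
    m: int = 150,
    causal_r2: float = 0.01,
    region_span: int = 40_000,
    expression: bool = True,
    outcome_salt: str = "",
) -> CatalogPaths:
    """Write a full synthetic input bundle (regions, sumstats, LD, truth manifest).

    ``outcome_salt`` perturbs only the outcome-noise seeds: with the same
    ``seed`` but a different salt the catalog shares every variant, allele,
    EAF and exposure estimate while the outcome GWAS is an independent sample
    — the construction used for replication experiments.

    Cytokines are named ``CYT01..``, outcomes ``cancer1..``; each pair's truth
    comes from ``truth_grid`` (default: null effects everywhere). Each
    cytokine's exposure GWAS is one dataset — its genetics and exposure noise
    are drawn once (from the first outcome's truth for exposure-side
    parameters) and shared across outcomes; only the outcome realizations
    differ per pair. The directory layout is consumable by
    :func:`cytomr.pipeline.run_pipeline` unchanged, and the truth manifest
    lists exactly n_cytokines * n_outcomes rows.
    """
    from pathlib import Path

    from .sumstats import write_ld_matrix, write_sumstats

    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    (root / "exposure").mkdir(exist_ok=True)
    (root / "outcome").mkdir(exist_ok=True)
    (root / "ld").mkdir(exist_ok=True)
    if expression:
        (root / "expression").mkdir(exist_ok=True)

    cytokines = [f"CYT{i + 1:02d}" for i in range(n_cytokines)]
    outcomes = [f"cancer{i + 1}" for i in range(n_outcomes)]
    regions = []
    for i, cyt in enumerate(cytokines):
        start = 1_000_000 + i * 5_000_000
        regions.append(
            GeneRegion(cyt, f"GENE_{cyt}", f"ENSG{i:011d}", str(i % 22 + 1),
                       start, start + region_span)
        )
    region_df = pd.DataFrame(
        {
            "cytokine": [r.cytokine_id for r in regions],
            "gene": [r.gene_symbol for r in regions],
            "ensembl_id": [r.ensembl_id for r in regions],
            "chr": [r.chromosome for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
        }
    )
    regions_path = root / "regions.tsv"
    region_df.to_csv(regions_path, sep="\t", index=False)

    paths = CatalogPaths(root=root, regions=regions_path)
    truth_rows = []
    outcome_frames: dict[str, list] = {o: [] for o in outcomes}
    for region in regions:
        cyt = region.cytokine_id
        pair_truths = {}
        for out_name in outcomes:
            base = truth_grid.get((cyt, out_name)) if truth_grid else None
            truth = base if base is not None else SimulationTruth()
            pair_truths[out_name] = SimulationTruth(
                **{**asdict(truth), "seed": derive_seed(seed, cyt, out_name, outcome_salt)}
            )
        exp_truth = pair_truths[outcomes[0]]
        rng_cyt = np.random.default_rng(derive_seed(seed, cyt, "exposure"))
        gen = _simulate_region_genetics(rng_cyt, exp_truth, region, m, causal_r2)

        p = root / "exposure" / f"{cyt}.tsv"
        write_sumstats(
            _assoc_list(gen, gen["beta_x"], gen["se_x"], exp_truth.n_exposure,
                        cyt, "quantitative"),
            p,
        )
        paths.exposure[cyt] = p
        pld = root / "ld" / f"{cyt}.tsv"
        write_ld_matrix(gen["ld"], pld)
        paths.ld[cyt] = pld
        if expression:
            pe = root / "expression" / f"{cyt}.tsv"
            write_sumstats(_simulate_expression(rng_cyt, gen, f"{cyt}_expression", 1000), pe)
            paths.expression[cyt] = pe

        for out_name in outcomes:
            truth = pair_truths[out_name]
            rng_pair = np.random.default_rng(truth.seed)
            outcome_frames[out_name].append(_simulate_outcome(rng_pair, truth, gen, out_name))
            truth_rows.append({"cytokine": cyt, "outcome": out_name, **asdict(truth)})

    for out_name, frames in outcome_frames.items():
        allrecs = [a for frame in frames for a in frame]
        p = root / "outcome" / f"{out_name}.tsv"
        write_sumstats(allrecs, p)
        paths.outcome[out_name] = p

    truth_path = root / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    paths.truth = truth_path
    return paths
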