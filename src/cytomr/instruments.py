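"""Cis instrument selection and instrument-strength diagnostics.

Instruments for a cytokine are variants inside its gene region extended by a
flank (default 500 kb each side, hg19), passing MAF and association-p filters,
and pruned to low pairwise LD by greedy p-value clumping. Two definitions are
supported: cis-pQTL (associated with the circulating protein at p < 1e-4) and
cis-eQTL (associated with the gene's expression aggregated across tissues at
p < 1e-4 AND with the circulating protein at p < 0.05; effect estimates kept
on the protein scale).

Per-variant explained variance uses r2 = 2*eaf*(1-eaf)*beta^2 for a
unit-variance phenotype with betas per SD; clumped variants are treated as
independent when summing. F = r2*(n-2)/(1-r2) per variant, averaged per
cytokine. Power for a binary outcome uses the standard two-sample
normal-approximation closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .sumstats import LDMatrix, VariantAssociation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRegion:
    """A cytokine's coding-gene interval (hg19, 1-based inclusive)."""

    cytokine_id: str
    gene_symbol: str
    ensembl_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise DomainError(f"{self.gene_symbol}: region start > end")


def read_gene_regions(path) -> list[GeneRegion]:
    """Read a gene-region table (columns cytokine, gene, ensembl_id, chr, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    return [
        GeneRegion(
            cytokine_id=str(r.cytokine),
            gene_symbol=str(r.gene),
            ensembl_id=str(getattr(r, "ensembl_id", "")),
            chromosome=str(r.chr),
            start=int(r.start),
            end=int(r.end),
        )
        for r in df.itertuples(index=False)
    ]


def define_cis_window(region: GeneRegion, flank: int = 500_000) -> tuple[str, int, int]:
    """Gene body extended by ``flank`` bp on each side, clamped at position 1."""
    return region.chromosome, max(1, region.start - flank), region.end + flank


def clump(
    assocs: list[VariantAssociation],
    ld: LDMatrix,
    r2_max: float = 0.1,
) -> list[VariantAssociation]:
    """Greedy LD clumping on ascending p-value.

    Candidates are ranked by (p, position, variant_id); a variant is accepted
    iff its LD r-squared with every already-accepted variant is below
    ``r2_max``. Output preserves acceptance order, so the globally smallest
    p-value always survives. Deterministic regardless of input order.
    """
    ranked = sorted(assocs, key=lambda a: (a.pvalue, a.position, a.variant_id))
    for a in ranked:
        ld.index(a.variant_id)  # raises MissingLDError with the variant named
    accepted: list[VariantAssociation] = []
    for a in ranked:
        if all(ld.r2(a.variant_id, b.variant_id) < r2_max for b in accepted):
            accepted.append(a)
    return accepted


def variant_r2(beta: float, eaf: float) -> float:
    """Proportion of exposure variance explained: 2*eaf*(1-eaf)*beta^2.

    Assumes a unit-variance phenotype with ``beta`` per allele in SD units.
    Invariant under allele flip (eaf -> 1-eaf, beta -> -beta).
    """
    if not (0.0 < eaf < 1.0):
        raise DomainError(f"degenerate allele frequency {eaf}")
    return float(2.0 * eaf * (1.0 - eaf) * beta**2)


def f_statistic(r2: float, n: float) -> float:
    """Single-variant instrument-strength F statistic: r2*(n-2)/(1-r2)."""
    if not (0.0 <= r2 < 1.0):
        raise DomainError(f"r2 must be in [0, 1), got {r2}")
    if n <= 2:
        raise DomainError(f"sample size must exceed 2, got {n}")
    return float(r2 * (n - 2) / (1.0 - r2))


@dataclass(frozen=True)
class PowerConfig:
    """Settings for post-hoc power: alternative OR per SD, type-I error, outcome GWAS size."""

    n: float
    case_fraction: float
    or_alt: float = 1.2
    alpha: float = 0.05

    def __post_init__(self):
        if self.or_alt <= 0:
            raise DomainError("or_alt must be positive")
        if not (0 < self.alpha < 1):
            raise DomainError("alpha must be in (0,1)")
        if not (0 < self.case_fraction < 1):
            raise DomainError("case_fraction must be in (0,1)")


def power_binary_outcome(cfg: PowerConfig, r2: float) -> float:
    """Two-sample MR power for a binary outcome (normal approximation).

    power = Phi( sqrt(n * r2 * phi * (1-phi)) * |ln(or_alt)| - z_{1-alpha/2} ),
    with phi the outcome case fraction and r2 the variance in the exposure
    explained by the instrument.
    """
    if not (0.0 <= r2 < 1.0):
        raise DomainError(f"r2 must be in [0, 1), got {r2}")
    phi = cfg.case_fraction
    z_crit = stats.norm.ppf(1.0 - cfg.alpha / 2.0)
    ncp = np.sqrt(cfg.n * r2 * phi * (1.0 - phi)) * abs(np.log(cfg.or_alt))
    return float(stats.norm.cdf(ncp - z_crit))


@dataclass
class InstrumentSet:
    """Clumped cis variants proxying one cytokine, with strength diagnostics."""

    cytokine_id: str
    definition: str  # "cis_pQTL" or "cis_eQTL"
    variants: list[VariantAssociation]
    per_variant_r2: list[float] = field(default_factory=list)
    per_variant_F: list[float] = field(default_factory=list)
    selection_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def total_r2(self) -> float:
        return float(sum(self.per_variant_r2))

    @property
    def mean_F(self) -> float:
        return float(np.mean(self.per_variant_F)) if self.per_variant_F else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        from .sumstats import to_dataframe

        df = to_dataframe(self.variants)
        df["r2"] = self.per_variant_r2
        df["F"] = self.per_variant_F
        df["cytokine"] = self.cytokine_id
        df["definition"] = self.definition
        return df


def _attach_diagnostics(
    inst: InstrumentSet, n_default: float | None = None
) -> InstrumentSet:
    r2s, fs = [], []
    for v in inst.variants:
        n = v.n if v.n is not None else n_default
        if v.eaf is None or not (0 < v.eaf < 1) or n is None or n <= 2:
            r2s.append(float("nan"))
            fs.append(float("nan"))
            continue
        r2 = variant_r2(v.beta, v.eaf)
        r2s.append(r2)
        fs.append(f_statistic(r2, n))
    inst.per_variant_r2 = r2s
    inst.per_variant_F = fs
    return inst


def _window_maf_filter(
    assocs: list[VariantAssociation],
    region: GeneRegion,
    flank: int,
    maf_min: float,
    log: list[tuple[str, str]],
) -> list[VariantAssociation]:
    chrom, lo, hi = define_cis_window(region, flank)
    kept = []
    for a in assocs:
        if a.chromosome != chrom or not (lo <= a.position <= hi):
            log.append((a.variant_id, "outside cis window"))
            continue
        if maf_min > 0:
            if a.maf is None:
                log.append((a.variant_id, "missing EAF for MAF filter"))
                continue
            if a.maf < maf_min:
                log.append((a.variant_id, f"MAF {a.maf:.3g} < {maf_min}"))
                continue
        kept.append(a)
    return kept


def select_pqtl_instruments(
    cyto_assocs: list[VariantAssociation],
    region: GeneRegion,
    ld: LDMatrix | None,
    p_max: float = 1e-4,
    maf_min: float = 0.05,
    r2_max: float = 0.1,
    flank: int = 500_000,
    n_default: float | None = None,
) -> InstrumentSet:
    """Build the cis-pQTL instrument set for one cytokine.

    Filter to the cis window, drop MAF < ``maf_min`` (variants with missing
    EAF are dropped with a log entry, not an error), drop p >= ``p_max``,
    clump at ``r2_max``, then attach r2/F diagnostics. An empty result is a
    valid InstrumentSet. ``ld=None`` skips LD pruning (variants treated as
    independent).
    """
    log: list[tuple[str, str]] = []
    kept = _window_maf_filter(cyto_assocs, region, flank, maf_min, log)
    strong = []
    for a in kept:
        if a.pvalue < p_max:
            strong.append(a)
        else:
            log.append((a.variant_id, f"p {a.pvalue:.3g} >= {p_max:g}"))
    clumped = clump(strong, ld, r2_max) if ld is not None else sorted(
        strong, key=lambda a: (a.pvalue, a.position, a.variant_id)
    )
    inst = InstrumentSet(region.cytokine_id, "cis_pQTL", clumped, selection_log=log)
    return _attach_diagnostics(inst, n_default)


def select_eqtl_instruments(
    expr_assocs: list[VariantAssociation],
    cyto_assocs: list[VariantAssociation],
    region: GeneRegion,
    ld: LDMatrix | None,
    p_expr: float = 1e-4,
    p_cyto: float = 0.05,
    maf_min: float = 0.05,
    r2_max: float = 0.1,
    flank: int = 500_000,
    n_default: float | None = None,
) -> InstrumentSet:
    """Build the cis-eQTL instrument set for one cytokine.

    A variant is kept iff it lies in the cis window, its aggregated-tissue
    expression p < ``p_expr``, its circulating-cytokine p < ``p_cyto``, and
    MAF >= ``maf_min``. Clumping ranks on the cytokine p-value, and the
    instrument betas/SEs are the cytokine (not expression) estimates.
    Expression and cytokine associations must be pre-harmonized to the same
    effect allele.
    """
    log: list[tuple[str, str]] = []
    expr_p = {a.variant_id: a.pvalue for a in expr_assocs}
    kept = _window_maf_filter(cyto_assocs, region, flank, maf_min, log)
    strong = []
    for a in kept:
        pe = expr_p.get(a.variant_id)
        if pe is None:
            log.append((a.variant_id, "no expression association"))
        elif pe >= p_expr:
            log.append((a.variant_id, f"expression p {pe:.3g} >= {p_expr:g}"))
        elif a.pvalue >= p_cyto:
            log.append((a.variant_id, f"cytokine p {a.pvalue:.3g} >= {p_cyto:g}"))
        else:
            strong.append(a)
    clumped = clump(strong, ld, r2_max) if ld is not None else sorted(
        strong, key=lambda a: (a.pvalue, a.position, a.variant_id)
    )
    inst = InstrumentSet(region.cytokine_id, "cis_eQTL", clumped, selection_log=log)
    return _attach_diagnostics(inst, n_default)


def trans_exclusion_filter(
    inst: InstrumentSet,
    other_trait_assocs: pd.DataFrame,
    p_trans: float = 5e-8,
) -> InstrumentSet:
    """Drop instruments associated in trans with other cytokines.

    ``other_trait_assocs`` has columns (variant_id, other_trait_id, pvalue)
    and must not include the instrumented cytokine itself. Variants with any
    other-trait p < ``p_trans`` are removed and diagnostics recomputed.
    Idempotent.
    """
    flagged = set(
        other_trait_assocs.loc[
            other_trait_assocs["pvalue"] < p_trans, "variant_id"
        ].astype(str)
    )
    kept, log = [], list(inst.selection_log)
    for v in inst.variants:
        if v.variant_id in flagged:
            log.append((v.variant_id, f"trans association p < {p_trans:g}"))
        else:
            kept.append(v)
    out = InstrumentSet(inst.cytokine_id, inst.definition, kept, selection_log=log)
    return _attach_diagnostics(out)
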