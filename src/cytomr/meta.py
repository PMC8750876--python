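"""Fixed-effect pooling of SNP-cytokine estimates across GWAS cohorts.

The cytokine exposure GWASs come from several sources (a Finnish meta-GWAS
plus SCALLOP or INTERVAL); per-SNP estimates are pooled by inverse-variance
weighting *before* instrument selection, but only when the per-SNP effect
estimates of the two GWASs correlate well over their shared variants.
Heterogeneity between cohorts is reported (Cochran's Q) but does not inflate
the pooled SE at this stage.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientOverlapError
from .sumstats import VariantAssociation, harmonize_pair, normal_p_from_z


def fixed_effect_meta(betas, ses) -> tuple[float, float]:
    """Inverse-variance weighted fixed-effect pooled estimate.

    beta = sum(b_k / se_k^2) / sum(1 / se_k^2); se = sqrt(1 / sum(1 / se_k^2)).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1 or b.size < 1:
        raise DomainError("betas and ses must be equal-length 1-d sequences of length >= 1")
    if np.any(s <= 0):
        raise DomainError("all standard errors must be positive")
    w = 1.0 / s**2
    return float(np.sum(w * b) / np.sum(w)), float(np.sqrt(1.0 / np.sum(w)))


def cochran_q(betas, ses) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic over cohort estimates of one SNP."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if np.any(s <= 0):
        raise DomainError("all standard errors must be positive")
    pooled, _ = fixed_effect_meta(b, s)
    w = 1.0 / s**2
    q = float(np.sum(w * (b - pooled) ** 2))
    df = int(b.size - 1)
    p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, df, p


def cross_gwas_beta_correlation(
    a: list[VariantAssociation], b: list[VariantAssociation]
) -> tuple[float, int]:
    """Pearson correlation of harmonized per-SNP betas over shared variants.

    The caller decides whether the two GWASs "correlate well" enough to pool
    (threshold configurable in :func:`pool_cohorts`).
    """
    hd = harmonize_pair(a, b)
    if hd.n_snps < 3:
        raise InsufficientOverlapError(
            f"only {hd.n_snps} shared harmonized variants; need >= 3"
        )
    bx, _, by, _ = hd.arrays()
    r = float(np.corrcoef(bx, by)[0, 1])
    return r, hd.n_snps


def pool_cohorts(
    cohorts: dict[str, list[VariantAssociation]],
    reference: str | None = None,
    min_corr: float = 0.5,
) -> list[VariantAssociation]:
    """Pool per-SNP estimates across cohorts for one cytokine.

    The reference cohort (default: the first key, conventionally the Finnish
    GWAS) anchors allele orientation. Each additional cohort is harmonized to
    the reference; if its betas correlate with the reference at Pearson r >=
    ``min_corr`` over shared variants, shared SNPs are pooled by fixed-effect
    meta-analysis (reference-only SNPs keep their reference estimates);
    otherwise that cohort is ignored. Pooled p-values are recomputed from the
    pooled beta/se, and sample sizes summed.
    """
    if not cohorts:
        raise DomainError("at least one cohort required")
    names = list(cohorts)
    ref_name = reference if reference is not None else names[0]
    ref = cohorts[ref_name]
    pooled: dict[str, VariantAssociation] = {a.variant_id: a for a in ref}
    extra_n: dict[str, float] = {}

    for name in names:
        if name == ref_name:
            continue
        other = cohorts[name]
        try:
            r, _ = cross_gwas_beta_correlation(ref, other)
        except InsufficientOverlapError:
            continue
        if not (r >= min_corr):
            continue
        hd = harmonize_pair(ref, other)
        for rec in hd.records:
            cur = pooled[rec.variant_id]
            beta, se = fixed_effect_meta([cur.beta, rec.beta_y], [cur.se, rec.se_y])
            n_other = next((a.n for a in other if a.variant_id == rec.variant_id), None)
            n_new = (cur.n or 0) + (n_other or 0)
            pooled[rec.variant_id] = VariantAssociation(
                variant_id=cur.variant_id,
                chromosome=cur.chromosome,
                position=cur.position,
                effect_allele=cur.effect_allele,
                other_allele=cur.other_allele,
                beta=beta,
                se=se,
                pvalue=normal_p_from_z(beta / se),
                eaf=cur.eaf,
                n=n_new if n_new > 0 else cur.n,
                trait_id=cur.trait_id,
                trait_type=cur.trait_type,
            )
    return [pooled[a.variant_id] for a in ref]
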