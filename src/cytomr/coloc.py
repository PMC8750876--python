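"""Bayesian colocalization of cytokine and cancer association signals.

For each FDR-significant cytokine-cancer pair the region extending 25 kb on
both sides of the lead cytokine variant is tested for a shared causal
variant. Per-SNP evidence is a Wakefield approximate Bayes factor; the five
standard single-causal-variant hypotheses are enumerated:

  H0 no association; H1 trait 1 only; H2 trait 2 only;
  H3 two distinct causal variants; H4 one shared causal variant.

Posteriors are priors times the summed ABF configurations, normalized.
A shared-variant posterior strictly greater than 0.8 is called colocalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import DomainError, EmptyOverlapError
from .sumstats import VariantAssociation


@dataclass(frozen=True)
class ColocConfig:
    """Colocalization priors and region settings.

    ``prior_p1``/``prior_p2`` are the per-SNP priors of association with each
    trait, ``prior_p12`` the per-SNP prior of association with both; ``w1``/
    ``w2`` are the prior effect variances (0.2^2 for a quantitative trait,
    0.15^2 for a binary log-OR trait).
    """

    window_bp: int = 25_000
    prior_p1: float = 1e-4
    prior_p2: float = 1e-4
    prior_p12: float = 1e-5
    w1: float = 0.2**2
    w2: float = 0.15**2

    def __post_init__(self):
        for p in (self.prior_p1, self.prior_p2, self.prior_p12):
            if not (0.0 < p < 1.0):
                raise DomainError("priors must lie in (0,1)")
        if self.prior_p12 > min(self.prior_p1, self.prior_p2):
            raise DomainError("prior_p12 must not exceed min(prior_p1, prior_p2)")


@dataclass
class ColocResult:
    """Five-hypothesis posteriors for one region, plus the shared-variant call."""

    region: tuple[int, int]
    n_snps: int
    pp: tuple[float, float, float, float, float]  # (none, t1 only, t2 only, distinct, shared)
    lead_variant_id: str
    shared_call: bool

    @property
    def pp_shared(self) -> float:
        return self.pp[4]

    @property
    def pp_distinct(self) -> float:
        return self.pp[3]


def lead_window(
    assocs: list[VariantAssociation], cfg: ColocConfig | None = None
) -> tuple[VariantAssociation, tuple[int, int]]:
    """Lead variant (smallest p, ties to the smaller position) and its +/- window."""
    if not assocs:
        raise EmptyOverlapError("no exposure associations to pick a lead variant from")
    cfg = cfg or ColocConfig()
    lead = min(assocs, key=lambda a: (a.pvalue, a.position, a.variant_id))
    return lead, (lead.position - cfg.window_bp, lead.position + cfg.window_bp)


def wakefield_labf(beta: float, se: float, w: float) -> float:
    """Log approximate Bayes factor for one association estimate.

    log ABF = 0.5*ln(se^2/(se^2+W)) + z^2*W/(2*(se^2+W)), z = beta/se, with W
    the prior variance of the true effect. Tends to 0 as W -> 0 and is
    negative for z = 0.
    """
    if se <= 0 or w <= 0:
        raise DomainError("se and W must be positive")
    v = se**2
    z = beta / se
    return float(0.5 * np.log(v / (v + w)) + z**2 * w / (2.0 * (v + w)))


def coloc_posteriors(
    trait1_assocs: list[VariantAssociation],
    trait2_assocs: list[VariantAssociation],
    cfg: ColocConfig | None = None,
) -> ColocResult:
    """Enumerate the five colocalization hypotheses over shared variants.

    Assumes at most one causal variant per trait in the region. The window is
    centred on the trait-1 (cytokine) lead variant. Likelihood sums use
    log-sum-exp; the distinct-variants configuration sum is S1*S2 - S12 (all
    ordered pairs minus the shared-index diagonal).
    """
    cfg = cfg or ColocConfig()
    lead, (lo, hi) = lead_window(trait1_assocs, cfg)
    t2 = {a.variant_id: a for a in trait2_assocs}
    pairs = [
        (a, t2[a.variant_id])
        for a in trait1_assocs
        if lo <= a.position <= hi and a.variant_id in t2
    ]
    if not pairs:
        raise EmptyOverlapError("no shared variants inside the colocalization window")
    labf1 = np.array([wakefield_labf(a.beta, a.se, cfg.w1) for a, _ in pairs])
    labf2 = np.array([wakefield_labf(b.beta, b.se, cfg.w2) for _, b in pairs])

    l1 = logsumexp(labf1)
    l2 = logsumexp(labf2)
    l12 = logsumexp(labf1 + labf2)
    # sum over ordered pairs i != j of ABF1_i * ABF2_j = S1*S2 - S12
    with np.errstate(divide="ignore"):
        diff = 1.0 - np.exp(l12 - (l1 + l2))
        lcross = (l1 + l2) + np.log(diff) if diff > 0 else -np.inf

    logpost = np.array(
        [
            0.0,
            np.log(cfg.prior_p1) + l1,
            np.log(cfg.prior_p2) + l2,
            np.log(cfg.prior_p1) + np.log(cfg.prior_p2) + lcross,
            np.log(cfg.prior_p12) + l12,
        ]
    )
    pp = np.exp(logpost - logsumexp(logpost))
    pp = pp / pp.sum()
    res = ColocResult(
        region=(lo, hi),
        n_snps=len(pairs),
        pp=tuple(float(x) for x in pp),
        lead_variant_id=lead.variant_id,
        shared_call=False,
    )
    res.shared_call = call_shared(res)
    return res


def call_shared(res: ColocResult, pp_min: float = 0.8) -> bool:
    """Shared-causal-variant call: strictly greater than ``pp_min``."""
    return bool(res.pp_shared > pp_min)
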