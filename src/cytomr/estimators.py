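"""Two-sample MR causal estimators and pleiotropy-robust sensitivity analyses.

All estimators consume a :class:`~cytomr.sumstats.HarmonizedDataset` of
allele-aligned (beta_x, se_x, beta_y, se_y) pairs and return an
:class:`MRResult` whose ``theta`` is the log odds ratio of the outcome per SD
of the exposure. First-order weights (w_j = beta_xj^2 / se_yj^2, equivalently
ratio SE se_yj/|beta_xj|) are used throughout; the random-effects IVW applies
multiplicative variance inflation max(1, sqrt(Q/(J-1))) so that the
random-effects SE never undercuts the fixed-effect one.

Estimator menu
--------------
wald_ratio            single-instrument ratio of coefficients
ivw                   fixed / multiplicative-random-effects IVW
ivw_correlated        generalized (LD-aware) IVW for correlated instruments
egger                 MR-Egger regression (slope + directional-pleiotropy intercept)
weighted_median       weighted median with parametric-bootstrap SE
contamination_mixture ConMix profile-likelihood estimate over a theta grid
mr_presso             global pleiotropy test + outlier removal
mvmr_ivw              multivariable MR across several exposures jointly
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    CollinearityError,
    DegenerateInstrumentError,
    DomainError,
    InsufficientInstrumentsError,
)
from .sumstats import HarmonizedDataset

Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class MRResult:
    """One causal-effect estimate: method, theta (log-OR per SD), SE, CI, p."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    notes: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _normal_result(method, theta, se, n_snps, **kw) -> MRResult:
    p = float(2.0 * stats.norm.sf(abs(theta) / se)) if se > 0 else (1.0 if theta == 0 else 0.0)
    return MRResult(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z95 * se),
        ci_high=float(theta + Z95 * se),
        pvalue=p,
        n_snps=n_snps,
        **kw,
    )


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MRResult:
    """Single-instrument ratio estimate with first-order standard error.

    theta = beta_y / beta_x, se = se_y / |beta_x|.
    """
    if beta_x == 0:
        raise DegenerateInstrumentError("exposure beta is zero; ratio undefined")
    theta = beta_y / beta_x
    se = se_y / abs(beta_x)
    return _normal_result("wald_ratio", theta, se, 1)


def _nonzero_bx(hd: HarmonizedDataset) -> HarmonizedDataset:
    if hd.n_snps == 0:
        raise InsufficientInstrumentsError("dataset contains no harmonized instruments")
    keep = [r.beta_x != 0 for r in hd.records]
    if all(keep):
        return hd
    out = hd.subset(keep)
    out.provenance_log = out.provenance_log + [
        (r.variant_id, "dropped: zero exposure beta") for r, k in zip(hd.records, keep) if not k
    ]
    if out.n_snps == 0:
        raise DegenerateInstrumentError("all instruments have zero exposure beta")
    return out


def ivw(hd: HarmonizedDataset, effects: str = "multiplicative_random") -> MRResult:
    """Inverse-variance weighted MR over per-SNP ratio estimates.

    With first-order weights w_j = beta_xj^2/se_yj^2 this equals weighted
    regression of beta_y on beta_x through the origin. ``effects`` is
    ``"fixed"`` or ``"multiplicative_random"``; the latter multiplies the SE
    by max(1, sqrt(Q/(J-1))) where Q is Cochran's heterogeneity statistic.
    A single-SNP dataset delegates to :func:`wald_ratio`.
    """
    if effects not in ("fixed", "multiplicative_random"):
        raise DomainError(f"unknown effects mode {effects!r}")
    hd = _nonzero_bx(hd)
    if hd.n_snps == 1:
        r = hd.records[0]
        return wald_ratio(r.beta_x, r.se_x, r.beta_y, r.se_y)
    bx, _, by, sy = hd.arrays()
    ratios = by / bx
    w = bx**2 / sy**2
    theta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (ratios - theta) ** 2))
    df = hd.n_snps - 1
    q_p = float(stats.chi2.sf(q, df))
    if effects == "multiplicative_random":
        se *= max(1.0, np.sqrt(q / df))
    return _normal_result(
        "ivw_re" if effects == "multiplicative_random" else "ivw_fe",
        theta, se, hd.n_snps, q_stat=q, q_df=df, q_pvalue=q_p,
    )


def ivw_correlated(hd: HarmonizedDataset, effects: str = "multiplicative_random") -> MRResult:
    """LD-aware IVW: generalized regression through the origin.

    The outcome covariance is Omega_jk = se_yj * se_yk * r_jk with r the LD
    correlation; theta = (bx' Omega^-1 bx)^-1 bx' Omega^-1 by. Reduces to the
    fixed-effect IVW under an identity LD matrix. The multiplicative SE
    inflation uses the generalized residual quadratic form over J-1 df.
    """
    if hd.ld is None:
        raise DomainError("ivw_correlated requires an LD matrix on the dataset")
    hd = _nonzero_bx(hd)
    bx, _, by, sy = hd.arrays()
    r = hd.ld.subset(hd.variant_ids()).r
    off = r[~np.eye(len(r), dtype=bool)]
    if off.size and np.max(np.abs(off)) >= 1.0:
        raise CollinearityError("off-diagonal LD |r| >= 1; instruments are duplicates")
    omega = np.outer(sy, sy) * r
    try:
        np.linalg.cholesky(omega)  # positive-definiteness gate
    except np.linalg.LinAlgError:
        raise CollinearityError(
            "singular outcome covariance; clump instruments at a stricter r2"
        ) from None
    oi_bx = np.linalg.solve(omega, bx)
    denom = float(bx @ oi_bx)
    theta = float(oi_bx @ by / denom)
    se = float(np.sqrt(1.0 / denom))
    resid = by - theta * bx
    q = float(resid @ np.linalg.solve(omega, resid))
    df = max(hd.n_snps - 1, 1)
    q_p = float(stats.chi2.sf(q, df)) if hd.n_snps > 1 else None
    if effects == "multiplicative_random" and hd.n_snps > 1:
        se *= max(1.0, np.sqrt(q / df))
    return _normal_result("ivw_ld", theta, se, hd.n_snps,
                          q_stat=q, q_df=df if hd.n_snps > 1 else None, q_pvalue=q_p)


def _orient_positive_bx(bx, by):
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def egger(hd: HarmonizedDataset) -> MRResult:
    """MR-Egger: weighted regression beta_y = alpha + theta*beta_x.

    Instruments are first oriented so every beta_x >= 0 (flipping paired
    signs), making the fit invariant to allele coding. Weights are 1/se_y^2;
    both SEs carry the multiplicative inflation max(1, sqrt(RSS_w/(J-2))).
    The intercept alpha estimates directional pleiotropy.
    """
    hd = _nonzero_bx(hd)
    if hd.n_snps < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {hd.n_snps}")
    bx, _, by, sy = hd.arrays()
    bx, by = _orient_positive_bx(bx, by)
    w = 1.0 / sy**2
    # weighted normal equations for [alpha, theta]
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    try:
        coef = np.linalg.solve(xtwx, xtwy)
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        raise CollinearityError("degenerate Egger design (constant beta_x?)") from None
    alpha, theta = float(coef[0]), float(coef[1])
    resid = by - x @ coef
    rss_w = float(np.sum(w * resid**2))
    infl = max(1.0, np.sqrt(rss_w / (hd.n_snps - 2)))
    se_alpha = float(np.sqrt(cov[0, 0])) * infl
    se_theta = float(np.sqrt(cov[1, 1])) * infl
    res = _normal_result("egger", theta, se_theta, hd.n_snps)
    res.egger_intercept = alpha
    res.egger_intercept_se = se_alpha
    res.egger_intercept_p = float(2.0 * stats.norm.sf(abs(alpha) / se_alpha)) if se_alpha > 0 else 1.0
    return res


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with midpoint cumulative weights and linear interpolation."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / np.sum(weights)
    p = np.cumsum(w) - w / 2.0
    if 0.5 <= p[0]:
        return float(v[0])
    if 0.5 >= p[-1]:
        return float(v[-1])
    return float(np.interp(0.5, p, v))


def weighted_median(hd: HarmonizedDataset, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median MR estimate with parametric-bootstrap SE.

    Per-SNP ratios are ordered with normalized weights w_j = beta_xj^2/se_yj^2;
    the estimate is the ratio at cumulative weight 0.5 (linear interpolation
    between bracketing SNPs). The SE is the SD of the estimate across
    ``n_boot`` parametric resamples of (beta_x, beta_y) from normals with
    their reported SEs; bit-reproducible given ``seed``.
    """
    hd = _nonzero_bx(hd)
    if hd.n_snps < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {hd.n_snps}")
    bx, sx, by, sy = hd.arrays()
    theta = _weighted_median(by / bx, bx**2 / sy**2)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        boots[b] = _weighted_median(byb[ok] / bxb[ok], bxb[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    return _normal_result("weighted_median", theta, se, hd.n_snps)


@dataclass(frozen=True)
class ConMixConfig:
    """Contamination-mixture settings: invalid-component SD, grid resolution/span."""

    psi: float | None = None  # None -> 1.5 * SD of the per-SNP ratio estimates
    grid_points: int = 500
    grid_span: float = 3.0  # multiplier of the ratio-estimate range

    def __post_init__(self):
        if self.psi is not None and self.psi <= 0:
            raise DomainError("psi must be positive when explicit")
        if self.grid_points < 50:
            raise DomainError("grid_points must be >= 50")


def contamination_mixture(hd: HarmonizedDataset, cfg: ConMixConfig | None = None) -> MRResult:
    """ConMix: profile likelihood over a theta grid with a two-component model.

    Each SNP's ratio estimate is either valid — normal around theta with its
    first-order SE — or invalid — normal around zero with variance inflated by
    psi^2. At every grid point each SNP joins the component with the higher
    likelihood; theta is the grid argmax and the 95% CI the grid region within
    1.92 log-likelihood units of the maximum. A disjoint CI region is flagged
    ``multimodal`` in the notes and reported as its widest bracketing interval;
    an all-invalid maximum (psi too large) is flagged ``flat-likelihood``.
    """
    cfg = cfg or ConMixConfig()
    hd = _nonzero_bx(hd)
    if hd.n_snps < 3:
        raise InsufficientInstrumentsError(f"ConMix needs >= 3 SNPs, got {hd.n_snps}")
    bx, _, by, sy = hd.arrays()
    ratios = by / bx
    ses = sy / np.abs(bx)
    spread = float(np.std(ratios, ddof=1))
    psi = cfg.psi if cfg.psi is not None else 1.5 * spread
    if psi <= 0 or np.ptp(ratios) <= 1e-10 * max(1.0, float(np.max(np.abs(ratios)))):
        # all ratios (numerically) identical: degenerate consensus
        theta = float(ratios[0])
        return _normal_result("conmix", theta, float(np.min(ses)), hd.n_snps,
                              notes="degenerate: identical ratios")
    width = max(float(np.ptp(ratios)), 4.0 * float(np.median(ses)))
    mid = float(np.median(ratios))
    grid = np.linspace(mid - cfg.grid_span * width / 2.0,
                       mid + cfg.grid_span * width / 2.0, cfg.grid_points)
    sd_invalid = np.sqrt(ses**2 + psi**2)
    ll_invalid = stats.norm.logpdf(ratios, 0.0, sd_invalid)  # theta-free
    # J x G matrix of valid-component log-likelihoods
    llv = stats.norm.logpdf(ratios[:, None], grid[None, :], ses[:, None])
    ll = np.sum(np.maximum(llv, ll_invalid[:, None]), axis=0)
    k = int(np.argmax(ll))
    theta = float(grid[k])
    in_ci = ll >= ll[k] - 1.92
    idx = np.flatnonzero(in_ci)
    ci_low, ci_high = float(grid[idx[0]]), float(grid[idx[-1]])
    notes = []
    if np.any(np.diff(idx) > 1):
        notes.append("multimodal CI; widest bracketing interval reported")
    valid_at_max = llv[:, k] > ll_invalid
    if not np.any(valid_at_max):
        notes.append("flat-likelihood: all SNPs assigned invalid")
    if psi > 100.0 * (np.ptp(ratios) + float(np.max(ses))):
        # with psi far beyond the ratio spread the invalid density is
        # vanishingly small everywhere and the mixture cannot separate
        notes.append("psi far exceeds ratio spread; mixture uninformative")
    # two-sided p from the profile likelihood ratio against theta = 0
    ll0 = float(np.sum(np.maximum(stats.norm.logpdf(ratios, 0.0, ses), ll_invalid)))
    lr = max(0.0, 2.0 * (float(ll[k]) - ll0))
    p = float(stats.chi2.sf(lr, 1))
    se = (ci_high - ci_low) / (2.0 * Z95)
    return MRResult(
        method="conmix", theta=theta, se=float(se), ci_low=ci_low, ci_high=ci_high,
        pvalue=p, n_snps=hd.n_snps, notes="; ".join(notes),
    )


def conmix_validity_mask(hd: HarmonizedDataset, cfg: ConMixConfig | None = None) -> np.ndarray:
    """Per-SNP valid/invalid assignment at the ConMix maximum-likelihood theta."""
    cfg = cfg or ConMixConfig()
    res = contamination_mixture(hd, cfg)
    bx, _, by, sy = hd.arrays()
    ratios, ses = by / bx, sy / np.abs(bx)
    spread = float(np.std(ratios, ddof=1))
    psi = cfg.psi if cfg.psi is not None else 1.5 * spread
    if psi <= 0:
        return np.ones(len(ratios), dtype=bool)
    lv = stats.norm.logpdf(ratios, res.theta, ses)
    li = stats.norm.logpdf(ratios, 0.0, np.sqrt(ses**2 + psi**2))
    return lv > li


@dataclass(frozen=True)
class PressoConfig:
    """MR-PRESSO settings: simulation count, seed, per-SNP outlier alpha."""

    n_sim: int = 1000
    seed: int = 0
    outlier_alpha: float = 0.05  # Bonferroni-adjusted over SNPs

    def __post_init__(self):
        if self.n_sim < 100:
            raise DomainError("n_sim must be >= 100")


def mr_presso(
    hd: HarmonizedDataset, cfg: PressoConfig | None = None
) -> tuple[float, list[bool], MRResult]:
    """MR-PRESSO global pleiotropy test and outlier-corrected estimate.

    The observed residual sum of squares uses leave-one-out IVW predictions of
    beta_y (residuals weighted by 1/se_y^2). The null distribution is built
    from ``n_sim`` datasets with beta_y* drawn from N(theta_(-j)*beta_xj,
    se_yj^2); the global p is the empirical tail proportion (add-one
    smoothed). Per-SNP outlier p-values compare each observed weighted
    residual to its simulated distribution, Bonferroni-corrected over J; the
    corrected estimate is the IVW on non-outliers (equal to the raw IVW when
    none are flagged).

    Returns ``(global_p, outlier_flags, corrected_result)``.
    """
    cfg = cfg or PressoConfig()
    hd = _nonzero_bx(hd)
    j = hd.n_snps
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 SNPs, got {j}")
    bx, _, by, sy = hd.arrays()
    w = bx**2 / sy**2
    ratios = by / bx
    sw, swr = np.sum(w), np.sum(w * ratios)
    # leave-one-out fixed-effect IVW estimates
    theta_loo = (swr - w * ratios) / (sw - w)
    resid = by - theta_loo * bx
    obs_rss_terms = resid**2 / sy**2
    obs_rss = float(np.sum(obs_rss_terms))

    rng = np.random.default_rng(cfg.seed)
    by_sim = rng.normal(theta_loo * bx, sy, size=(cfg.n_sim, j))
    ratios_sim = by_sim / bx
    sw_sim = sw  # weights are fixed (beta_x, se_y unchanged)
    swr_sim = ratios_sim @ w
    theta_loo_sim = (swr_sim[:, None] - w * ratios_sim) / (sw_sim - w)
    resid_sim = by_sim - theta_loo_sim * bx
    rss_terms_sim = resid_sim**2 / sy**2
    rss_sim = np.sum(rss_terms_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= obs_rss)) / (cfg.n_sim + 1))
    per_snp_p = (1 + np.sum(rss_terms_sim >= obs_rss_terms, axis=0)) / (cfg.n_sim + 1)
    flags = list(per_snp_p < cfg.outlier_alpha / j)

    if any(flags):
        kept = hd.subset([not f for f in flags])
        corrected = ivw(kept)
        corrected.method = "presso_corrected"
        corrected.notes = f"{sum(flags)} outlier(s) removed"
    else:
        corrected = ivw(hd)
        corrected.method = "presso_corrected"
        corrected.notes = "no outliers flagged"
    return global_p, flags, corrected


def mvmr_ivw(beta_X: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray) -> list[MRResult]:
    """Multivariable MR: weighted least squares of beta_y on all exposures jointly.

    ``beta_X`` is J x K (J SNPs, K >= 2 exposures), no intercept, weights
    1/se_y^2. Returns one MRResult per exposure with the multiplicative SE
    inflation max(1, sqrt(RSS_w/(J-K))). A K=1 column matrix reduces to the
    fixed-effect IVW.
    """
    X = np.atleast_2d(np.asarray(beta_X, dtype=float))
    y = np.asarray(beta_y, dtype=float)
    s = np.asarray(se_y, dtype=float)
    if X.ndim != 2:
        raise DomainError("beta_X must be a J x K matrix")
    j, k = X.shape
    if j <= k:
        raise InsufficientInstrumentsError(f"need more SNPs ({j}) than exposures ({k})")
    if np.linalg.matrix_rank(X) < k:
        # name offending exposures: columns expressible from the others
        bad = []
        for c in range(k):
            others = np.delete(X, c, axis=1)
            if others.shape[1] == 0:
                continue
            proj, *_ = np.linalg.lstsq(others, X[:, c], rcond=None)
            if np.linalg.norm(X[:, c] - others @ proj) < 1e-10 * max(np.linalg.norm(X[:, c]), 1.0):
                bad.append(c)
        raise CollinearityError(
            f"rank-deficient exposure matrix; collinear exposure columns: {bad or 'unidentified'}"
        )
    w = 1.0 / s**2
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    cov = np.linalg.inv(xtwx)
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    infl = max(1.0, np.sqrt(rss_w / (j - k))) if j > k else 1.0
    out = []
    for c in range(k):
        se = float(np.sqrt(cov[c, c])) * infl
        out.append(_normal_result("mvmr", float(coef[c]), se, j))
    return out
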