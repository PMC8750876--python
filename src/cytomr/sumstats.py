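"""Reading, validation and harmonization of GWAS summary statistics.

This module is the single entry point for tabular genetic data: per-variant
association records (``VariantAssociation``), dense LD correlation matrices
(``LDMatrix``) and allele-aligned exposure/outcome pairs
(``HarmonizedDataset``) consumed by every MR estimator.

Coordinates are hg19, 1-based inclusive throughout. Effect sizes are on an SD
scale for quantitative traits and natural-log odds ratios for binary traits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    EmptyInputError,
    EmptyOverlapError,
    FormatError,
    MissingLDError,
)

logger = logging.getLogger(__name__)

#: canonical output headers for summary-statistic TSVs
CANONICAL_COLUMNS = ["variant_id", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]

_REQUIRED = ["variant_id", "chr", "pos", "ea", "oa", "beta", "se"]
_VALID_ALLELE_CHARS = set("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP-trait association estimate (one row of a GWAS summary file)."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None
    n_cases: float | None = None
    trait_id: str = ""
    trait_type: str = "quantitative"  # or "binary"

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


def normal_p_from_z(z: float) -> float:
    """Two-sided normal p-value for a z statistic."""
    return float(2.0 * stats.norm.sf(abs(z)))


def _validate_record(rec: VariantAssociation) -> str | None:
    """Return a drop reason for a hard-invariant violation, else None."""
    if rec.se is None or not math.isfinite(rec.se) or rec.se <= 0:
        return "nonpositive SE"
    if not math.isfinite(rec.beta):
        return "non-finite beta"
    if not set(rec.effect_allele) <= _VALID_ALLELE_CHARS or not rec.effect_allele:
        return "invalid effect allele"
    if not set(rec.other_allele) <= _VALID_ALLELE_CHARS or not rec.other_allele:
        return "invalid other allele"
    if rec.effect_allele == rec.other_allele:
        return "identical alleles"
    if rec.eaf is not None and not (0.0 <= rec.eaf <= 1.0):
        return "EAF outside [0,1]"
    if not (0.0 < rec.pvalue <= 1.0):
        return "p-value outside (0,1]"
    return None


def _warn_p_inconsistency(rec: VariantAssociation) -> None:
    # source files round p; warn only when the printed p disagrees grossly
    p_implied = normal_p_from_z(rec.beta / rec.se)
    if p_implied > 0 and rec.pvalue > 0:
        rel = abs(math.log(rec.pvalue) - math.log(p_implied)) / max(abs(math.log(p_implied)), 1.0)
        if rel > 0.10:
            logger.warning(
                "variant %s: reported p=%.3g inconsistent with beta/se (implies %.3g)",
                rec.variant_id, rec.pvalue, p_implied,
            )


def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_id: str = "",
    drop_log: list | None = None,
) -> list[VariantAssociation]:
    """Read a headered TSV/CSV of GWAS summary statistics.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row.
    column_map
        Mapping from canonical names (``variant_id, chr, pos, ea, oa, eaf,
        beta, se, p, n, n_cases``) to the file's column names. Defaults to the
        canonical names themselves.
    trait_type
        ``"quantitative"`` (betas in SD units) or ``"binary"`` (log odds ratios).
    drop_log
        Optional list; ``(variant_id, reason)`` tuples are appended for every
        row dropped by a hard invariant.

    Rows failing hard invariants (nonpositive SE, identical or non-ACGT
    alleles, EAF outside [0,1]) are dropped and logged. A missing p column is
    back-filled from the two-sided normal test of beta/se; a present p that is
    inconsistent with beta/se only triggers a warning, since published tables
    round.
    """
    if trait_type not in ("quantitative", "binary"):
        raise ConfigError(f"unknown trait_type {trait_type!r}")
    cmap = dict.fromkeys(CANONICAL_COLUMNS + ["n_cases"])
    for k in cmap:
        cmap[k] = k
    if column_map:
        for key, col in column_map.items():
            if key not in cmap:
                raise ConfigError(f"unknown canonical column {key!r} in column_map")
            cmap[key] = col

    df = pd.read_csv(path, sep=_detect_sep(path))
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    for key in _REQUIRED:
        if cmap[key] not in df.columns:
            raise ConfigError(f"mapped column {cmap[key]!r} (for {key!r}) not found in {path}")

    have_p = cmap["p"] in df.columns
    have_eaf = cmap["eaf"] in df.columns
    have_n = cmap["n"] in df.columns
    have_nc = cmap["n_cases"] in df.columns

    out: list[VariantAssociation] = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        getv = lambda key: row[cmap[key]]
        beta = float(getv("beta"))
        se = float(getv("se"))
        if have_p and pd.notna(getv("p")):
            pvalue = float(getv("p"))
        elif se > 0:
            pvalue = normal_p_from_z(beta / se)
        else:
            pvalue = float("nan")
        eaf = float(getv("eaf")) if have_eaf and pd.notna(getv("eaf")) else None
        rec = VariantAssociation(
            variant_id=str(getv("variant_id")),
            chromosome=str(getv("chr")),
            position=int(getv("pos")),
            effect_allele=str(getv("ea")).upper(),
            other_allele=str(getv("oa")).upper(),
            beta=beta,
            se=se,
            pvalue=pvalue,
            eaf=eaf,
            n=float(getv("n")) if have_n and pd.notna(getv("n")) else None,
            n_cases=float(getv("n_cases")) if have_nc and pd.notna(getv("n_cases")) else None,
            trait_id=trait_id,
            trait_type=trait_type,
        )
        reason = _validate_record(rec)
        if reason is not None:
            logger.info("dropping %s: %s", rec.variant_id, reason)
            if drop_log is not None:
                drop_log.append((rec.variant_id, reason))
            continue
        if have_p and pd.notna(row[cmap["p"]]):
            _warn_p_inconsistency(rec)
        out.append(rec)
    return out


def to_dataframe(assocs: list[VariantAssociation]) -> pd.DataFrame:
    """Serialize association records to the canonical column layout."""
    return pd.DataFrame(
        {
            "variant_id": [a.variant_id for a in assocs],
            "chr": [a.chromosome for a in assocs],
            "pos": [a.position for a in assocs],
            "ea": [a.effect_allele for a in assocs],
            "oa": [a.other_allele for a in assocs],
            "eaf": [a.eaf for a in assocs],
            "beta": [a.beta for a in assocs],
            "se": [a.se for a in assocs],
            "p": [a.pvalue for a in assocs],
            "n": [a.n for a in assocs],
        }
    )


def write_sumstats(assocs: list[VariantAssociation], path) -> None:
    to_dataframe(assocs).to_csv(path, sep="\t", index=False)


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, signed) over an ordered variant list."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise FormatError(f"LD matrix shape {self.r.shape} does not match {m} variant ids")
        self._idx = {v: i for i, v in enumerate(self.variant_ids)}

    def index(self, variant_id: str) -> int:
        try:
            return self._idx[variant_id]
        except KeyError:
            raise MissingLDError(f"variant {variant_id!r} absent from LD matrix") from None

    def r2(self, a: str, b: str) -> float:
        i, j = self.index(a), self.index(b)
        return float(self.r[i, j] ** 2)

    def subset(self, variant_ids: list[str]) -> "LDMatrix":
        idx = [self.index(v) for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.variant_ids


def validate_ld(ld: LDMatrix, psd_tol: float = 1e-8) -> None:
    r = ld.r
    if not np.allclose(r, r.T, atol=1e-6):
        raise FormatError("LD matrix is not symmetric")
    if np.max(np.abs(np.diag(r) - 1.0)) > 1e-6:
        raise FormatError("LD matrix diagonal deviates from 1")
    if np.max(np.abs(r)) > 1.0 + 1e-8:
        raise FormatError("LD correlations outside [-1, 1]")
    w = np.linalg.eigvalsh((r + r.T) / 2.0)
    if w.min() < -psd_tol:
        raise FormatError(f"LD matrix not positive semi-definite (min eigenvalue {w.min():.3g})")


def read_ld_matrix(path) -> LDMatrix:
    """Read a dense LD matrix TSV with variant IDs as header row and first column.

    Asymmetries below 1e-6 are repaired by averaging ``(r + r')/2``; anything
    larger, a non-square layout, or a diagonal off 1 by more than 1e-6 is a
    format error.
    """
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: LD matrix is not square ({df.shape[0]}x{df.shape[1]})")
    ids_row = [str(c) for c in df.columns]
    ids_col = [str(i) for i in df.index]
    if ids_row != ids_col:
        raise FormatError(f"{path}: header row and first column variant IDs differ")
    r = df.to_numpy(dtype=float)
    asym = np.max(np.abs(r - r.T)) if r.size else 0.0
    if asym >= 1e-6:
        raise FormatError(f"{path}: LD matrix asymmetry {asym:.3g} exceeds 1e-6")
    r = (r + r.T) / 2.0
    ld = LDMatrix(ids_row, r)
    validate_ld(ld)
    return ld


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")


@dataclass(frozen=True)
class HarmonizedRecord:
    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf: float | None = None


@dataclass
class HarmonizedDataset:
    """Allele-aligned exposure/outcome effect pairs for one cytokine-cancer analysis."""

    exposure_id: str
    outcome_id: str
    records: list[HarmonizedRecord]
    ld: LDMatrix | None = None
    provenance_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.records)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        bx = np.array([r.beta_x for r in self.records])
        sx = np.array([r.se_x for r in self.records])
        by = np.array([r.beta_y for r in self.records])
        sy = np.array([r.se_y for r in self.records])
        return bx, sx, by, sy

    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def subset(self, keep: list[bool]) -> "HarmonizedDataset":
        recs = [r for r, k in zip(self.records, keep) if k]
        ld = self.ld.subset([r.variant_id for r in recs]) if self.ld is not None else None
        return HarmonizedDataset(self.exposure_id, self.outcome_id, recs, ld,
                                 list(self.provenance_log))


def harmonize_pair(
    exposure: list[VariantAssociation],
    outcome: list[VariantAssociation],
    palindrome_eaf_limit: float = 0.42,
    ld: LDMatrix | None = None,
) -> HarmonizedDataset:
    """Align outcome effect estimates to the exposure effect allele.

    For each variant shared between the two lists:

    * same allele pair, same orientation: kept as is;
    * same pair, swapped orientation: the outcome beta sign is flipped (and its
      EAF replaced by 1-EAF internally);
    * palindromic pair (A/T or C/G): kept only when both EAFs are present and
      both minor-allele frequencies are below ``palindrome_eaf_limit``, aligned
      by frequency (flip when the EAFs sit on opposite sides of 0.5); otherwise
      dropped as an ambiguous palindrome;
    * any other allele pair: dropped as a mismatch.

    Every action is recorded in ``provenance_log``.
    """
    if not exposure or not outcome:
        raise EmptyInputError("harmonize_pair requires non-empty exposure and outcome lists")
    exp_by_id = {a.variant_id: a for a in exposure}
    out_by_id = {a.variant_id: a for a in outcome}
    shared = [a.variant_id for a in exposure if a.variant_id in out_by_id]
    exposure_id = exposure[0].trait_id
    outcome_id = outcome[0].trait_id
    if not shared:
        raise EmptyOverlapError(
            f"no shared variants between {exposure_id!r} and {outcome_id!r}"
        )

    records: list[HarmonizedRecord] = []
    log: list[tuple[str, str]] = []
    for vid in shared:
        ex, oc = exp_by_id[vid], out_by_id[vid]
        if ex.is_palindromic() and oc.is_palindromic():
            if ex.eaf is None or oc.eaf is None:
                log.append((vid, "dropped: ambiguous palindrome (missing EAF)"))
                continue
            if min(ex.eaf, 1 - ex.eaf) >= palindrome_eaf_limit or \
               min(oc.eaf, 1 - oc.eaf) >= palindrome_eaf_limit:
                log.append((vid, "dropped: ambiguous palindrome"))
                continue
            same_side = (ex.eaf < 0.5) == (oc.eaf < 0.5)
            if same_side:
                log.append((vid, "kept: palindrome aligned by frequency"))
                records.append(HarmonizedRecord(vid, ex.beta, ex.se, oc.beta, oc.se, ex.eaf))
            else:
                log.append((vid, "flipped: palindrome aligned by frequency"))
                records.append(HarmonizedRecord(vid, ex.beta, ex.se, -oc.beta, oc.se, ex.eaf))
            continue
        if (ex.effect_allele, ex.other_allele) == (oc.effect_allele, oc.other_allele):
            log.append((vid, "kept: alleles aligned"))
            records.append(HarmonizedRecord(vid, ex.beta, ex.se, oc.beta, oc.se, ex.eaf))
        elif (ex.effect_allele, ex.other_allele) == (oc.other_allele, oc.effect_allele):
            log.append((vid, "flipped: swapped allele orientation"))
            records.append(HarmonizedRecord(vid, ex.beta, ex.se, -oc.beta, oc.se, ex.eaf))
        else:
            log.append((vid, "dropped: allele mismatch"))

    sub_ld = None
    if ld is not None and records:
        sub_ld = ld.subset([r.variant_id for r in records])
    return HarmonizedDataset(exposure_id, outcome_id, records, sub_ld, log)
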