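"""Cis windows, LD clumping, instrument filters and strength diagnostics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_assoc
from cytomr.errors import DomainError, MissingLDError
from cytomr.instruments import (
    GeneRegion,
    PowerConfig,
    clump,
    define_cis_window,
    f_statistic,
    power_binary_outcome,
    select_eqtl_instruments,
    select_pqtl_instruments,
    trans_exclusion_filter,
    variant_r2,
)
from cytomr.simulate import simulate_ld
from cytomr.sumstats import LDMatrix


class TestCisWindow:
    def test_mif_gene_window_with_default_flank(self):
        region = GeneRegion("MIF", "MIF", "ENSG00000240972", "22", 24_236_565, 24_237_409)
        assert define_cis_window(region) == ("22", 23_736_565, 24_737_409)

    def test_zero_flank_returns_gene_body(self, region):
        assert define_cis_window(region, flank=0) == ("1", region.start, region.end)

    def test_window_clamped_at_position_one(self):
        region = GeneRegion("X", "G", "E", "1", 100, 200)
        assert define_cis_window(region, flank=500_000) == ("1", 1, 500_200)


def _ld(ids, r2_pairs):
    """Build an LD matrix from a dict of {(i, j): r2} (r = sqrt(r2))."""
    m = len(ids)
    r = np.eye(m)
    for (i, j), r2 in r2_pairs.items():
        r[i, j] = r[j, i] = math.sqrt(r2)
    return LDMatrix(list(ids), r)


class TestClump:
    def test_mutually_independent_snps_all_retained(self):
        assocs = [make_assoc(variant_id=f"rs{i}", position=100 * i, pvalue=1e-5)
                  for i in range(3)]
        ld = _ld([f"rs{i}" for i in range(3)], {})
        assert len(clump(assocs, ld)) == 3

    def test_correlated_weaker_snp_pruned(self):
        a = make_assoc(variant_id="A", position=1, pvalue=1e-6)
        b = make_assoc(variant_id="B", position=2, pvalue=1e-5)
        c = make_assoc(variant_id="C", position=3, pvalue=1e-4)
        ld = _ld(["A", "B", "C"], {(0, 1): 0.5})
        kept = clump([c, b, a], ld, r2_max=0.1)
        assert [v.variant_id for v in kept] == ["A", "C"]

    def test_greedy_matches_exhaustive_oracle(self, rng):
        # oracle: among all subsets satisfying the pairwise constraint that
        # can be produced greedily, the greedy result takes lowest p first
        ids = [f"rs{i}" for i in range(6)]
        assocs = [make_assoc(variant_id=v, position=i, pvalue=float(p))
                  for i, (v, p) in enumerate(zip(ids, rng.uniform(size=6)))]
        r = simulate_ld(6, 0.6).r
        ld = LDMatrix(ids, r)
        kept = clump(assocs, ld, r2_max=0.1)
        # re-derive greedily with an independent direct implementation
        expected = []
        for a in sorted(assocs, key=lambda a: a.pvalue):
            if all(r[ids.index(a.variant_id), ids.index(b.variant_id)] ** 2 < 0.1
                   for b in expected):
                expected.append(a)
        assert [v.variant_id for v in kept] == [v.variant_id for v in expected]
        # every retained pair satisfies the constraint
        for x, y in itertools.combinations(kept, 2):
            assert ld.r2(x.variant_id, y.variant_id) < 0.1
        # the globally smallest p always survives
        assert min(assocs, key=lambda a: a.pvalue).variant_id in [v.variant_id for v in kept]

    def test_vacuous_threshold_retains_everything(self):
        assocs = [make_assoc(variant_id=f"rs{i}", position=i) for i in range(4)]
        ld = LDMatrix([f"rs{i}" for i in range(4)], np.full((4, 4), 0.99) + 0.01 * np.eye(4))
        assert len(clump(assocs, ld, r2_max=1.01)) == 4

    def test_missing_variant_raises_named_error(self):
        assocs = [make_assoc(variant_id="rsX")]
        ld = _ld(["rsY"], {})
        with pytest.raises(MissingLDError, match="rsX"):
            clump(assocs, ld)

    def test_deterministic_under_input_permutation(self, rng):
        ids = [f"rs{i}" for i in range(8)]
        assocs = [make_assoc(variant_id=v, position=i, pvalue=float(p))
                  for i, (v, p) in enumerate(zip(ids, rng.uniform(size=8)))]
        ld = LDMatrix(ids, simulate_ld(8, 0.5).r)
        ref = [v.variant_id for v in clump(assocs, ld)]
        perm = [assocs[i] for i in rng.permutation(8)]
        assert [v.variant_id for v in clump(perm, ld)] == ref


class TestDiagnostics:
    def test_variant_r2_values_and_flip_invariance(self):
        assert variant_r2(0.0, 0.3) == 0.0
        assert variant_r2(0.1, 0.5) == pytest.approx(0.005)
        assert variant_r2(0.1, 0.2) == pytest.approx(variant_r2(-0.1, 0.8))
        with pytest.raises(DomainError):
            variant_r2(0.1, 1.0)

    def test_f_statistic_values_and_monotonicity(self):
        assert f_statistic(0.0, 100) == 0.0
        assert f_statistic(0.01, 10_000) == pytest.approx(0.01 * 9998 / 0.99)
        assert f_statistic(0.02, 1000) > f_statistic(0.01, 1000)
        assert f_statistic(0.01, 2000) > f_statistic(0.01, 1000)
        with pytest.raises(DomainError):
            f_statistic(1.0, 100)

    def test_power_null_information_limit_is_half_alpha(self):
        cfg = PowerConfig(n=100_000, case_fraction=0.5)
        assert power_binary_outcome(cfg, 0.0) == pytest.approx(0.025, rel=1e-3)

    def test_power_closed_form_against_independent_normal_cdf(self):
        cfg = PowerConfig(n=100_000, case_fraction=0.5, or_alt=1.2, alpha=0.05)
        got = power_binary_outcome(cfg, 0.01)
        ncp = math.sqrt(100_000 * 0.01 * 0.25) * abs(math.log(1.2))
        z975 = 1.959963984540054
        expected = 0.5 * math.erfc(-(ncp - z975) / math.sqrt(2.0))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_power_nondecreasing_in_r2(self):
        cfg = PowerConfig(n=50_000, case_fraction=0.3)
        powers = [power_binary_outcome(cfg, r2) for r2 in (0, 0.005, 0.01, 0.05)]
        assert powers == sorted(powers)


class TestSelectPqtl:
    def _region(self):
        return GeneRegion("CYT", "G", "E", "1", 1_000_000, 1_001_000)

    def _fixture(self):
        region = self._region()
        inside = region.start + 10
        assocs = [
            make_assoc(variant_id=f"rs{i}", position=inside + i, pvalue=1e-6, eaf=0.3)
            for i in range(5)
        ]
        assocs.append(make_assoc(variant_id="rs_lowmaf", position=inside + 99,
                                 pvalue=1e-8, eaf=0.97))
        assocs.append(make_assoc(variant_id="rs_weak", position=inside + 50,
                                 pvalue=1e-3, eaf=0.3))
        assocs.append(make_assoc(variant_id="rs_far", position=region.end + 10**7,
                                 pvalue=1e-9, eaf=0.3))
        assocs.append(make_assoc(variant_id="rs_noeaf", position=inside + 77,
                                 pvalue=1e-9, eaf=None))
        ld = _ld([a.variant_id for a in assocs], {})
        return assocs, region, ld

    def test_filters_and_diagnostics(self):
        assocs, region, ld = self._fixture()
        inst = select_pqtl_instruments(assocs, region, ld)
        kept = {v.variant_id for v in inst.variants}
        assert kept == {f"rs{i}" for i in range(5)}
        assert inst.total_r2 == pytest.approx(sum(inst.per_variant_r2))
        assert inst.mean_F == pytest.approx(np.mean(inst.per_variant_F))
        reasons = dict(inst.selection_log)
        assert "MAF" in reasons["rs_lowmaf"]
        assert "outside cis window" in reasons["rs_far"]
        assert "missing EAF" in reasons["rs_noeaf"]
        assert "p " in reasons["rs_weak"]

    def test_emitted_variants_satisfy_all_filters_post_hoc(self):
        assocs, region, ld = self._fixture()
        inst = select_pqtl_instruments(assocs, region, ld, p_max=1e-4, maf_min=0.05)
        chrom, lo, hi = define_cis_window(region)
        for v in inst.variants:
            assert v.chromosome == chrom and lo <= v.position <= hi
            assert v.maf >= 0.05
            assert v.pvalue < 1e-4

    def test_empty_selection_is_valid(self):
        assocs, region, ld = self._fixture()
        inst = select_pqtl_instruments(assocs, region, ld, p_max=1e-20)
        assert inst.n_variants == 0 and inst.total_r2 == 0.0

    def test_total_r2_nondecreasing_when_clump_relaxed(self, rng):
        ids = [f"rs{i}" for i in range(10)]
        region = self._region()
        assocs = [make_assoc(variant_id=v, position=region.start + i,
                             pvalue=float(p), eaf=0.3, beta=0.15)
                  for i, (v, p) in enumerate(zip(ids, rng.uniform(1e-8, 1e-5, size=10)))]
        ld = LDMatrix(ids, simulate_ld(10, 0.7).r)
        strict = select_pqtl_instruments(assocs, region, ld, r2_max=0.05)
        loose = select_pqtl_instruments(assocs, region, ld, r2_max=0.5)
        assert loose.total_r2 >= strict.total_r2 - 1e-12


class TestSelectEqtl:
    def test_dual_condition_rule(self):
        region = GeneRegion("CYT", "G", "E", "1", 1_000_000, 1_001_000)
        pos = region.start + 1
        cyto = [make_assoc(variant_id="rs1", position=pos, pvalue=0.2, eaf=0.3),
                make_assoc(variant_id="rs2", position=pos + 1, pvalue=0.01, eaf=0.3,
                           beta=0.25)]
        expr = [make_assoc(variant_id="rs1", position=pos, pvalue=1e-6),
                make_assoc(variant_id="rs2", position=pos + 1, pvalue=1e-6)]
        ld = _ld(["rs1", "rs2"], {})
        inst = select_eqtl_instruments(expr, cyto, region, ld)
        assert [v.variant_id for v in inst.variants] == ["rs2"]
        # betas are the cytokine, not expression, estimates
        assert inst.variants[0].beta == 0.25
        assert inst.definition == "cis_eQTL"


class TestTransExclusion:
    def _inst(self):
        region = GeneRegion("CYT", "G", "E", "1", 1_000_000, 1_001_000)
        assocs = [make_assoc(variant_id=f"rs{i}", position=region.start + i,
                             pvalue=1e-6, eaf=0.3) for i in range(3)]
        ld = _ld([a.variant_id for a in assocs], {})
        return select_pqtl_instruments(assocs, region, ld)

    def test_no_cross_associations_leaves_set_unchanged(self):
        inst = self._inst()
        table = pd.DataFrame({"variant_id": [], "other_trait_id": [], "pvalue": []})
        out = trans_exclusion_filter(inst, table)
        assert [v.variant_id for v in out.variants] == [v.variant_id for v in inst.variants]

    def test_trans_associated_variant_removed_and_idempotent(self):
        inst = self._inst()
        table = pd.DataFrame({"variant_id": ["rs1"], "other_trait_id": ["OTHER"],
                              "pvalue": [1e-9]})
        out = trans_exclusion_filter(inst, table)
        assert "rs1" not in [v.variant_id for v in out.variants]
        again = trans_exclusion_filter(out, table)
        assert [v.variant_id for v in again.variants] == [v.variant_id for v in out.variants]
        # diagnostics recomputed for the smaller set
        assert len(out.per_variant_r2) == out.n_variants
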