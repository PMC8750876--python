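import numpy as np
import pytest

from cytomr.instruments import GeneRegion
from cytomr.sumstats import HarmonizedDataset, HarmonizedRecord, VariantAssociation


def make_assoc(
    variant_id="rs1",
    chromosome="1",
    position=1_000_000,
    ea="A",
    oa="G",
    beta=0.1,
    se=0.02,
    pvalue=None,
    eaf=0.3,
    n=10_000.0,
    trait_id="trait",
    trait_type="quantitative",
):
    from cytomr.sumstats import normal_p_from_z

    if pvalue is None:
        pvalue = normal_p_from_z(beta / se)
    return VariantAssociation(
        variant_id=variant_id,
        chromosome=chromosome,
        position=position,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        pvalue=pvalue,
        eaf=eaf,
        n=n,
        trait_id=trait_id,
        trait_type=trait_type,
    )


def make_hd(bx, by, se_x=0.02, se_y=0.03, exposure_id="exp", outcome_id="out", ld=None):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    recs = [
        HarmonizedRecord(f"rs{i + 1}", float(bx[i]), se_x, float(by[i]), se_y, 0.3)
        for i in range(len(bx))
    ]
    return HarmonizedDataset(exposure_id, outcome_id, recs, ld)


@pytest.fixture
def region():
    return GeneRegion("CYT", "GENE", "ENSG00000000001", "1", 1_000_000, 1_040_000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
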