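import numpy as np
import pytest

from drugtarget_mr.sumstats import VariantAssociation
from drugtarget_mr.mr import HarmonizedInstrument


def make_assoc(**kwargs) -> VariantAssociation:
    """A valid association record with overridable fields."""
    defaults = dict(
        variant_id="rs1",
        chrom="1",
        pos=1_000_000,
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        beta=0.1,
        se=0.01,
        pval=1e-10,
        n=30_000.0,
    )
    defaults.update(kwargs)
    return VariantAssociation(**defaults)


def make_inst(**kwargs) -> HarmonizedInstrument:
    defaults = dict(
        variant_id="rs1",
        beta_exp=0.1,
        se_exp=0.01,
        beta_out=0.05,
        se_out=0.01,
        eaf_exp=0.3,
        eaf_out=0.3,
        n_exp=30_000.0,
        n_out=100_000.0,
    )
    defaults.update(kwargs)
    return HarmonizedInstrument(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
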