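import numpy as np
import pandas as pd
import pytest

from csfmr.gwas_io import SUMSTATS_COLUMNS, SummaryStats
from csfmr.harmonize import HarmonizedPair


@pytest.fixture
def make_pair():
    """Factory for harmonized pairs with sensible defaults."""

    def _make(beta_exp=0.5, se_exp=0.05, beta_out=0.1, se_out=0.02,
              variant_id="rs1", **kw):
        return HarmonizedPair(
            variant_id=variant_id, effect_allele="A", other_allele="G",
            beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out,
            **kw)

    return _make


@pytest.fixture
def make_sumstats():
    """Factory for in-memory SummaryStats from compact row tuples."""

    def _make(rows, trait_id="trait"):
        # rows: (variant_id, chrom, pos, ea, oa, eaf, beta, se, p, n)
        table = pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)
        table["pos"] = table["pos"].astype("Int64")
        return SummaryStats(trait_id=trait_id, table=table)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240104)
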