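import numpy as np
import pytest
from hypothesis import settings

from mrkit.summary_io import HarmonizedSet, SummaryStatRecord

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-9, n=1000, eaf=0.3):
    return SummaryStatRecord(snp_id, ea, oa, beta, se, pval, n, eaf=eaf)


def make_harmonized(beta_exp, se_exp, beta_out, se_out, ids=None):
    beta_exp = np.asarray(beta_exp, float)
    J = len(beta_exp)
    return HarmonizedSet(
        snp_ids=ids or [f"rs{j + 1}" for j in range(J)],
        beta_exposure=beta_exp,
        se_exposure=np.broadcast_to(np.asarray(se_exp, float), (J,)).copy(),
        beta_outcome=np.asarray(beta_out, float),
        se_outcome=np.broadcast_to(np.asarray(se_out, float), (J,)).copy(),
        effect_alleles=["A"] * J,
        other_alleles=["G"] * J,
    )


@pytest.fixture
def harmonized_factory():
    return make_harmonized


@pytest.fixture
def record_factory():
    return make_record
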