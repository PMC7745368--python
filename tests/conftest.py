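import numpy as np
import pytest

from chbgrs.cohort_model import GenotypeCounts
from chbgrs.synthetic_data import PUBLISHED_COUNTS, published_counts_fixture

#: Published two-decimal allele-test odds ratios, in locus order.
PRINTED_ORS = {
    "rs12614": 0.44, "rs9277535": 0.49, "rs3077": 0.48, "rs2856718": 1.72,
    "rs7453920": 0.49, "rs1419881": 0.74, "rs652888": 1.65, "rs1265163": 1.32,
    "rs35875104": 0.53, "rs9394021": 0.73, "rs2517459": 0.53,
}

#: Published 95% CIs (two-decimal display bounds).
PRINTED_CIS = {
    "rs12614": (0.33, 0.57), "rs9277535": (0.43, 0.56), "rs3077": (0.41, 0.55),
    "rs2856718": (1.50, 1.97), "rs7453920": (0.41, 0.60), "rs1419881": (0.64, 0.85),
    "rs652888": (1.37, 1.99), "rs1265163": (1.14, 1.53), "rs35875104": (0.39, 0.71),
    "rs9394021": (0.64, 0.84), "rs2517459": (0.43, 0.67),
}


@pytest.fixture(scope="session")
def fixture_cohort():
    return published_counts_fixture()


def counts_pair(snp_id: str) -> tuple[GenotypeCounts, GenotypeCounts]:
    _, _, _, case, ctrl = PUBLISHED_COUNTS[snp_id]
    return GenotypeCounts(*case), GenotypeCounts(*ctrl)


@pytest.fixture
def rng():
    return np.random.default_rng(20201217)
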