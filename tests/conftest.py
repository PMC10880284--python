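import numpy as np
import pytest

from mendelscan import SimConfig, simulate_cohort
from mendelscan.io_formats import SummaryStatRecord, SummaryStatsTable
from mendelscan.synthetic import instrument_exposure_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_individuals=4000, n_phecodes=12, n_null_phecodes=10)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def exposure_table(small_config):
    return instrument_exposure_table(small_config)


def make_record(vid="rs1", ea="T", oa="C", beta=0.1, se=0.02, eaf=0.3, **kw):
    return SummaryStatRecord(
        variant_id=vid, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, eaf=eaf, **kw,
    )


def make_table(records, trait_id="trait", **kw):
    return SummaryStatsTable(trait_id=trait_id, records=records, **kw)
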