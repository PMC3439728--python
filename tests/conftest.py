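import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import setopics as st

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(drug_id, indications=(), bw=False, atc=None, sections=None, date=None):
    return st.DrugRecord(
        drug_id=drug_id,
        sections=sections or {},
        has_boxed_warning=bw,
        indications=frozenset(indications),
        atc_level1=atc,
        effective_date=date,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A small synthetic corpus shared by read-only tests."""
    config = st.GeneratorConfig(
        n_drugs=40, vocab_size=30, n_topics=3, n_atc=3, seed=42
    )
    records, matrix, truth = st.generate_corpus(config)
    return config, records, matrix, truth


@pytest.fixture(scope="session")
def small_fit(small_corpus):
    """A quick LDA fit on the small corpus (also warms the numba kernels)."""
    _, _, matrix, _ = small_corpus
    config = st.LdaConfig(
        n_topics=3, alpha=1.0, beta=0.5, n_iterations=120, burn_in=60,
        sample_lag=10, seed=9,
    )
    return st.fit(matrix, config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
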