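import numpy as np
import pytest

from flcdna.synthetic_data import SynthConfig, simulate


def hits_by_query(sim):
    out = {}
    for h in sim.hits:
        out.setdefault(h.query_id, []).append(h)
    return out


@pytest.fixture(scope="session")
def clean_sim():
    """Defect-free two-species set: every transcript is truly full-length."""
    cfg = SynthConfig(
        seed=5,
        n_transcripts=120,
        n_shared_identities=40,
        n_allele_triples=3,
        n_paralog_triples=3,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def defect_sim():
    """Set with every defect class planted among species-specific transcripts."""
    cfg = SynthConfig(
        seed=11,
        n_transcripts=100,
        n_shared_identities=20,
        defect_rates={
            "missing_polya": 0.08,
            "missing_stop": 0.08,
            "internal_polya": 0.08,
            "no_hit": 0.08,
            "missing_start": 0.08,
        },
        n_allele_triples=0,
        n_paralog_triples=0,
    )
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
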