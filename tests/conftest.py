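import numpy as np
import pytest

from amplimeth import (AlleleSpec, ChemistryParams, synthetic_panel,
                       simulate_sample)
from amplimeth.pipeline import run_pipeline


@pytest.fixture(scope="session")
def panel():
    """Three-amplicon synthetic panel: ICR with one A/C SNP + both controls."""
    return synthetic_panel(0)


@pytest.fixture(scope="session")
def icr(panel):
    return panel["icr1"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def perfect_chem():
    """Error-free chemistry: every call must match truth exactly."""
    return ChemistryParams(conversion_rate=1.0, inappropriate_conversion=0.0,
                           seq_error_rate=0.0, mean_pcr_copies=1.0)


@pytest.fixture(scope="session")
def imprint_spec():
    return AlleleSpec(maternal_meth_p=0.98, paternal_meth_p=0.02,
                      maternal_fraction=0.5)


@pytest.fixture(scope="session")
def perfect_run(panel, perfect_chem, imprint_spec):
    """Zero-error imprint simulation over the ICR plus its pipeline result."""
    amp = panel["icr1"]
    pairs, molecules = simulate_sample([amp], {"icr1": imprint_spec}, 400,
                                       perfect_chem, seed=7)
    result = run_pipeline(pairs, panel)
    return pairs, molecules, result


def molecule_id_of(read_id: str) -> str:
    """Recover the truth molecule id from a simulated, UMI-tagged read id."""
    return ":".join(read_id.split(":")[1:3])
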