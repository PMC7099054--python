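import pytest

from bcrpipe.germline import load_reference
from bcrpipe.pipeline import process_simulation
from bcrpipe.simulate import simulate_donor


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def era_sim_small(reference):
    """One small ERA-preset donor simulation (2,000 IgG reads, seed 11)."""
    return simulate_donor("ERA", seed=11, reference=reference, n_reads=2000)


@pytest.fixture(scope="session")
def era_records_small(reference, era_sim_small):
    """Annotated records for the small ERA donor, full pipeline."""
    records, _ = process_simulation(era_sim_small, reference)
    return records
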