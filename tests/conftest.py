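import numpy as np
import pytest

from afdip.io_quant import PeptideRecord, SampleDesign, time_course_design
from afdip.simulate import toy_structure


@pytest.fixture
def design16() -> SampleDesign:
    """2 conditions x 8 hourly time points, single replicate (one TMT set)."""
    return time_course_design(range(1, 9), n_replicates=1)


@pytest.fixture
def design48() -> SampleDesign:
    """2 conditions x 8 time points x 3 replicates."""
    return time_course_design(range(1, 9), n_replicates=3)


@pytest.fixture
def full_record(design16) -> PeptideRecord:
    """A peptide observed in every channel of the 16-channel design."""
    rng = np.random.default_rng(7)
    return PeptideRecord(
        "ELVISLIVESK",
        ("P12345",),
        {c: float(v) for c, v in zip(design16.channels, rng.uniform(10, 100, 16))},
    )


@pytest.fixture(scope="session")
def toy_pdb_text() -> str:
    return toy_structure()
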