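import numpy as np
import pytest

from spacerhost.evalue import calibrate
from spacerhost.glocal import AlignmentParams

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@pytest.fixture(scope="session")
def params() -> AlignmentParams:
    return AlignmentParams()


@pytest.fixture(scope="session")
def spacer_model():
    """E-value model covering the 35-37 nt spacer lengths (session-wide)."""
    return calibrate([35, 36, 37], calib_db_nt=150_000, n_replicates=80,
                     seed=101)
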