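import numpy as np
import pytest

from phenoscreen import Fingerprint, ScreenRecord, TrainingSet, scenario_paper_like


def record(
    cid: str, bits, rfp: float, egfp: float, nbits: int = 8
) -> ScreenRecord:
    """Build a ScreenRecord from explicit fingerprint bits (test helper)."""
    return ScreenRecord(
        id=cid,
        fingerprint=Fingerprint(nbits=nbits, bits=frozenset(bits), radius=0),
        rfp=rfp,
        egfp=egfp,
    )


def random_records(rng: np.random.Generator, n: int, nbits: int) -> list[ScreenRecord]:
    """Random small dataset for oracle-equivalence checks."""
    out = []
    for i in range(n):
        bits = frozenset(int(b) for b in np.flatnonzero(rng.integers(0, 2, nbits)))
        out.append(
            ScreenRecord(
                id=f"r{i}",
                fingerprint=Fingerprint(nbits=nbits, bits=bits, radius=0),
                rfp=float(rng.uniform(0, 2)),
                egfp=float(rng.uniform(0, 2)),
            )
        )
    return out


@pytest.fixture(scope="session")
def small_scenario():
    """A compact synthetic screen shared across tests (80 compounds)."""
    return scenario_paper_like(seed=7, n=80, nbits=256)
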