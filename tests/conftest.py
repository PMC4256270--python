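import numpy as np
import pytest

from mtssb.genome import CircularGenome, rcrs_geometry
from mtssb.synthetic import SimulationSpec, random_genome


@pytest.fixture(scope="session")
def toy_genome() -> CircularGenome:
    """100 nt circle with OriL half a circle from OriH, random sequence."""
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    return CircularGenome(length=100, ori_h=0, ori_l=50, sequence=seq, name="toy")


@pytest.fixture(scope="session")
def rcrs_genome() -> CircularGenome:
    """Standard mtDNA geometry without sequence (exposure work only)."""
    return rcrs_geometry()


@pytest.fixture(scope="session")
def rcrs_genome_seq() -> CircularGenome:
    """Standard geometry with a reproducible random sequence (mapping work)."""
    return random_genome(SimulationSpec(seed=20141204))
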