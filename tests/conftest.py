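import logging

import pytest

from pseudoscan.config import RunConfig
from pseudoscan.synth import make_standard_case

logging.getLogger("pseudoscan").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def standard_case():
    """One gene with the eight canonical single-lesion targets (seed 11)."""
    return make_standard_case(seed=11)


@pytest.fixture(scope="session")
def warm_aligner():
    """Trigger the numba JIT once so timing-sensitive tests are not skewed."""
    from pseudoscan.align import DEFAULT_SCHEMES, align_exon

    align_exon("ACGT", "TTACGTTT", DEFAULT_SCHEMES[0])
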