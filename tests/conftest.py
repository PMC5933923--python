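import pytest

from perinuc.chipseq import SpikeNormConfig
from perinuc.genome import GenomicInterval
from perinuc.synthetic import default_toy_genome


@pytest.fixture(scope="session")
def toy_genome():
    return default_toy_genome()


@pytest.fixture(scope="session")
def toy_spike_cfg():
    """Spike/reference intervals matching the toy genome's spike locus.

    Mirrors the published layout: the euchromatic reference interval
    encloses the spike locus.
    """
    return SpikeNormConfig(
        spike_interval=GenomicInterval("chrIII", 30_000, 32_000),
        reference_interval=GenomicInterval("chrIII", 20_000, 58_000),
    )
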