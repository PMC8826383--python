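import numpy as np
import pytest

from methcall.features import ErrorRecord, RawReadEvents
from methcall.nn.model import ConvSpec, ModelSpec
from methcall.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_spec():
    """A scaled-down architecture for fast structural tests."""
    return ModelSpec(
        mode="joint",
        sequence_conv=ConvSpec(2, 8, 4),
        error_conv=ConvSpec(2, 8, 3),
        error_local=ConvSpec(2, 8, 3),
        head_units=16,
    )


@pytest.fixture(scope="session")
def small_separable_windows():
    """600 simulated windows with a strong methylation signal shift."""
    cfg = SimulationConfig(
        n_reads=600, signal_shift=2.0, error_rate_unmeth=0.05,
        error_rate_meth=0.20, seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def clean_read():
    """A 30-base read with one CpG in the middle and clean error records."""
    rng = np.random.default_rng(0)
    seq = "ATTAGTAACCTTAACGTTAAGGTTAATTGA"  # single CG at index 14
    positions = list(range(100, 100 + len(seq)))
    events = RawReadEvents(
        read_id="readA",
        chrom="chr1",
        strand="+",
        positions=positions,
        bases=list(seq),
        samples_per_base=[rng.normal(90, 5, size=6) for _ in seq],
    )
    errors = [
        ErrorRecord("readA", p, "match", 30.0, b) for p, b in zip(positions, seq)
    ]
    return events, errors
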