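import pytest

from memtop import synthetic_data as sd


@pytest.fixture(scope="session")
def gpcr_spec():
    """7-TM receptor-like synthetic protein with two extracellular disulfides."""
    return sd.make_protein(7, helix_len=24, loop_len=14, n_disulfides=2, seed=1)


@pytest.fixture(scope="session")
def channel_spec():
    """11-TM channel-like homotrimer, no disulfides."""
    return sd.make_protein(
        11, helix_len=24, loop_len=12, n_disulfides=0, seed=3, oligomer_count=3
    )


@pytest.fixture(scope="session")
def channel_monomer(channel_spec):
    from memtop.masses_ions import ProteinSpec

    return ProteinSpec(
        id="monomer",
        sequence=channel_spec.sequence,
        oligomer_count=1,
        topology=channel_spec.topology,
        disulfides=channel_spec.disulfides,
        helix_stability=channel_spec.helix_stability,
    )


@pytest.fixture
def default_cfg():
    return sd.SimConfig(seed=0)


@pytest.fixture
def noiseless_cfg():
    return sd.SimConfig(seed=0).noiseless()
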