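import pytest

import amplimine as am


@pytest.fixture(scope="session")
def panel():
    """The packaged 15-pair reference panel, keyed by name."""
    return {p.name: p for p in am.load_reference_panel()}


@pytest.fixture(scope="session")
def mollcoi253(panel):
    return panel["MollCOI253"]


@pytest.fixture
def small_sim_cfg():
    """Ten target species across three classes plus decoys, clean flanks."""
    return am.SimulationConfig(
        seed=20240531,
        classes={"Bivalvia": 6, "Gastropoda": 3, "Cephalopoda": 1},
        n_decoys=5,
        theta_flank=0.0,
    )


def perfect_template(pair, core_len):
    """Template that the pair amplifies with zero mismatches."""
    return am.SequenceRecord(
        f"perfect_{pair.name}",
        pair.forward.seq + "A" * core_len + am.reverse_complement(pair.reverse.seq),
    )
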