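import pytest

from fluorplate import protocol, simulate


@pytest.fixture(scope="session")
def fig5():
    return protocol.preset_protocol("fig5_steps")


@pytest.fixture(scope="session")
def dark_only():
    return protocol.LightProtocol(
        name="dark_only",
        phases=(protocol.ProtocolPhase("dark_adapt", 0.0, 3600.0, 0.0, "dark"),),
    )


@pytest.fixture(scope="session")
def noiseless_plate(fig5):
    """25-section noiseless render of the three-step protocol."""
    layout = simulate.grid_layout(5, 5, (200, 200))
    params = simulate.GENOTYPE_PRESETS["paragon"]
    stack, truth = simulate.render_plate(layout, params, fig5, seed=11)
    return layout, stack, truth
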