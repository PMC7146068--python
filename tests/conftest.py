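"""Shared fixtures: reduced-density builds reused across test modules."""

import pytest

import cbsim


@pytest.fixture(scope="session")
def base_spec():
    return cbsim.builtin_cerebellar_tile_spec()


@pytest.fixture(scope="session")
def okr_spec():
    return cbsim.builtin_okr_extension_spec()


@pytest.fixture(scope="session")
def small_spec(base_spec):
    """4% density tile: ~33k neurons, builds in well under a second."""
    return cbsim.scale_tile_spec(base_spec, 0.04)


@pytest.fixture(scope="session")
def small_graph(small_spec):
    settings = cbsim.SimulationSettings(duration=1000, seed=7)
    return cbsim.build_network(small_spec, settings)


def isolated_population_graph(name, params, n=2, duration=4000.0, seed=0, drivers=()):
    """A population with no synapses at all, for single-neuron dynamics."""
    spec = cbsim.TileModelSpec(
        layers=[cbsim.LayerSpec("L", 100.0, [cbsim.SheetSpec(name, n, n)])],
        neuron_params={name: params},
        projections=[],
        drivers=list(drivers),
    )
    settings = cbsim.SimulationSettings(duration=duration, seed=seed)
    return cbsim.build_network(spec, settings), settings
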