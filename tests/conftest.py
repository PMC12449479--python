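import numpy as np
import pytest

from tccoupling.membrane import BiophysModel, Passive, build_cell
from tccoupling.morphology import (Compartment, Morphology, MorphologyParams,
                                   attach_axon, generate_pt_morphology)


@pytest.fixture(scope="session")
def morph():
    """Default synthetic PT morphology with axon attached."""
    return attach_axon(generate_pt_morphology(MorphologyParams(seed=3)))


@pytest.fixture(scope="session")
def passive_cell(morph):
    """Fully passive cell on the standard morphology."""
    bio = BiophysModel(channels=(), passive=Passive(g_leak=5e-5, e_leak=-70.0))
    return build_cell(morph, bio)


@pytest.fixture(scope="session")
def small_tree():
    """Hand-built minimal tree: soma, two basals, trunk, two tuft branches."""
    comps = [
        Compartment(0, None, "soma", 20.0, 20.0, 20.0, 0.0),
        Compartment(1, 0, "basal", 150.0, 1.2, 0.6, 150.0),
        Compartment(2, 0, "basal", 100.0, 1.2, 0.6, 100.0),
        Compartment(3, 0, "trunk", 200.0, 4.0, 3.0, 200.0),
        Compartment(4, 3, "tuft", 120.0, 1.5, 0.6, 320.0),
        Compartment(5, 3, "tuft", 100.0, 1.5, 0.6, 300.0),
    ]
    return Morphology(comps, bp_id=3, tuft_tip_distance=320.0)


@pytest.fixture(scope="session")
def reference_cell():
    """Packaged reference cell without synapses (session-cached)."""
    from tccoupling.fixtures import make_reference_cell

    cell, pops = make_reference_cell(seed=0, with_synapses=False)
    return cell


@pytest.fixture(scope="session")
def embedded_reference():
    """Reference cell with synapses plus its population table."""
    from tccoupling.fixtures import make_reference_cell

    return make_reference_cell(seed=0)


class StaticInputs:
    """Minimal trial-inputs stand-in for direct simulator tests."""

    def __init__(self, duration_ms, activations=None, t_onset=None):
        self.duration_ms = duration_ms
        self.activations = activations or {}
        self.t_onset = t_onset


@pytest.fixture
def static_inputs():
    return StaticInputs
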