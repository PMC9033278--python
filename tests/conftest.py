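import numpy as np
import pytest

from statecompare import synthetic as syn


@pytest.fixture(scope="session")
def noiseless_eseem():
    """Noiseless trace with a known planted depth."""
    params = syn.EseemSimParams(depth_k=0.30, noise_sigma=0.0, seed=0)
    return params, syn.simulate_eseem_trace(params, label="X30")


@pytest.fixture(scope="session")
def toy_membrane():
    """Default toy bilayer + cylindrical pore + vertical helix."""
    return syn.build_toy_structure(syn.ToySystemParams(seed=7))


def subset_system(system, keep):
    """Test helper: restrict a MolecularSystem to an atom index subset."""
    from statecompare.mdstruct import MolecularSystem

    keep = np.asarray(keep)
    return MolecularSystem(
        names=system.names[keep], resnames=system.resnames[keep],
        resids=system.resids[keep], segids=system.segids[keep],
        frames=system.frames[:, keep], box=system.box,
        radii=None if system.radii is None else system.radii[keep],
        charges=None if system.charges is None else system.charges[keep],
        sigmas=None if system.sigmas is None else system.sigmas[keep],
        epsilons=None if system.epsilons is None else system.epsilons[keep],
    )
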