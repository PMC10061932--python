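import numpy as np
import pytest

from monofilm.synth import MonolayerSpec, ProteinSpec, generate_monolayer


@pytest.fixture(scope="session")
def small_monolayer():
    """Protein-free 100-lipid monolayer with a 40% condensed plant."""
    spec = MonolayerSpec(n_lipids_per_leaflet=100, f_lc=0.4, seed=1)
    topology, frame, truth = generate_monolayer(spec)
    return spec, topology, frame, truth


@pytest.fixture(scope="session")
def protein_monolayer():
    """300-lipid monolayer with a pseudo-protein and a full condensed halo."""
    spec = MonolayerSpec(
        n_lipids_per_leaflet=300,
        f_lc=0.4,
        seed=3,
        protein=ProteinSpec(radius=1.2, halo_width=1.5, halo_lc_suppression=1.0),
    )
    topology, frame, truth = generate_monolayer(spec)
    return spec, topology, frame, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
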