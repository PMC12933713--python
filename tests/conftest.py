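import numpy as np
import pytest

from surfibs.geodesy import extract_all_patches
from surfibs.model import pack_patches
from surfibs.synthetic import PlantConfig, make_planted_dataset, make_toy_protein


@pytest.fixture(scope="session")
def planted_packed():
    """Planted-IBS study set: 20 bumpy-sphere proteins with the IBS signal on
    hydropathy + shape index, decomposed into geodesic patches and packed for
    the network.  Built once per session (it backs several training tests)."""
    dataset = make_planted_dataset(PlantConfig(n_proteins=20, seed=0))
    packed = []
    for i, p in enumerate(dataset):
        patches = extract_all_patches(p.mesh, p.features, rng_seed=100 + i)
        packed.append(pack_patches(patches, p.protein_id, p.labels.labels, p.group))
    return packed


@pytest.fixture(scope="session")
def helix_protein():
    structure, text = make_toy_protein(n_residues=10, seed=7)
    return structure, text
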