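import numpy as np
import pytest

from parashift.pcs_core import DeltaChiTensor, MetalSite
from parashift.synthetic_data import (
    HelixSpec,
    SimulationSpec,
    default_tensors,
    make_junction,
    plant_pcs,
)


@pytest.fixture(scope="session")
def junction():
    """Two-helix junction at 113° with ground truth, 6 bp per helix."""
    spec = HelixSpec(n_bp=6)
    structure, truth = make_junction([(spec, 0.0, 0.0), (spec, 113.0, 0.0)])
    return structure, truth


@pytest.fixture(scope="session")
def planted(junction):
    """Noiseless four-metal PCS datasets planted on the junction."""
    structure, truth = junction
    tensors, labels = default_tensors()
    site = MetalSite.from_array(truth["junction"])
    sim = SimulationSpec(
        site=site, tensors=tensors, metal_labels=labels,
        noise_sigma=0.0, blind_radius=0.0, missing_fraction=0.0, seed=11,
    )
    datasets = plant_pcs(structure, sim)
    return {
        "structure": structure,
        "truth": truth,
        "tensors": tensors,
        "labels": labels,
        "site": site,
        "datasets": datasets,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_tensor(rng):
    return DeltaChiTensor.from_components(rng.normal(scale=2.0, size=5))
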