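import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark():
    """Default-size synthetic benchmark (200 compounds, 20 templates).

    Session-scoped: template selection and the full profile table are
    computed once and shared by the modeling/validation tests.
    """
    from brs3d.synthetic import generate_benchmark

    return generate_benchmark(seed=7)


@pytest.fixture(scope="session")
def pair_dataset(benchmark):
    from brs3d.dataprep import build_pair_dataset, curate_records

    curated = curate_records(benchmark.activities)
    return build_pair_dataset(curated, "T1", "T2")


@pytest.fixture(scope="session")
def small_molecules():
    """A handful of embedded small molecules for shape/descriptor tests."""
    from brs3d.shape import embed_molecule

    smiles = {
        "ethanol": "CCO",
        "benzene": "c1ccccc1",
        "phenol": "c1ccccc1O",
        "pyridine": "c1ccncc1",
        "toluene": "Cc1ccccc1",
        "benzoate": "c1ccccc1C(=O)[O-]",
    }
    return {name: embed_molecule(s, seed=11, mol_id=name) for name, s in smiles.items()}


def make_single_atom(mol_id="atom", xyz=(0.0, 0.0, 0.0), radius=1.0):
    """A one-heavy-atom molecule with a unit-ish Gaussian sphere."""
    from brs3d.shape import Molecule3D

    return Molecule3D(
        mol_id=mol_id,
        elements=("C",),
        coords=np.array([xyz], dtype=float),
        charges=np.zeros(1),
        radii=np.array([radius]),
    )
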