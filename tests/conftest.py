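import numpy as np
import pytest

from grnlab.lab import Dataset, NoiseModel, Perturbation, add_noise, apply_perturbation
from grnlab.model import (
    GeneSpec,
    ModelInstance,
    NetworkSpec,
    ParameterSet,
    RegulationSpec,
    TimeGrid,
    simulate,
)
from grnlab.fixtures import model1_fixture, model2_fixture


@pytest.fixture(scope="session")
def model1():
    return model1_fixture()


@pytest.fixture(scope="session")
def model2():
    return model2_fixture()


@pytest.fixture(scope="session")
def single_gene_model():
    """One unregulated mRNA+protein gene: pro=2, rbs=3, protein deg 0.5."""
    spec = NetworkSpec((GeneSpec("g1"),), (), "mrna_protein")
    params = ParameterSet(
        {"g1_promoter": 2.0, "g1_rbs": 3.0, "protein_degradation_rate": 0.5}
    )
    return ModelInstance(spec, params)


@pytest.fixture(scope="session")
def three_gene_po():
    """3-gene protein-only chain g1 -> g2 -| g3 with known truth."""
    spec = NetworkSpec(
        (GeneSpec("g1"), GeneSpec("g2"), GeneSpec("g3")),
        (
            RegulationSpec("r1", "g1", ("g2",), "+"),
            RegulationSpec("r2", "g2", ("g3",), "-"),
        ),
        "protein_only",
    )
    params = ParameterSet(
        {
            "r1_synthesis": 2.0,
            "r1_Kd": 1.5,
            "r1_h": 2.0,
            "r2_synthesis": 3.0,
            "r2_Kd": 2.0,
            "r2_h": 2.0,
            "g1_degradation": 0.4,
            "g2_degradation": 0.6,
            "g3_degradation": 0.5,
            "g1_basal": 1.2,
        }
    )
    return ModelInstance(spec, params)


def noisy_datasets(model, conditions, rng, nm=None, grid=None):
    """Simulate each condition (a tuple of perturbations) and add noise."""
    nm = nm or NoiseModel()
    grid = grid or TimeGrid(0.0, 20.0, 0.5)
    out = []
    for perts in conditions:
        m = model
        for p in perts:
            m = apply_perturbation(m, p)
        traj = simulate(m, grid)
        out.append(
            Dataset(
                perturbations=tuple(perts),
                technology="massspec"
                if model.spec.model_class == "protein_only"
                else "fluorescence",
                grid=grid,
                species=traj.species,
                values=add_noise(traj.values, nm, rng),
            )
        )
    return out


@pytest.fixture(scope="session")
def knockdown_conditions():
    return [
        (),
        (Perturbation("sirna_knockdown", "g1"),),
        (Perturbation("sirna_knockdown", "g2"),),
        (Perturbation("sirna_knockdown", "g3"),),
    ]
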