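import numpy as np
import pytest

from pharmfunnel import ml_triage, synth
from pharmfunnel.pharmacophore import default_gpr40_model


@pytest.fixture(scope="session")
def gpr40_model():
    model, ref = default_gpr40_model()
    return model, ref


@pytest.fixture(scope="session")
def small_library(gpr40_model):
    """Noise-free 10 actives + 30 decoys with ground-truth labels."""
    model, ref = gpr40_model
    spec = synth.LibrarySpec(
        n_actives=10, n_decoys=30, model=model,
        geometric_noise_sd=0.0, seed=11, reference_points=ref,
    )
    return synth.make_feature_library(spec)


@pytest.fixture(scope="session")
def activity_features():
    """Featurized planted-rule activity table (n=600), shared across tests."""
    table = synth.make_activity_table(
        synth.ActivityTableSpec(n=600, active_fraction=0.5,
                                ec50_noise_sd=0.3, seed=21)
    )
    labeled = ml_triage.label_activities(table)
    X, ok = ml_triage.featurize_smiles(labeled["smiles"].tolist())
    assert ok.all()
    y = labeled["label"].to_numpy()
    return labeled, X, y


@pytest.fixture(scope="session")
def pocket_pose():
    return synth.make_pocket_pose(n_receptor_atoms=30, n_ligand_atoms=10, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
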