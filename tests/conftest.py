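import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def helix_ensemble():
    """Three frames of an ideal, fully formed 30-residue helix."""
    from idpkit import synth

    model = synth.HelixModel(
        n_residues=30, helix_region=(1, 30),
        p_nucleate=1.0, p_stay=1.0, dihedral_noise_deg=0.0, seed=7,
    )
    return synth.gen_ensemble(model, n_frames=3)


@pytest.fixture
def coil_ensemble():
    """Twenty frames with the helix turned off entirely."""
    from idpkit import synth

    model = synth.HelixModel(
        n_residues=25, helix_region=(1, 25),
        p_nucleate=0.0, p_stay=0.0, seed=11,
    )
    return synth.gen_ensemble(model, n_frames=20)
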