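import numpy as np
import pytest

from tmdyn import (
    ALPHA,
    Ensemble,
    HingeSpec,
    build_ideal_helix,
    generate_hinge_ensemble,
    parametric_ca_helix,
)
from tmdyn.constants import C99_WT_CONSTRUCT

WT_SEQ = C99_WT_CONSTRUCT


@pytest.fixture(scope="session")
def wt_helix():
    """Ideal alpha-helix backbone of the KKW-tagged C99(28-55) construct."""
    return build_ideal_helix(WT_SEQ, ALPHA)


@pytest.fixture(scope="session")
def wt_param_helix():
    """Exact 3.6-residue/turn Calpha helix of the construct (rise 1.5 A)."""
    return parametric_ca_helix(WT_SEQ)


@pytest.fixture()
def rigid_ensemble(wt_helix):
    """Three identical frames of the ideal helix."""
    return Ensemble(wt_helix.topology, np.repeat(wt_helix.xyz[None], 3, axis=0),
                    wt_helix.residue_map, frame_spacing_ns=0.05)


@pytest.fixture()
def noisy_ensemble(wt_helix):
    """200 frames of the helix with small isotropic coordinate noise."""
    rng = np.random.default_rng(2024)
    xyz = wt_helix.xyz[None] + rng.normal(0.0, 0.08, (200, *wt_helix.xyz.shape))
    return Ensemble(wt_helix.topology, xyz, wt_helix.residue_map,
                    frame_spacing_ns=0.05)


@pytest.fixture()
def bend30_ensemble(wt_helix):
    """Noiseless 30-degree hinge bend at G37 toward the -40 azimuth."""
    spec = HingeSpec(hinge=37, bend_mean=30.0, bend_sd=0.0,
                     azimuth_mean=-40.0, azimuth_sd=0.0)
    return generate_hinge_ensemble(wt_helix, spec, 5, seed=11)


def random_rigid_transform(rng):
    """A uniformly random rotation matrix and a translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t
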