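import numpy as np
import pytest

from conformotion import (SyntheticSpec, fill_gaps, make_arc_ensemble,
                          make_gapped_cif_fixture, make_hinge_ensemble,
                          make_linear_motion_ensemble, superimpose_ensemble)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def linear_default():
    """Default linear-motion ensemble (m=50, n=30, 10% noise), superimposed."""
    ens, truth = make_linear_motion_ensemble(SyntheticSpec(seed=0))
    ens = superimpose_ensemble(ens)
    dense, _ = fill_gaps(ens)
    return ens, truth, dense


@pytest.fixture(scope="session")
def linear_small():
    """Small noise-free linear ensemble for exact-rank checks."""
    ens, truth = make_linear_motion_ensemble(
        SyntheticSpec(m=20, n=10, amplitude=1.0, noise_sd=0.0, seed=1))
    dense, _ = fill_gaps(ens)
    return ens, truth, dense


@pytest.fixture(scope="session")
def arc_fixture():
    ens, truth = make_arc_ensemble(
        SyntheticSpec(m=20, n=40, motion="arc", amplitude=3.0, noise_sd=0.05,
                      seed=2))
    dense, _ = fill_gaps(ens)
    return ens, truth, dense


@pytest.fixture(scope="session")
def hinge_fixture():
    ens, truth = make_hinge_ensemble(
        SyntheticSpec(m=30, n=30, motion="hinge", noise_sd=0.05, seed=3),
        angle_range=1.2)
    return ens, truth


@pytest.fixture(scope="session")
def cif_set(tmp_path_factory):
    """Gapped CIF fixture files + ground truth, with an injected duplicate."""
    out = tmp_path_factory.mktemp("cifset")
    spec = SyntheticSpec(m=30, n=8, noise_sd=0.0, missing_fraction=0.15, seed=4)
    paths, truth = make_gapped_cif_fixture(spec, out, include_duplicate=True)
    return paths, truth, spec
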