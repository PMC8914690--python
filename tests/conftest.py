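import numpy as np
import pytest

from grasptex import synth_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Six-class synthetic dataset, scaled down for fast unit tests."""
    return synth_dataset(n_per_class=12, duration_s=1.5, fs=500.0, seed=7)


@pytest.fixture(scope="session")
def mat_fixture_dir(tmp_path_factory):
    """A miniature MAT-file dataset directory (1 file, 2 trials/class, 100 samples)."""
    import scipy.io

    from grasptex.data import DEFAULT_MAT_NAMES, GraspClass

    root = tmp_path_factory.mktemp("matdata")
    gen = np.random.default_rng(3)
    variables = {}
    for cls in GraspClass.ordered():
        stem = DEFAULT_MAT_NAMES[cls]
        variables[f"{stem}_ch1"] = gen.standard_normal((2, 100))
        variables[f"{stem}_ch2"] = gen.standard_normal((2, 100))
    scipy.io.savemat(root / "subject_1.mat", variables)
    return root
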