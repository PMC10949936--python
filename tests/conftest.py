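import numpy as np
import pytest

from slesa import FeatureMatrix, SyntheticSpec, generate


@pytest.fixture
def tiny_features() -> FeatureMatrix:
    """Three hand-written samples of length 6, both classes present."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
        [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
    ])
    return FeatureMatrix(values, np.array(["m", "n", "m"], dtype=object),
                         np.array(["a", "b", "c"], dtype=object))


@pytest.fixture
def clean_disjoint_data():
    """Noise-free two-class set with disjoint class subspaces (seeded)."""
    spec = SyntheticSpec(n_per_class=12, l=32, atoms_per_class=4, sparsity=2,
                         noise_sigma=0.0, subspace_overlap=0.0, seed=3)
    return generate(spec)


@pytest.fixture
def random_unit_dictionary():
    def make(s: int, M: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        D = rng.standard_normal((s, M))
        return D / np.linalg.norm(D, axis=0)

    return make
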