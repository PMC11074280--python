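import numpy as np
import pytest

from debatch import NormalizationSpec, OmicsMatrix, SimulationSpec, generate


@pytest.fixture
def small_matrix() -> OmicsMatrix:
    """12 samples, 2 batches, 2 classes, 1 QC pair, deterministic values."""
    rng = np.random.default_rng(7)
    values = rng.gamma(2.0, 50.0, size=(12, 5))
    return OmicsMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(12)],
        feature_ids=[f"f{j}" for j in range(5)],
        batch_labels=np.array(["b1"] * 6 + ["b2"] * 6, dtype=object),
        class_labels=np.array((["x", "y"] * 5) + ["QC", "QC"], dtype=object),
        qc_flags=np.array([False] * 10 + [True, True]),
    )


@pytest.fixture(scope="session")
def null_dataset():
    """Six balanced batches, no batch effect."""
    return generate(SimulationSpec(n_batches=6, samples_per_batch=40, n_features=50,
                                   batch_additive_sd=0.0, seed=11))[0]


@pytest.fixture(scope="session")
def shifted_dataset():
    """Six balanced batches with an overwhelming additive batch shift."""
    return generate(SimulationSpec(n_batches=6, samples_per_batch=40, n_features=50,
                                   batch_additive_sd=3.0, noise_sd=0.3, seed=11))[0]


@pytest.fixture
def default_norm() -> NormalizationSpec:
    return NormalizationSpec()
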