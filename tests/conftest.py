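import numpy as np
import pytest

from mule import GeneratorSpec, LabelMatrix, ModelPredictions, generate_scenario


def random_label_matrix(rng, n_instances, n_labels, density=0.15) -> LabelMatrix:
    return LabelMatrix.from_dense(rng.random((n_instances, n_labels)) < density)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_scenario():
    """A modest selection scenario with a known dominant model."""
    spec = GeneratorSpec(
        n_instances=1500, n_labels=120, zipf_exponent=0.5,
        target_cardinality=13.0, seed=42,
    )
    return generate_scenario(spec, n_models=3, n_designated_frequent=10,
                             n_designated_rare=10, seed=42)


def random_models(rng, gold, n_models, flip=0.05):
    """Random perturbations of gold as a bank of component models."""
    dense = gold.toarray().astype(bool)
    preds = []
    for i in range(n_models):
        mask = rng.random(dense.shape) < flip
        preds.append(
            ModelPredictions(model_id=f"R{i}", predictions=LabelMatrix.from_dense(dense ^ mask))
        )
    return preds
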