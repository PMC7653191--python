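import numpy as np
import pytest

from g4forge.dataset_builder import split_train_eval
from g4forge.network import NetworkConfig, build_model
from g4forge.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def trained_models():
    """Three classifiers trained on balanced synthetic data (8000/2000).

    Negatives are unscreened background (as genomic negatives would be);
    one entry per seed: the model, its held-out set, and the generator
    spec. Shared session-wide because training is the expensive step.
    """
    runs = []
    for seed in (1, 2, 3):
        spec = SyntheticSpec(seed=seed, exclude_regex_in_negatives=False)
        rng = np.random.default_rng(seed)
        data, _ = generate_dataset(spec, ratio_k=1, total=10000, rng=rng)
        train_set, eval_set = split_train_eval(data, 0.2, rng)
        model = build_model(NetworkConfig(seed=seed)).fit(train_set, eval_set)
        runs.append({"seed": seed, "model": model, "eval_set": eval_set,
                     "spec": spec})
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
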