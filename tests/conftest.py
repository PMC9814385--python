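import numpy as np
import pytest

from rxngen.corpus import build_vocabulary, encode_equation, split_dataset
from rxngen.synthetic import SHORT_LIBRARY, GeneratorConfig, generate_corpus
from rxngen.vae import ModelConfig, ReactionVAE

# The toy-scale training configuration shared by VAE, generator and
# acceptance tests.  Short strings (short-SMILES library, <= 2 species per
# side, coefficients <= 2) and the settings below were fixed by pre-build
# experiment as the best-learning desk-scale setup; embedding 64 / latent 32
# / 200 epochs / kl_weight 0.1 are the scaled-down reference values.
TOY_CORPUS_CONFIG = dict(
    library=SHORT_LIBRARY, n_equations=500, max_species_per_side=2,
    max_coefficient=2, seed=11,
)
TOY_MODEL_CONFIG = dict(
    embedding_dim=64, latent_dim=32, hidden_dim=96, recurrent_dropout=0.1,
    kl_weight=0.1, learning_rate=1e-2, epochs=200, batch_size=8,
    dtype="float32", logvar_bias_init=-6.0, seed=5,
)
TOY_SPLIT_SEED = 1


@pytest.fixture(scope="session")
def toy_corpus():
    """500 clean synthetic reactions (strings)."""
    df = generate_corpus(GeneratorConfig(**TOY_CORPUS_CONFIG))
    return df["line"].tolist()


@pytest.fixture(scope="session")
def toy_vocab(toy_corpus):
    return build_vocabulary(toy_corpus)


@pytest.fixture(scope="session")
def toy_split(toy_corpus, toy_vocab):
    encoded = [encode_equation(s, toy_vocab) for s in toy_corpus]
    return split_dataset(encoded, seed=TOY_SPLIT_SEED)


@pytest.fixture(scope="session")
def toy_model(toy_vocab, toy_split):
    """The scaled-down VAE trained once per session; several tests and the
    acceptance suite share it."""
    model = ReactionVAE(ModelConfig(**TOY_MODEL_CONFIG), toy_vocab)
    history = model.fit(toy_split)
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
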