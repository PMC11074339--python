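"""Shared fixtures: fixture corpora, a memorization-trained VAE, a full
desk-scale scenario, and the hand-built curation defect set."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from polygen.corpus import RawCompoundRecord, generate_fixture_corpus
from polygen.fixtures import ScenarioSpec, build_scenario
from polygen.vae import SmilesVAE

# The 20-record curation fixture: 13 clean molecules, 2 salts (desalted on
# curation), 3 over-length strings, 2 with atoms outside the whitelist.
CLEAN_SMILES = [
    "CCO", "CCN", "CCC", "CCOC", "CC(C)O", "CCCN", "c1ccccc1", "CC(=O)O",
    "CC(=O)NC", "CCOCC", "C1CCCCC1", "CCS", "CC(C)C",
]
SALT_SMILES = ["CCO.Cl", "CCN.[Na+].[Cl-]"]
TOO_LONG_SMILES = ["C" * 101, "C" * 120, "CC(C)" + "C" * 100]
DISALLOWED_SMILES = ["[AsH3]", "CC[Hg]CC"]


@pytest.fixture(scope="session")
def defect_records():
    records = [RawCompoundRecord(s, f"clean{i}") for i, s in enumerate(CLEAN_SMILES)]
    records += [RawCompoundRecord(s, f"salt{i}") for i, s in enumerate(SALT_SMILES)]
    records += [RawCompoundRecord(s, f"long{i}") for i, s in enumerate(TOO_LONG_SMILES)]
    records += [RawCompoundRecord(s, f"atom{i}") for i, s in enumerate(DISALLOWED_SMILES)]
    return records


@pytest.fixture(scope="session")
def two_family_corpus():
    return generate_fixture_corpus(2, 25, seed=7)


#: Training recipe for exact memorization of the 50-molecule fixture corpus
#: on CPU: compact dims, low KL weight with warm-up, decaying learning rate.
MEMORIZATION_CONFIG = dict(
    embed_dim=32, encoder_hidden=96, encoder_layers=1, encoder_dropout=0.0,
    latent_dim=24, decoder_hidden=128, decoder_layers=1, max_len=40,
    epochs=900, learning_rate=3e-3, batch_size=50, kl_weight=0.01,
    kl_warmup_epochs=100, lr_decay=0.998, seed=1)

#: Small config for fast unit tests that only need a functioning model.
TINY_CONFIG = dict(
    embed_dim=12, encoder_hidden=16, latent_dim=8, decoder_hidden=24,
    decoder_layers=1, encoder_dropout=0.0, max_len=40, epochs=30,
    learning_rate=3e-3, batch_size=50, kl_weight=0.05, seed=0)


@pytest.fixture(scope="session")
def memorized_vae(two_family_corpus):
    return SmilesVAE(**MEMORIZATION_CONFIG).fit(two_family_corpus)


@pytest.fixture(scope="session")
def tiny_vae(two_family_corpus):
    return SmilesVAE(**TINY_CONFIG).fit(two_family_corpus)


@pytest.fixture(scope="session")
def scenario():
    return build_scenario(ScenarioSpec(seed=5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
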