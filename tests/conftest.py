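import pytest

import bapstools as bt
from bapstools import synthetic as syn


@pytest.fixture(scope="session")
def fixture_suite():
    """The 12-contig cascade fixture with constructed ground truth."""
    return syn.make_fixture_suite(seed=7)


@pytest.fixture(scope="session")
def small_model_bundle():
    """A quickly trained classifier on a reduced two-class corpus, shared
    across unit tests that only need *a* working model."""
    pos = syn.make_training_contigs(syn.phage_like_model(), 40, 15_000, seed=10)
    neg = syn.make_training_contigs(syn.host_like_model(), 40, 15_000, seed=20)
    corpus = bt.build_corpus(pos, neg)
    model = bt.train_phager(corpus, bt.Hyperparams(n_estimators=120), seed=1)
    return model, corpus


@pytest.fixture(scope="session")
def small_model(small_model_bundle):
    return small_model_bundle[0]
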