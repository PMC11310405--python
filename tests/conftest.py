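import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mpnlp.ner import annotate_corpus
from mpnlp.synthetic import RenderConfig, et_config, render_corpus, sample_cohort
from mpnlp.vocab import default_vocabulary

settings.register_profile(
    "suite",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def small_truth():
    """A 150-patient ET-like cohort used across NER/inference tests."""
    return sample_cohort(et_config(150, seed=11))


@pytest.fixture(scope="session")
def zero_noise_corpus(small_truth, vocab):
    """(documents, gold annotations, gold labels) with all noise rates 0."""
    render = RenderConfig(negated_rate=0.0, ambiguous_rate=0.0,
                          other_subject_rate=0.0, seed=11)
    return render_corpus(small_truth, render, vocab)


@pytest.fixture(scope="session")
def noisy_corpus(small_truth, vocab):
    render = RenderConfig(seed=11)  # default noise rates
    return render_corpus(small_truth, render, vocab)


@pytest.fixture(scope="session")
def noisy_predictions(noisy_corpus, vocab):
    docs, _, _ = noisy_corpus
    return annotate_corpus(docs, vocab)
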