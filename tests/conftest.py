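import pytest
from hypothesis import settings

import ftrclassify as f

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def battery():
    return f.generate_battery()


@pytest.fixture(scope="session")
def k_grid(battery):
    return f.candidate_k_grid(battery)


@pytest.fixture(scope="session")
def lexicon():
    return f.ModalLexicon.default()


@pytest.fixture(scope="session")
def template_corpus():
    """Balanced labeled template corpus used by classifier and closure tests."""
    return f.generate_labeled_sentences(30, seed=7)


@pytest.fixture(scope="session")
def trained_model(template_corpus):
    examples = [f.AnnotatedExample(s.text, s.time_ref) for s in template_corpus]
    model, metrics = f.train_time_reference_model(examples, split=0.8, seed=0)
    return model, metrics
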