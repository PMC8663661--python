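from __future__ import annotations

import numpy as np
import pytest

from chartsift import default_term_set, regression_fixture
from chartsift.synthetic import SimulationConfig, generate


@pytest.fixture(scope="session")
def term_set():
    return default_term_set()


@pytest.fixture(scope="session")
def fixture_corpus():
    """The frozen five-patient regression corpus."""
    return regression_fixture()


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down simulation (few, short documents) for fast tests."""
    defaults = dict(
        seed=11,
        n_patients=10,
        grade_weights={0: 5, 1: 3, 2: 1, 3: 1},
        total_documents=None,
        docs_log_mean=np.log(5.0),
        docs_min=3,
        docs_max=9,
        sentences_per_doc_rate=4.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small in-memory synthetic corpus shared across read-only tests."""
    return generate(small_config())


def random_document_lines(rng: np.random.Generator, n_sentences: int) -> list[str]:
    """Sentences stressing the matcher: key-term words, near-miss words,
    hyphenated variants, mixed case."""
    vocab = [
        "pneumonitis", "radiation", "induced", "lung", "injury", "fibrosis",
        "Pneumonitis", "RADIATION", "Fibrosis", "pneumonitic", "fibrotic",
        "radiation-induced", "radiation-pneumonitis", "the", "left", "base",
        "no", "evidence", "of", "mild", "seen", "is", "there", "opacity",
        "post-radiation", "lungs", "injuries", "perifibrosis",
    ]
    lines = []
    for _ in range(n_sentences):
        k = int(rng.integers(3, 12))
        words = [vocab[int(rng.integers(len(vocab)))] for _ in range(k)]
        words[0] = words[0][0].upper() + words[0][1:]
        lines.append(" ".join(words) + ".")
    return lines
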