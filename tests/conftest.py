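"""Shared fixtures: small hand-built corpora and seeded random corpora."""

from __future__ import annotations

import numpy as np
import pytest

from charhmm.corpus_io import AnnotatedDocument, ConceptSpan, Corpus


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Two documents, three concept types, hand-placed spans."""
    d1 = AnnotatedDocument(
        "d1",
        [["his", "melanoma", "worsened"], ["ct", "scan", "was", "clear"]],
        [ConceptSpan(0, 1, 2, "Problem"), ConceptSpan(1, 0, 2, "Test")],
    )
    d2 = AnnotatedDocument(
        "d2",
        [["started", "on", "aspirin", "for", "chest", "pain"]],
        [ConceptSpan(0, 2, 3, "Treatment"), ConceptSpan(0, 4, 6, "Problem")],
    )
    return Corpus([d1, d2], ["Problem", "Test", "Treatment"])


def random_corpus(seed: int, n_docs: int = 5, types=("X", "Y")) -> Corpus:
    """Small random but valid corpus for round-trip property tests."""
    rng = np.random.default_rng(seed)
    docs = []
    for d in range(n_docs):
        n_sents = int(rng.integers(1, 4))
        sentences, spans = [], []
        for si in range(n_sents):
            n_tok = int(rng.integers(1, 9))
            sentences.append([f"w{rng.integers(0, 20)}" for _ in range(n_tok)])
            pos = 0
            while pos < n_tok:
                if rng.random() < 0.4:
                    length = int(rng.integers(1, min(3, n_tok - pos) + 1))
                    spans.append(
                        ConceptSpan(si, pos, pos + length, str(rng.choice(types)))
                    )
                    pos += length
                pos += int(rng.integers(1, 3))
        docs.append(AnnotatedDocument(f"r{seed}-{d}", sentences, spans))
    return Corpus(docs, list(types))


@pytest.fixture
def corpus_factory():
    return random_corpus
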