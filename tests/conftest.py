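import numpy as np
import pytest

from sublocnet.datasets import AnnotatedProteinSet, LocationVocabulary, ProteinRecord


@pytest.fixture
def tiny_set() -> AnnotatedProteinSet:
    """Three proteins over a 2-location vocabulary."""
    vocab = LocationVocabulary(("Nucleus", "Cytoplasm"))
    recs = [
        ProteinRecord("p1", "MKV", np.array([1, 0])),
        ProteinRecord("p2", "ACDEFG", np.array([1, 1])),
        ProteinRecord("p3", "GGHH", np.array([0, 1])),
    ]
    return AnnotatedProteinSet(vocab, recs)


def random_annotated_set(rng: np.random.Generator, n: int = 30, L: int = 5) -> AnnotatedProteinSet:
    """Random valid set: every protein gets >= 1 location."""
    vocab = LocationVocabulary(tuple(f"Loc{j}" for j in range(L)))
    aas = "ACDEFGHIKLMNPQRSTVWY"
    recs = []
    for i in range(n):
        labels = (rng.random(L) < 0.3).astype(np.int64)
        if labels.sum() == 0:
            labels[rng.integers(L)] = 1
        seq = "".join(aas[k] for k in rng.integers(0, 20, size=rng.integers(10, 60)))
        recs.append(ProteinRecord(f"p{i}", seq, labels))
    return AnnotatedProteinSet(vocab, recs)
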