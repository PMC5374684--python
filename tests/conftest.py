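import numpy as np
import pytest

from kmerforest import (
    FeatureMatrix,
    GenomeSource,
    KmerVocabulary,
    SparseKmerVector,
)


@pytest.fixture
def tiny_genome():
    return GenomeSource({"chr1": "ACGTACGT"})


@pytest.fixture
def vocab2():
    return KmerVocabulary(k=2)


@pytest.fixture
def vocab3():
    return KmerVocabulary(k=3)


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def dense_to_matrix(X: np.ndarray, y, vocab: KmerVocabulary) -> FeatureMatrix:
    """Wrap a dense array as a FeatureMatrix of sparse vectors."""
    vectors = []
    for row in np.asarray(X, dtype=float):
        idx = np.nonzero(row)[0]
        vectors.append(SparseKmerVector(X.shape[1], idx, row[idx]))
    return FeatureMatrix(vectors, y, vocab)


def naive_kmer_counts(seq: str, k: int) -> dict:
    """Independent substring-enumeration oracle for k-mer counting."""
    counts = {}
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k].upper()
        if all(b in "ACGT" for b in window):
            counts[window] = counts.get(window, 0) + 1
    return counts
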