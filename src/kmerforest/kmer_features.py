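"""Sparse k-mer featurization of DNA sequences.

A length-L sequence has L−k+1 overlapping windows; each window that
consists only of A/C/G/T increments one of the 4^k k-mer features. In
conservation-weighted mode each occurrence contributes the mean per-base
conservation frequency of its k positions instead of 1, so every weighted
value is bounded above by the plain count and equals it exactly when all
touched frequencies are 1.

Nucleotides are encoded as base-4 digits A=0, C=1, G=2, T=3; a k-mer's
feature index is its base-4 value, so index order is lexicographic.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .sequence_io import ConservationTrack, GenomeSource, IntervalSet

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

COUNT_MODE = "count"
CONSERVATION_MODE = "conservation"


def vocabulary_dimension(k: int, rc_collapse: bool = False) -> int:
    """Number of k-mer features: 4^k, or the number of reverse-complement
    equivalence classes when collapsing strands."""
    if not 2 <= k <= 12:
        raise ValueError(f"k must be in [2, 12], got {k}")
    if not rc_collapse:
        return 4**k
    if k % 2 == 0:
        # palindromic k-mers (self reverse-complement) exist only for even k
        return 4**k // 2 + 4 ** (k // 2) // 2
    return 4**k // 2


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


class KmerVocabulary:
    """Bijection between k-mer strings over {A,C,G,T} and feature indices.

    With ``rc_collapse`` a k-mer and its reverse complement share one
    canonical index; canonical representatives are the lexicographically
    smaller member of each pair, indexed in lexicographic order.
    """

    def __init__(self, k: int, rc_collapse: bool = False):
        if not 2 <= k <= 10:
            raise ValueError(f"k must be in [2, 10], got {k}")
        self.k = int(k)
        self.rc_collapse = bool(rc_collapse)
        self._canon_map: Optional[np.ndarray] = None  # raw code -> compact index
        self._rep_codes: Optional[np.ndarray] = None  # compact index -> raw code

    @property
    def dimension(self) -> int:
        return vocabulary_dimension(self.k, self.rc_collapse)

    # -- raw base-4 codes ---------------------------------------------------

    def _rc_codes(self, codes: np.ndarray) -> np.ndarray:
        """Reverse-complement of base-4 encoded k-mers, vectorized."""
        out = np.zeros_like(codes)
        c = codes.copy()
        for _ in range(self.k):
            out = out * 4 + (3 - (c % 4))
            c //= 4
        return out

    def _ensure_canon(self) -> None:
        if self._canon_map is not None or not self.rc_collapse:
            return
        raw = np.arange(4**self.k, dtype=np.int64)
        canon = np.minimum(raw, self._rc_codes(raw))
        reps = np.unique(canon)
        self._canon_map = np.searchsorted(reps, canon).astype(np.int64)
        self._rep_codes = reps

    def _compact(self, raw_codes: np.ndarray) -> np.ndarray:
        if not self.rc_collapse:
            return raw_codes
        self._ensure_canon()
        return self._canon_map[raw_codes]

    # -- string interface ---------------------------------------------------

    def index(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        code = 0
        for b in kmer.upper():
            d = _CODE[ord(b)]
            if d == 255:
                raise ValueError(f"non-ACGT base in {kmer!r}")
            code = code * 4 + int(d)
        return int(self._compact(np.array([code]))[0])

    def kmer(self, index: int) -> str:
        if not 0 <= index < self.dimension:
            raise IndexError(f"feature index {index} out of range")
        if self.rc_collapse:
            self._ensure_canon()
            code = int(self._rep_codes[index])
        else:
            code = index
        out = []
        for _ in range(self.k):
            out.append(BASES[code % 4])
            code //= 4
        return "".join(reversed(out))

    def all_kmers(self) -> List[str]:
        return [self.kmer(i) for i in range(self.dimension)]

    def checksum(self) -> str:
        payload = json.dumps({"k": self.k, "rc_collapse": self.rc_collapse})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(
                {"k": self.k, "rc_collapse": self.rc_collapse, "checksum": self.checksum()},
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "KmerVocabulary":
        with open(path) as fh:
            meta = json.load(fh)
        return cls(k=meta["k"], rc_collapse=meta["rc_collapse"])

    # -- window machinery ---------------------------------------------------

    def window_indices(self, seq: str) -> Tuple[np.ndarray, np.ndarray]:
        """(compact feature index per window, local start per window) for
        every window free of non-ACGT characters; windows are in sequence
        order."""
        k = self.k
        if len(seq) < k:
            raise ValueError(
                f"sequence shorter than k (length {len(seq)} < {k})"
            )
        codes = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
        n_win = len(seq) - k + 1
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (windows < 4).all(axis=1)
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        raw = windows[valid].astype(np.int64) @ powers
        starts = np.nonzero(valid)[0]
        return self._compact(raw), starts


@dataclass
class SparseKmerVector:
    """One sequence's sparse feature vector (counts or weighted counts)."""

    dimension: int
    indices: np.ndarray  # sorted, strictly increasing
    values: np.ndarray  # > 0, aligned with indices
    seq_id: str = ""
    length: int = 0
    mode: str = COUNT_MODE

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)

    def to_dict(self, vocab: KmerVocabulary) -> Dict[str, float]:
        return {vocab.kmer(int(i)): float(v) for i, v in zip(self.indices, self.values)}

    def dense(self) -> np.ndarray:
        out = np.zeros(self.dimension)
        out[self.indices] = self.values
        return out

    @property
    def total(self) -> float:
        return float(self.values.sum())


def _sparsify(dense_idx: np.ndarray, dense_val: np.ndarray, dim: int, **meta) -> SparseKmerVector:
    order = np.argsort(dense_idx, kind="stable")
    idx_sorted = dense_idx[order]
    uniq, inverse = np.unique(idx_sorted, return_inverse=True)
    summed = np.zeros(len(uniq))
    np.add.at(summed, inverse, dense_val[order])
    keep = summed > 0
    return SparseKmerVector(dim, uniq[keep], summed[keep], **meta)


def count_kmers(seq: str, vocab: KmerVocabulary, seq_id: str = "") -> SparseKmerVector:
    """Count every ACGT-only window of width k; Σ counts equals the number
    of valid windows (L−k+1 on an N-free sequence)."""
    idx, _ = vocab.window_indices(seq)
    return _sparsify(
        idx,
        np.ones(len(idx)),
        vocab.dimension,
        seq_id=seq_id,
        length=len(seq),
        mode=COUNT_MODE,
    )


def weight_kmers_by_conservation(
    seq: str,
    chrom: str,
    offset: int,
    track: ConservationTrack,
    vocab: KmerVocabulary,
    seq_id: str = "",
) -> SparseKmerVector:
    """Conservation-weighted counts: each window occurrence contributes the
    mean of the k per-base frequencies it covers, instead of 1."""
    idx, starts = vocab.window_indices(seq)
    fre = track.values(chrom, offset, offset + len(seq))
    csum = np.concatenate([[0.0], np.cumsum(fre)])
    weights = (csum[starts + vocab.k] - csum[starts]) / vocab.k
    return _sparsify(
        idx,
        weights,
        vocab.dimension,
        seq_id=seq_id,
        length=len(seq),
        mode=CONSERVATION_MODE,
    )


class FeatureMatrix:
    """Sparse feature vectors sharing one vocabulary, with 0/1 labels
    (1 = open/accessible chromatin, 0 = closed)."""

    def __init__(
        self,
        vectors: Sequence[SparseKmerVector],
        labels: Sequence[int],
        vocab: KmerVocabulary,
    ):
        if len(vectors) != len(labels):
            raise ValueError("vectors and labels must be parallel")
        dims = {v.dimension for v in vectors}
        if dims and dims != {vocab.dimension}:
            raise ValueError("vector dimension mismatch with vocabulary")
        self.vectors = list(vectors)
        self.labels = np.asarray(labels, dtype=np.int64)
        if self.labels.size and not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0/1")
        self.vocab = vocab

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def n_features(self) -> int:
        return self.vocab.dimension

    def to_csr(self, dtype=np.float64) -> sp.csr_matrix:
        indptr = np.zeros(len(self.vectors) + 1, dtype=np.int64)
        for i, v in enumerate(self.vectors):
            indptr[i + 1] = indptr[i] + len(v.indices)
        if len(self.vectors):
            indices = np.concatenate([v.indices for v in self.vectors])
            data = np.concatenate([v.values for v in self.vectors])
        else:
            indices = np.zeros(0, dtype=np.int64)
            data = np.zeros(0)
        return sp.csr_matrix(
            (data.astype(dtype), indices, indptr),
            shape=(len(self.vectors), self.n_features),
        )


def build_feature_matrix(
    genome: GenomeSource,
    intervals: IntervalSet,
    vocab: KmerVocabulary,
    track: Optional[ConservationTrack] = None,
) -> Tuple[FeatureMatrix, int]:
    """One feature vector per interval, in input order; conservation mode
    iff ``track`` is given. Intervals shorter than k are dropped; the drop
    count is returned alongside the matrix."""
    if len(intervals) == 0:
        raise ValueError("interval set is empty")
    vectors: List[SparseKmerVector] = []
    labels: List[int] = []
    n_dropped = 0
    for iv in intervals:
        if iv.length < vocab.k:
            n_dropped += 1
            continue
        seq = genome.fetch(iv.chrom, iv.start, iv.end)
        seq_id = f"{iv.chrom}:{iv.start}-{iv.end}"
        if track is None:
            vec = count_kmers(seq, vocab, seq_id=seq_id)
        else:
            vec = weight_kmers_by_conservation(
                seq, iv.chrom, iv.start, track, vocab, seq_id=seq_id
            )
        vectors.append(vec)
        labels.append(iv.label_int)
    if not vectors:
        raise ValueError("all intervals shorter than k")
    return FeatureMatrix(vectors, labels, vocab), n_dropped


# ---------------------------------------------------------------------------
# sparse on-disk representation (SVMlight / LIBSVM text, 1-based feature ids)


def write_svmlight(matrix: FeatureMatrix, path) -> None:
    from sklearn.datasets import dump_svmlight_file

    X = matrix.to_csr()
    dump_svmlight_file(X, matrix.labels, str(path), zero_based=False)


def read_svmlight(path, vocab: KmerVocabulary) -> FeatureMatrix:
    from sklearn.datasets import load_svmlight_file

    X, y = load_svmlight_file(str(path), n_features=vocab.dimension, zero_based=False)
    X = X.tocsr()
    vectors = []
    for i in range(X.shape[0]):
        row = X.getrow(i)
        vectors.append(
            SparseKmerVector(vocab.dimension, row.indices.astype(np.int64), row.data)
        )
    return FeatureMatrix(vectors, y.astype(np.int64), vocab)
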