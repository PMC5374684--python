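"""Random forest with explicit out-of-bag bookkeeping and OOB permutation
importance (mean decrease accuracy, MDA).

The forest is a hand-rolled bagging ensemble over scikit-learn decision
trees: each tree is grown to full depth (no pruning) on a bootstrap
resample of the training set, with random feature subsampling at every
split, and the complementary OOB sample indices are recorded per tree.
Prediction is majority vote; a 50/50 tie maps to label 0.

MDA of feature j is the average over trees of the drop in that tree's OOB
accuracy when feature j's values are permuted among its OOB samples
(Breiman's raw accuracy decrease, no variance normalization). Permutations
are seeded per (permutation seed, tree index, feature index), making the
result bit-identical regardless of execution order or thread count. A tree
contributes exactly 0 for every feature it never splits on — permuting an
unused feature cannot change the tree's predictions — so only split
features are permuted; features unused by every tree, and features constant
across the matrix, score exactly 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.tree import DecisionTreeClassifier

from .kmer_features import FeatureMatrix, KmerVocabulary, SparseKmerVector


@dataclass
class ForestConfig:
    """Hyper-parameters of the bagged forest.

    Trees are always full-depth, Gini-split, and trained on a bootstrap of
    the same size as the training set drawn with replacement (so one sample
    may be selected more than once).
    """

    n_trees: int = 500
    features_per_split: Union[int, str] = "sqrt"  # int or "sqrt" = floor(sqrt(n))
    seed: int = 0
    n_threads: int = 1
    n_repeats: int = 1  # permutations per (tree, feature) in MDA

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class ForestModel:
    """Trained ensemble plus per-tree bootstrap/OOB indices."""

    trees: List[DecisionTreeClassifier]
    bootstrap_indices: List[np.ndarray]  # multisets: repeats allowed
    oob_indices: List[np.ndarray]
    config: ForestConfig
    n_features: int
    n_samples: int
    vocab_checksum: str = ""

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "ForestModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a ForestModel")
        return model


@dataclass
class MdaTable:
    """Per-feature mean-decrease-accuracy scores and the derived ranking."""

    scores: np.ndarray  # length n, MDA_j
    ranking: np.ndarray  # feature indices, best first; ties by ascending index
    baseline_oob_accuracy: np.ndarray  # per tree; NaN where OOB set is empty

    @property
    def n_features(self) -> int:
        return len(self.scores)

    def rank_of(self, feature_index: int) -> int:
        """1-based rank of a feature in the importance ordering."""
        return int(np.nonzero(self.ranking == feature_index)[0][0]) + 1

    def to_tsv(self, path, vocab: KmerVocabulary) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "kmer": [vocab.kmer(int(i)) for i in self.ranking],
                "index": self.ranking,
                "mda": self.scores[self.ranking],
                "rank": np.arange(1, len(self.ranking) + 1),
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MdaTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        n = len(df)
        scores = np.zeros(n)
        scores[df["index"].to_numpy()] = df["mda"].to_numpy()
        ranking = _rank_features(scores)
        return cls(scores, ranking, np.array([]))


def _rank_features(scores: np.ndarray) -> np.ndarray:
    """Descending by score; ties broken by ascending feature index."""
    return np.lexsort((np.arange(len(scores)), -scores))


def _as_csr(matrix: Union[FeatureMatrix, sp.spmatrix, np.ndarray]) -> sp.csr_matrix:
    if isinstance(matrix, FeatureMatrix):
        return matrix.to_csr(dtype=np.float32)
    return sp.csr_matrix(matrix, dtype=np.float32)


def train_forest(matrix: FeatureMatrix, config: ForestConfig) -> ForestModel:
    """Fit the bagged forest; deterministic given ``config.seed``.

    Bootstrap index multisets and per-tree random states are drawn from a
    single seeded generator before any fitting, so the result does not
    depend on how the fits are scheduled across threads.
    """
    X = _as_csr(matrix)
    y = matrix.labels if isinstance(matrix, FeatureMatrix) else None
    if y is None:
        raise TypeError("train_forest expects a FeatureMatrix")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    n = X.shape[0]

    rng = np.random.default_rng(config.seed)
    boot = [rng.integers(0, n, size=n) for _ in range(config.n_trees)]
    tree_seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(config.n_trees)]
    oob = [np.setdiff1d(np.arange(n), b) for b in boot]

    max_features = config.features_per_split
    if max_features == "sqrt":
        max_features = max(1, int(np.sqrt(X.shape[1])))

    def _fit(b: np.ndarray, ts: int) -> DecisionTreeClassifier:
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_depth=None,
            max_features=max_features,
            random_state=ts,
        )
        tree.fit(X[b], y[b])
        return tree

    if config.n_threads > 1:
        trees = joblib.Parallel(n_jobs=config.n_threads, prefer="threads")(
            joblib.delayed(_fit)(b, ts) for b, ts in zip(boot, tree_seeds)
        )
    else:
        trees = [_fit(b, ts) for b, ts in zip(boot, tree_seeds)]

    checksum = matrix.vocab.checksum() if isinstance(matrix, FeatureMatrix) else ""
    return ForestModel(
        trees=list(trees),
        bootstrap_indices=boot,
        oob_indices=oob,
        config=config,
        n_features=X.shape[1],
        n_samples=n,
        vocab_checksum=checksum,
    )


def _vote_matrix(model: ForestModel, X: sp.csr_matrix) -> np.ndarray:
    """(n_trees, n_samples) array of per-tree 0/1 votes."""
    Xd = X.toarray().astype(np.float32)
    return np.stack([t.predict(Xd, check_input=False) for t in model.trees])


def predict(
    model: ForestModel,
    vectors: Union[FeatureMatrix, Sequence[SparseKmerVector], sp.spmatrix, np.ndarray],
) -> Tuple[np.ndarray, np.ndarray]:
    """Majority-vote prediction.

    Returns (score, label): score is the fraction of trees voting 1; label
    is 1 where score > 0.5 (an exact tie maps to 0).
    """
    if isinstance(vectors, FeatureMatrix):
        X = vectors.to_csr(dtype=np.float32)
    elif sp.issparse(vectors) or isinstance(vectors, np.ndarray):
        X = sp.csr_matrix(vectors, dtype=np.float32)
    else:
        vecs = list(vectors)
        if any(v.dimension != model.n_features for v in vecs):
            raise ValueError("vector dimension does not match the model")
        indptr = np.cumsum([0] + [len(v.indices) for v in vecs])
        indices = (
            np.concatenate([v.indices for v in vecs]) if vecs else np.zeros(0, int)
        )
        data = np.concatenate([v.values for v in vecs]) if vecs else np.zeros(0)
        X = sp.csr_matrix(
            (data, indices, indptr), shape=(len(vecs), model.n_features)
        ).astype(np.float32)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    votes = _vote_matrix(model, X)
    score = (votes == 1).mean(axis=0)
    label = (score > 0.5).astype(np.int64)
    return score, label


def oob_accuracy(model: ForestModel, matrix: FeatureMatrix) -> float:
    """Out-of-bag accuracy: each training sample is predicted by majority
    vote of only the trees for which it is out-of-bag; samples that are
    in-bag for every tree are excluded from the denominator."""
    X = _as_csr(matrix)
    y = matrix.labels
    if X.shape[0] != model.n_samples or X.shape[1] != model.n_features:
        raise ValueError("matrix shape does not match the trained model")
    votes1 = np.zeros(model.n_samples)
    total = np.zeros(model.n_samples)
    Xd = X.toarray().astype(np.float32)
    for tree, oob in zip(model.trees, model.oob_indices):
        if len(oob) == 0:
            continue
        pred = tree.predict(Xd[oob], check_input=False)
        votes1[oob] += pred == 1
        total[oob] += 1
    covered = total > 0
    if not covered.any():
        raise ValueError("no sample is out-of-bag for any tree")
    oob_label = (votes1[covered] / total[covered] > 0.5).astype(np.int64)
    return float((oob_label == y[covered]).mean())


def _permutation_rng(permutation_seed: int, tree_index: int, feature_index: int):
    return np.random.default_rng((permutation_seed, tree_index, feature_index))


def _tree_mda(
    tree: DecisionTreeClassifier,
    tree_index: int,
    X_oob: np.ndarray,
    y_oob: np.ndarray,
    selected: Optional[np.ndarray],
    permutation_seed: int,
    n_repeats: int,
    n_features: int,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """(baseline accuracy, permuted features, accuracy decreases) for one
    tree. Only features the tree splits on are permuted."""
    base_pred = tree.predict(X_oob, check_input=False)
    acc_b = float((base_pred == y_oob).mean())
    used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
    if selected is not None:
        used = np.intersect1d(used, selected)
    m = len(y_oob)
    decreases = np.zeros(len(used))
    for pos, j in enumerate(used):
        j = int(j)
        rng = _permutation_rng(permutation_seed, tree_index, j)
        saved = X_oob[:, j].copy()
        drop = 0.0
        for _ in range(n_repeats):
            perm = rng.permutation(m)
            X_oob[:, j] = saved[perm]
            pred = tree.predict(X_oob, check_input=False)
            drop += acc_b - float((pred == y_oob).mean())
        X_oob[:, j] = saved
        decreases[pos] = drop / n_repeats
    return acc_b, used, decreases


def compute_mda(
    model: ForestModel,
    matrix: FeatureMatrix,
    features: Optional[Sequence[int]] = None,
    permutation_seed: int = 0,
) -> MdaTable:
    """OOB permutation importance for every feature (or a subset).

    MDA_j = (1/B) Σ_b (acc_b − acc_{b,j}) where acc_b is tree b's accuracy
    on its OOB samples and acc_{b,j} the accuracy after permuting feature j
    among those samples. Trees with an empty OOB set contribute 0 and a NaN
    baseline. Deterministic given ``permutation_seed``; per-tree work is
    independent, and concurrent execution is bit-identical to sequential.
    """
    X = _as_csr(matrix)
    y = matrix.labels
    if X.shape[0] != model.n_samples or X.shape[1] != model.n_features:
        raise ValueError("matrix shape does not match the trained model")
    selected = None
    if features is not None:
        selected = np.asarray(sorted(set(int(f) for f in features)), dtype=np.int64)
        if len(selected) and (selected[0] < 0 or selected[-1] >= model.n_features):
            raise IndexError("feature index out of range")

    B = model.n_trees
    scores = np.zeros(model.n_features)
    baselines = np.full(B, np.nan)
    Xd = X.toarray().astype(np.float32)

    def _one(b: int):
        oob = model.oob_indices[b]
        if len(oob) == 0:
            return b, np.nan, np.zeros(0, int), np.zeros(0)
        X_oob = np.ascontiguousarray(Xd[oob])
        acc_b, used, decreases = _tree_mda(
            model.trees[b],
            b,
            X_oob,
            y[oob],
            selected,
            permutation_seed,
            model.config.n_repeats,
            model.n_features,
        )
        return b, acc_b, used, decreases

    if model.config.n_threads > 1:
        results = joblib.Parallel(n_jobs=model.config.n_threads, prefer="threads")(
            joblib.delayed(_one)(b) for b in range(B)
        )
    else:
        results = [_one(b) for b in range(B)]

    for b, acc_b, used, decreases in sorted(results, key=lambda r: r[0]):
        baselines[b] = acc_b
        if len(used):
            scores[used] += decreases
    scores /= B
    return MdaTable(scores=scores, ranking=_rank_features(scores), baseline_oob_accuracy=baselines)


def rank_kmers(
    table: MdaTable, vocab: KmerVocabulary, top: int
) -> List[Tuple[str, float, int]]:
    """Top k-mers by MDA: (k-mer string, score, 1-based rank), descending
    score with ties broken by lexicographic k-mer order."""
    if top <= 0:
        raise ValueError("top must be positive")
    if top > table.n_features:
        raise ValueError("top exceeds the number of features")
    if table.n_features != vocab.dimension:
        raise ValueError("table/vocabulary dimension mismatch")
    return [
        (vocab.kmer(int(j)), float(table.scores[j]), r + 1)
        for r, j in enumerate(table.ranking[:top])
    ]
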