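"""SNV impact scoring from k-mer importance.

A single-nucleotide variant at position p alters only the k windows that
overlap p (fewer at a sequence end). For each such window the ref k-mer is
replaced by an alt k-mer differing at exactly one position; the variant's
impact is the accumulated change in per-k-mer MDA importance across those
windows. Three aggregates are reported: the sum of |Δ MDA| (default
ranking key), the signed sum, and the mean |Δ| per contributing window.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .forest_mda import MdaTable
from .kmer_features import KmerVocabulary
from .sequence_io import VALID_BASES, GenomeSource, Variant

log = logging.getLogger(__name__)

SCORE_MODES = ("abs", "signed", "mean_abs")


@dataclass(frozen=True)
class WindowContribution:
    """One affected k-mer window; ``offset`` is the window start relative
    to the variant, in {−(k−1), …, 0}."""

    offset: int
    ref_kmer: str
    alt_kmer: str
    ref_mda: float
    alt_mda: float

    @property
    def delta(self) -> float:
        return self.alt_mda - self.ref_mda


@dataclass
class VariantScore:
    variant: Variant
    contributions: List[WindowContribution]

    @property
    def n_contributions(self) -> int:
        return len(self.contributions)

    @property
    def score_abs(self) -> float:
        return float(sum(abs(c.delta) for c in self.contributions))

    @property
    def score_signed(self) -> float:
        return float(sum(c.delta for c in self.contributions))

    @property
    def score_mean_abs(self) -> float:
        return self.score_abs / max(1, self.n_contributions)

    def score(self, mode: str = "abs") -> float:
        if mode not in SCORE_MODES:
            raise ValueError(f"score mode must be one of {SCORE_MODES}")
        return getattr(self, f"score_{mode}")


def enumerate_affected_windows(
    genome: GenomeSource, v: Variant, k: int
) -> List[Tuple[int, str, str]]:
    """Aligned (offset, ref window, alt window) triples for the up-to-k
    windows overlapping the variant.

    Windows truncated by a sequence end, and windows whose REF version
    contains a non-ACGT base, are dropped (both versions, keeping ref and
    alt sums symmetric).
    """
    if v.chrom not in genome:
        raise KeyError(f"variant {v.id} on unknown record {v.chrom!r}")
    clen = genome.length(v.chrom)
    p = v.pos0
    if not 0 <= p < clen:
        raise ValueError(f"variant {v.id} position {v.pos} outside {v.chrom}")
    out: List[Tuple[int, str, str]] = []
    for o in range(-(k - 1), 1):
        start = p + o
        if start < 0 or start + k > clen:
            continue
        ref_win = genome.fetch(v.chrom, start, start + k)
        if any(b not in VALID_BASES for b in ref_win):
            continue
        i = -o  # variant's position within the window
        alt_win = ref_win[:i] + v.alt + ref_win[i + 1 :]
        out.append((o, ref_win, alt_win))
    return out


def score_variant(
    genome: GenomeSource,
    v: Variant,
    table: MdaTable,
    vocab: KmerVocabulary,
    clamp_negative: bool = False,
) -> VariantScore:
    """Score one SNV as the accumulated MDA change over its affected
    windows. ``clamp_negative`` floors (slightly negative, permutation-
    noise) MDA values at 0 before differencing."""
    if table.n_features != vocab.dimension:
        raise ValueError("MDA table dimension does not match vocabulary")
    if genome.base_at(v.chrom, v.pos0) != v.ref:
        raise ValueError(
            f"variant {v.id}: REF {v.ref!r} does not match genome at "
            f"{v.chrom}:{v.pos}"
        )
    if v.ref == v.alt:
        return VariantScore(v, [])
    scores = np.maximum(table.scores, 0.0) if clamp_negative else table.scores
    contributions = []
    for o, ref_win, alt_win in enumerate_affected_windows(genome, v, vocab.k):
        ref_mda = float(scores[vocab.index(ref_win)])
        alt_mda = float(scores[vocab.index(alt_win)])
        contributions.append(WindowContribution(o, ref_win, alt_win, ref_mda, alt_mda))
    return VariantScore(v, contributions)


def score_variant_set(
    genome: GenomeSource,
    variants: Sequence[Variant],
    table: MdaTable,
    vocab: KmerVocabulary,
    mode: str = "abs",
    clamp_negative: bool = False,
) -> Tuple[List[VariantScore], int]:
    """Score a panel of SNVs, sorted descending by the chosen aggregate.

    Per-variant failures (REF mismatch, unknown contig) are skipped and
    counted; the skip count is returned alongside the ranked list.
    """
    if not variants:
        raise ValueError("empty variant list")
    if mode not in SCORE_MODES:
        raise ValueError(f"score mode must be one of {SCORE_MODES}")
    scored: List[VariantScore] = []
    n_skipped = 0
    for v in variants:
        try:
            scored.append(score_variant(genome, v, table, vocab, clamp_negative))
        except (ValueError, KeyError) as exc:
            log.warning("skipping variant %s: %s", v.id, exc)
            n_skipped += 1
    if not scored:
        raise ValueError("all variants were rejected")
    scored.sort(key=lambda s: -s.score(mode))
    return scored, n_skipped


def scores_to_tsv(scored: Sequence[VariantScore], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "chrom": [s.variant.chrom for s in scored],
            "pos": [s.variant.pos for s in scored],
            "id": [s.variant.id for s in scored],
            "ref": [s.variant.ref for s in scored],
            "alt": [s.variant.alt for s in scored],
            "n_windows": [s.n_contributions for s in scored],
            "score_abs": [s.score_abs for s in scored],
            "score_signed": [s.score_signed for s in scored],
            "score_mean_abs": [s.score_mean_abs for s in scored],
            "rank": np.arange(1, len(scored) + 1),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def separation_auc(a: Sequence[float], b: Sequence[float]) -> float:
    """P(random a-score > random b-score), ties counted 1/2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float((gt + 0.5 * eq) / (len(a) * len(b)))


def compare_score_distributions(
    group_a: Sequence[VariantScore],
    group_b: Sequence[VariantScore],
    mode: str = "abs",
) -> Dict[str, float]:
    """Two-group comparison of variant scores: per-group mean/median, the
    two-sided Wilcoxon rank-sum (Mann-Whitney) test, and the empirical
    separation AUC."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a = np.array([s.score(mode) for s in group_a])
    b = np.array([s.score(mode) for s in group_b])
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
        "separation_auc": separation_auc(a, b),
    }
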