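"""Seed-deterministic synthetic benchmark data with planted structure.

The generator emulates the shape of a chromatin-accessibility study:
"open" intervals are motif-enriched (each positive interval receives each
planted word with a configurable probability, mimicking DNase-seq peaks
harbouring transcription-factor binding sites), negatives are plain
background genome, the conservation track is elevated inside planted motif
spans (functional sequence under purifying selection), and two SNV panels
place "pathogenic-like" variants inside planted motifs and "normal-like"
variants in motif-free background. A truth record lists every planted
occurrence; chance background occurrences of the words are detected and
recorded separately as incidental, not scrubbed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sequence_io import (
    NEGATIVE,
    POSITIVE,
    ConservationTrack,
    GenomeSource,
    Interval,
    IntervalSet,
    Variant,
    sample_negative_intervals,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment."""

    seed: int = 0
    chrom: str = "chr1"
    genome_length: int = 200_000
    n_pos: int = 300
    n_neg: int = 300
    interval_length_range: Tuple[int, int] = (150, 300)
    motifs: Tuple[str, ...] = ("GATAAG",)
    insertion_prob: float = 0.9
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    conservation_motif_mean: float = 0.95
    conservation_background_mean: float = 0.55
    conservation_sd: float = 0.05
    n_pathogenic: int = 200
    n_normal: int = 200

    def __post_init__(self):
        if not 0.0 <= self.insertion_prob <= 1.0:
            raise ValueError("insertion_prob must be in [0, 1]")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        for m in self.motifs:
            if not set(m) <= set("ACGT"):
                raise ValueError(f"motif {m!r} not over ACGT")
            if len(m) > self.interval_length_range[0]:
                raise ValueError(f"motif {m!r} longer than the shortest interval")


@dataclass
class MotifOccurrence:
    chrom: str
    start: int  # 0-based
    word: str

    @property
    def end(self) -> int:
        return self.start + len(self.word)


@dataclass
class TruthRecord:
    """Ground truth of a simulation: planted and incidental motif sites."""

    planted: List[MotifOccurrence] = field(default_factory=list)
    incidental: List[MotifOccurrence] = field(default_factory=list)

    def motif_spans(self, include_incidental: bool = False) -> List[Tuple[str, int, int]]:
        occs = self.planted + (self.incidental if include_incidental else [])
        return [(o.chrom, o.start, o.end) for o in occs]

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(
                {
                    "planted": [
                        {"chrom": o.chrom, "start": o.start, "word": o.word}
                        for o in self.planted
                    ],
                    "incidental": [
                        {"chrom": o.chrom, "start": o.start, "word": o.word}
                        for o in self.incidental
                    ],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            planted=[MotifOccurrence(**o) for o in data["planted"]],
            incidental=[MotifOccurrence(**o) for o in data["incidental"]],
        )


def _find_all(haystack: str, needle: str) -> List[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _place_nonoverlapping(
    rng: np.random.Generator, genome_length: int, n: int, length_range: Tuple[int, int]
) -> List[Tuple[int, int]]:
    """Rejection-sample n non-overlapping intervals, sorted by start."""
    lo, hi = length_range
    placed: List[Tuple[int, int]] = []
    attempts, budget = 0, 500 * n
    while len(placed) < n:
        if attempts > budget:
            raise RuntimeError(
                f"could not place {n} intervals of {lo}-{hi} bp in {genome_length} bp"
            )
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, genome_length - length + 1))
        end = start + length
        if any(s < end and start < e for s, e in placed):
            continue
        placed.append((start, end))
    return sorted(placed)


def simulate_genome(
    config: SimConfig,
) -> Tuple[GenomeSource, IntervalSet, ConservationTrack, TruthRecord]:
    """Build the synthetic genome, labelled intervals, conservation track
    and truth record; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom
    seq = rng.choice(_BASES, size=config.genome_length, p=list(config.base_composition))

    pos_spans = _place_nonoverlapping(
        rng, config.genome_length, config.n_pos, config.interval_length_range
    )
    planted: List[MotifOccurrence] = []
    for start, end in pos_spans:
        for word in config.motifs:
            if rng.random() >= config.insertion_prob:
                continue
            offset = int(rng.integers(start, end - len(word) + 1))
            seq[offset : offset + len(word)] = np.frombuffer(
                word.encode(), dtype="S1"
            )
            planted.append(MotifOccurrence(chrom, offset, word))
    genome_str = seq.tobytes().decode("ascii")
    # a later plant may overwrite an earlier one; keep only intact entries
    planted = [
        o for o in planted if genome_str[o.start : o.end] == o.word
    ]
    genome = GenomeSource({chrom: genome_str})

    positives = IntervalSet([Interval(chrom, s, e, POSITIVE) for s, e in pos_spans])
    negatives = sample_negative_intervals(
        genome, positives, config.n_neg, seed=int(rng.integers(0, 2**31 - 1))
    )
    intervals = IntervalSet(list(positives) + list(negatives))

    planted_starts = {(o.chrom, o.start, o.word) for o in planted}
    incidental = [
        MotifOccurrence(chrom, i, word)
        for word in config.motifs
        for i in _find_all(genome_str, word)
        if (chrom, i, word) not in planted_starts
    ]

    fre = rng.normal(
        config.conservation_background_mean, config.conservation_sd, config.genome_length
    )
    for o in planted:
        fre[o.start : o.end] = rng.normal(
            config.conservation_motif_mean, config.conservation_sd, o.end - o.start
        )
    track = ConservationTrack.from_array(chrom, np.clip(fre, 0.0, 1.0))

    return genome, intervals, track, TruthRecord(planted, incidental)


def simulate_snp_panels(
    genome: GenomeSource,
    truth: TruthRecord,
    config: SimConfig,
    k: int = 6,
    seed: Optional[int] = None,
) -> Tuple[List[Variant], List[Variant]]:
    """Two SNV panels: pathogenic-like variants uniform over planted motif
    positions, normal-like variants uniform over background positions at
    least k bases away from any motif occurrence (planted or incidental).
    REF always matches the genome; ALT is uniform over the 3 other bases."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    chrom = config.chrom
    glen = genome.length(chrom)

    motif_positions = np.unique(
        np.concatenate(
            [np.arange(o.start, o.end) for o in truth.planted]
            or [np.zeros(0, dtype=np.int64)]
        )
    )
    if len(motif_positions) < config.n_pathogenic:
        raise ValueError(
            f"only {len(motif_positions)} planted motif positions; "
            f"need {config.n_pathogenic}"
        )

    excluded = np.zeros(glen, dtype=bool)
    for c, s, e in truth.motif_spans(include_incidental=True):
        excluded[max(0, s - k) : min(glen, e + k)] = True
    background_positions = np.nonzero(~excluded)[0]
    if len(background_positions) < config.n_normal:
        raise ValueError("not enough motif-free background positions")

    def _panel(positions: np.ndarray, n: int, prefix: str) -> List[Variant]:
        chosen = rng.choice(positions, size=n, replace=False)
        chosen.sort()
        panel = []
        for i, p in enumerate(chosen):
            ref = genome.base_at(chrom, int(p))
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            panel.append(Variant(chrom, int(p) + 1, ref, alt, f"{prefix}_{i + 1}"))
        return panel

    pathogenic = _panel(motif_positions, config.n_pathogenic, "path")
    normal = _panel(background_positions, config.n_normal, "norm")
    return pathogenic, normal
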