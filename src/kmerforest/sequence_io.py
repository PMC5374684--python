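"""Genomic file I/O and coordinate plumbing.

Conventions: BED, bedGraph and all internal arithmetic are 0-based
half-open; VCF positions are 1-based and converted exactly once, on read.
Sequences are uppercased on retrieval, over the alphabet {A,C,G,T,N}.
"""
from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
_LABEL_TO_INT = {POSITIVE: 1, NEGATIVE: 0}
VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared format."""


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


class GenomeSource:
    """Random access to uppercase DNA sequences keyed by record name.

    Lookup uses 0-based half-open coordinates and returns exactly
    ``end - start`` characters.
    """

    def __init__(self, records: Mapping[str, str]):
        self._records: Dict[str, str] = {
            str(name): str(seq).upper() for name, seq in records.items()
        }

    @property
    def names(self) -> List[str]:
        return list(self._records)

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def length(self, name: str) -> int:
        self._check_name(name)
        return len(self._records[name])

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self._records.items()}

    def fetch(self, name: str, start: int, end: int) -> str:
        """Return the slice [start, end) of record ``name``."""
        self._check_name(name)
        seq = self._records[name]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"slice [{start}, {end}) out of bounds for {name!r} "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    def sequence(self, name: str) -> str:
        self._check_name(name)
        return self._records[name]

    def base_at(self, name: str, pos0: int) -> str:
        """Single base at 0-based position ``pos0``."""
        return self.fetch(name, pos0, pos0 + 1)

    def _check_name(self, name: str) -> None:
        if name not in self._records:
            raise KeyError(f"unknown sequence record {name!r}")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    label: str = POSITIVE

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval {self}")
        if self.label not in _LABEL_TO_INT:
            raise ValueError(f"label must be positive/negative, got {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def label_int(self) -> int:
        return _LABEL_TO_INT[self.label]


class IntervalSet:
    """Ordered collection of labelled genomic intervals."""

    def __init__(self, intervals: Sequence[Interval] = (), n_rejected: int = 0):
        self.intervals: List[Interval] = list(intervals)
        #: intervals dropped during reading (out of genome bounds)
        self.n_rejected = n_rejected

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def subset(self, label: str) -> "IntervalSet":
        return IntervalSet([iv for iv in self.intervals if iv.label == label])

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Brute-force overlap test against every stored interval."""
        return any(
            iv.chrom == chrom and iv.start < end and start < iv.end
            for iv in self.intervals
        )


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant; ``pos`` is 1-based as in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass
class VcfReadStats:
    n_accepted: int = 0
    n_indel: int = 0
    n_ref_mismatch: int = 0
    n_other: int = 0  # symbolic alleles, non-ACGT bases, unknown chrom


class ConservationTrack:
    """Per-base conservation frequencies in [0, 1], sparse over the genome.

    Positions not covered by any span return ``default``. With the default
    of 1.0 a missing track degrades conservation-weighted counting to plain
    counting.
    """

    def __init__(self, default: float = 1.0):
        if not 0.0 <= default <= 1.0:
            raise ValueError("default must lie in [0, 1]")
        self.default = float(default)
        # chrom -> (starts, ends, list of per-span value arrays)
        self._spans: Dict[str, Tuple[np.ndarray, np.ndarray, List[np.ndarray]]] = {}
        self._building: Dict[str, List[Tuple[int, int, np.ndarray]]] = {}

    def add_span(self, chrom: str, start: int, end: int, values) -> None:
        """Register values for [start, end); scalar values are broadcast."""
        if start < 0 or end <= start:
            raise ValueError(f"bad span [{start}, {end})")
        arr = np.asarray(values, dtype=float)
        if arr.ndim == 0:
            arr = np.full(end - start, float(arr))
        elif arr.shape != (end - start,):
            raise ValueError("values length must equal span length")
        self._building.setdefault(chrom, []).append((start, end, arr))
        self._spans.pop(chrom, None)

    @classmethod
    def from_array(cls, chrom: str, values, default: float = 1.0) -> "ConservationTrack":
        track = cls(default=default)
        track.add_span(chrom, 0, len(values), values)
        return track

    def _compiled(self, chrom: str):
        if chrom not in self._spans:
            spans = sorted(self._building.get(chrom, []))
            prev_end = -1
            for s, e, _ in spans:
                if s < prev_end:
                    raise ValueError(f"overlapping track spans on {chrom}")
                prev_end = e
            starts = np.array([s for s, _, _ in spans], dtype=np.int64)
            ends = np.array([e for _, e, _ in spans], dtype=np.int64)
            self._spans[chrom] = (starts, ends, [v for _, _, v in spans])
        return self._spans[chrom]

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense values over [start, end), default-filled where uncovered."""
        if end < start:
            raise ValueError("end < start")
        out = np.full(end - start, self.default, dtype=float)
        starts, ends, arrays = self._compiled(chrom)
        if len(starts) == 0:
            return out
        lo = int(np.searchsorted(ends, start, side="right"))
        for i in range(lo, len(starts)):
            s, e = int(starts[i]), int(ends[i])
            if s >= end:
                break
            a, b = max(s, start), min(e, end)
            if a < b:
                out[a - start : b - start] = arrays[i][a - s : b - s]
        return out

    def value(self, chrom: str, pos: int) -> float:
        return float(self.values(chrom, pos, pos + 1)[0])


# ---------------------------------------------------------------------------
# readers


def read_fasta(path) -> GenomeSource:
    """Load a FASTA file (optionally gzipped) into a :class:`GenomeSource`."""
    records: Dict[str, str] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise FormatError(f"duplicate FASTA record {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq)
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSource(records)


def read_bed(path, genome: GenomeSource) -> IntervalSet:
    """Read a BED3+ file; column 4, when present, carries the class label.

    Intervals extending past the genome bounds are rejected and counted in
    ``IntervalSet.n_rejected``.
    """
    intervals: List[Interval] = []
    n_rejected = 0
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            label = fields[3] if len(fields) > 3 and fields[3] in _LABEL_TO_INT else POSITIVE
            if start < 0 or chrom not in genome or end > genome.length(chrom):
                n_rejected += 1
                continue
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            intervals.append(Interval(chrom, start, end, label))
    if not intervals:
        log.warning("no usable intervals read from %s", path)
    if n_rejected:
        log.warning("%d out-of-bounds intervals rejected from %s", n_rejected, path)
    return IntervalSet(intervals, n_rejected=n_rejected)


def read_vcf(path, genome: GenomeSource) -> Tuple[List[Variant], VcfReadStats]:
    """Read SNVs from a VCF; multi-allelic records split per alt allele.

    Indels, symbolic alleles, records on unknown contigs, and records whose
    REF disagrees with the genome are excluded and counted.
    """
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise FormatError(f"unreadable VCF {path}: {exc}") from exc
    variants: List[Variant] = []
    stats = VcfReadStats()
    for rec in reader:
        ref = rec.REF.upper()
        for alt in rec.ALT:
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1:
                stats.n_indel += 1
                continue
            if ref not in VALID_BASES or alt not in VALID_BASES:
                stats.n_other += 1
                continue
            if rec.CHROM not in genome:
                stats.n_other += 1
                continue
            if genome.base_at(rec.CHROM, rec.POS - 1) != ref:
                stats.n_ref_mismatch += 1
                continue
            variants.append(
                Variant(rec.CHROM, rec.POS, ref, alt, rec.ID or ".")
            )
            stats.n_accepted += 1
    reader.close()
    return variants, stats


def read_conservation(path, default: float = 1.0) -> ConservationTrack:
    """Read a bedGraph of per-base conservation frequencies.

    Values outside [0, 1] are clipped with a warning.
    """
    track = ConservationTrack(default=default)
    n_clipped = 0
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if not 0.0 <= value <= 1.0:
                n_clipped += 1
                value = min(1.0, max(0.0, value))
            track.add_span(fields[0], start, end, value)
    if n_clipped:
        log.warning("%d bedGraph values clipped into [0, 1] from %s", n_clipped, path)
    return track


# ---------------------------------------------------------------------------
# writers


def write_fasta(genome: GenomeSource, path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name in genome.names:
            seq = genome.sequence(name)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(intervals: IntervalSet, path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def write_bedgraph(track: ConservationTrack, path) -> None:
    """Write one bedGraph line per base (exact, format-round-trippable)."""
    with open(path, "wt") as fh:
        for chrom in sorted(track._building):
            for start, end, values in sorted(track._building[chrom]):
                for i, v in enumerate(values):
                    fh.write(f"{chrom}\t{start + i}\t{start + i + 1}\t{float(v)!r}\n")


def write_vcf(variants: Sequence[Variant], genome: GenomeSource, path) -> None:
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in genome.names:
            fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# negative sampling


def sample_negative_intervals(
    genome: GenomeSource,
    positives: IntervalSet,
    n: int,
    seed: int,
    max_n_fraction: float = 0.10,
    max_attempts_per_interval: int = 500,
    mutually_disjoint: bool = True,
) -> IntervalSet:
    """Sample ``n`` background intervals length-matched to ``positives``.

    Lengths are drawn with replacement from the positive length
    distribution; candidate placements overlapping any positive interval or
    containing more than ``max_n_fraction`` N bases are rejected and
    resampled. By default the sampled negatives are also disjoint from each
    other: on a real genome two random draws essentially never coincide,
    and on a small genome overlapping negatives would leak near-duplicate
    sequences across train/test splits. Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(positives) == 0:
        raise ValueError("need at least one positive interval to match lengths")
    rng = np.random.default_rng(seed)
    pos_lengths = np.array([iv.length for iv in positives])
    names = genome.names
    chrom_lengths = np.array([genome.length(c) for c in names], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()

    # sorted positive spans per chrom for overlap rejection
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in positives:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    starts_by_chrom = {
        c: (np.array(sorted(s for s, _ in spans)), np.array([e for _, e in sorted(spans)]))
        for c, spans in by_chrom.items()
    }

    out: List[Interval] = []
    budget = n * max_attempts_per_interval
    attempts = 0
    while len(out) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n} negative intervals after {attempts} attempts"
            )
        attempts += 1
        length = int(rng.choice(pos_lengths))
        chrom = names[int(rng.choice(len(names), p=chrom_p))]
        clen = genome.length(chrom)
        if clen < length:
            continue
        start = int(rng.integers(0, clen - length + 1))
        end = start + length
        if chrom in starts_by_chrom:
            s_arr, e_arr = starts_by_chrom[chrom]
            i = int(np.searchsorted(s_arr, end))
            if i > 0 and e_arr[:i].max() > start:
                continue
        if mutually_disjoint and any(
            iv.chrom == chrom and iv.start < end and start < iv.end for iv in out
        ):
            continue
        seq = genome.fetch(chrom, start, end)
        if seq.count("N") > max_n_fraction * length:
            continue
        out.append(Interval(chrom, start, end, NEGATIVE))
    return IntervalSet(out)
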