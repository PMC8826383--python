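"""Per-read feature extraction around target motifs.

Converts raw per-base nanopore signal events (re-squiggled currents aligned
to the reference) and per-position basecalling error records into fixed-length
windowed examples: for each motif occurrence, an ``l``-length vector per
feature covering the target base and its (l-1)/2 neighbours on each side.

Signal features are computed on median/MAD-normalized currents (per read).
Error features are the base quality and binary mismatch/insertion/deletion
indicators derived from the alignment of the basecalled read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: channel order for one-hot encoded nucleotides
ALPHABET = "ACGTN"

#: signal feature names in canonical (network input) order
CORE_SIGNAL_FEATURES = ("signal_mean", "signal_median", "signal_sd", "signal_range")
#: extended statistics kept for feature selection, not used by the default model
EXTENDED_SIGNAL_FEATURES = ("signal_skew", "signal_kurtosis", "n_signals")
ERROR_FEATURES = ("quality", "mismatch", "insertion", "deletion")

ALL_SIGNAL_FEATURES = CORE_SIGNAL_FEATURES + EXTENDED_SIGNAL_FEATURES


class DegenerateSignalError(ValueError):
    """Raised when a read's signal has zero median absolute deviation."""


class MissingEventError(ValueError):
    """Raised when a base has no signal samples."""


class CoverageGapError(KeyError):
    """Raised when a requested position is outside the read's alignment span."""


class InvalidSequenceError(ValueError):
    """Raised on characters outside the A/C/G/T/N alphabet."""


@dataclass
class RawReadEvents:
    """Re-squiggled signal events for one read.

    ``samples_per_base[i]`` holds the raw current samples assigned to
    reference position ``positions[i]``. Positions are 0-based and strictly
    increasing in the reference orientation of the read.
    """

    read_id: str
    chrom: str
    strand: str
    positions: list[int]
    bases: list[str]
    samples_per_base: list[np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.bases) == n == len(self.samples_per_base)):
            raise ValueError("positions, bases and samples_per_base must align")
        if any(b - a <= 0 for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")
        for s in self.samples_per_base:
            if len(s) == 0:
                raise MissingEventError(f"empty sample list in read {self.read_id}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def sequence(self) -> str:
        return "".join(self.bases)


@dataclass(frozen=True)
class ErrorRecord:
    """One alignment outcome for one read at one reference position."""

    read_id: str
    position: int
    status: str  # match | mismatch | deletion | insertion
    quality: float
    base: str = "N"

    def __post_init__(self) -> None:
        if self.status not in ("match", "mismatch", "deletion", "insertion"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.quality < 0:
            raise ValueError("Phred quality must be >= 0")


@dataclass(frozen=True)
class NormalizationStats:
    median: float
    mad: float


@dataclass
class ReadWindow:
    """One training/inference example: l bases of context around a target base."""

    read_id: str
    chrom: str
    strand: str
    center_position: int
    sequence: str
    features: dict[str, np.ndarray] = field(default_factory=dict)
    label: int | None = None

    @property
    def l(self) -> int:
        return len(self.sequence)


def median_mad_normalize(samples: Sequence[float]) -> tuple[np.ndarray, NormalizationStats]:
    """Median/MAD normalization of a read's raw current stream.

    Returns ``(samples - median) / MAD`` with MAD the raw median absolute
    deviation (no 1.4826 consistency constant). A zero MAD means the signal
    carries no scale information and the read is rejected.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        raise DegenerateSignalError("median absolute deviation is zero")
    return (x - med) / mad, NormalizationStats(median=med, mad=mad)


def summarize_base_signal(samples: Sequence[float], extended: bool = False) -> dict[str, float]:
    """Summary statistics of the (normalized) current samples of one base.

    Standard deviation uses the population convention (divide by n).
    With ``extended=True`` also returns skewness, kurtosis (Fisher, i.e. 0 for
    a normal distribution) and the number of signal samples.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise MissingEventError("no signal samples for base")
    out = {
        "signal_mean": float(np.mean(x)),
        "signal_median": float(np.median(x)),
        "signal_sd": float(np.std(x)),
        "signal_range": float(np.max(x) - np.min(x)),
    }
    if extended:
        sd = out["signal_sd"]
        if sd > 0:
            z = (x - out["signal_mean"]) / sd
            skew = float(np.mean(z**3))
            kurt = float(np.mean(z**4) - 3.0)
        else:
            skew, kurt = 0.0, 0.0
        out["signal_skew"] = skew
        out["signal_kurtosis"] = kurt
        out["n_signals"] = float(x.size)
    return out


def extract_error_profile(
    records: Iterable[ErrorRecord], positions: Sequence[int]
) -> dict[str, np.ndarray]:
    """Windowed error features for one read.

    For each requested position: quality of the base call (0 at deletions) and
    binary indicators for mismatch / insertion / deletion. A position with no
    record at all is a coverage gap. Insertions are attributed to the
    reference base immediately 5' of the inserted sequence, so an insertion
    record may coexist with a match/mismatch record at the same position.
    """
    by_pos: dict[int, list[ErrorRecord]] = {}
    for rec in records:
        by_pos.setdefault(rec.position, []).append(rec)

    n = len(positions)
    quality = np.zeros(n)
    mismatch = np.zeros(n)
    insertion = np.zeros(n)
    deletion = np.zeros(n)
    for i, pos in enumerate(positions):
        recs = by_pos.get(pos)
        if not recs:
            raise CoverageGapError(f"position {pos} not covered by read alignment")
        for rec in recs:
            if rec.status == "mismatch":
                mismatch[i] = 1.0
                quality[i] = rec.quality
            elif rec.status == "insertion":
                insertion[i] = 1.0
            elif rec.status == "deletion":
                deletion[i] = 1.0
                quality[i] = 0.0
            else:
                quality[i] = rec.quality
    return {"quality": quality, "mismatch": mismatch, "insertion": insertion, "deletion": deletion}


def one_hot_encode(sequence: str) -> np.ndarray:
    """l x 5 one-hot matrix over (A, C, G, T, N)."""
    idx = []
    for ch in sequence.upper():
        j = ALPHABET.find(ch)
        if j < 0:
            raise InvalidSequenceError(f"invalid nucleotide {ch!r}")
        idx.append(j)
    mat = np.zeros((len(sequence), len(ALPHABET)))
    mat[np.arange(len(sequence)), idx] = 1.0
    return mat


def find_motif_occurrences(sequence: str, motif: str, target_offset: int) -> list[int]:
    """Indices (into ``sequence``) of the target base of every motif occurrence."""
    if not 0 <= target_offset < len(motif):
        raise ValueError("target_offset must index into the motif")
    hits = []
    start = 0
    while True:
        k = sequence.find(motif, start)
        if k < 0:
            break
        hits.append(k + target_offset)
        start = k + 1
    return hits


def build_windows(
    events: RawReadEvents,
    errors: Iterable[ErrorRecord],
    motif: str = "CG",
    target_offset: int = 0,
    l: int = 17,
    label: int | None = None,
    extended: bool = False,
) -> list[ReadWindow]:
    """Emit one ReadWindow per motif occurrence with full flanking context.

    The read's whole signal stream is median/MAD-normalized first; per-base
    summaries are then computed on the normalized samples. Occurrences whose
    target base lacks (l-1)/2 neighbours on either side of the read are
    discarded (read-edge exclusion).
    """
    if l % 2 == 0:
        raise ValueError("window length l must be odd")
    flank = (l - 1) // 2

    all_samples = np.concatenate([np.asarray(s, float) for s in events.samples_per_base])
    _, stats = median_mad_normalize(all_samples)

    sig_names = ALL_SIGNAL_FEATURES if extended else CORE_SIGNAL_FEATURES
    per_base = [
        summarize_base_signal((np.asarray(s, float) - stats.median) / stats.mad, extended=extended)
        for s in events.samples_per_base
    ]
    error_list = list(errors)

    windows: list[ReadWindow] = []
    seq = events.sequence
    for center in find_motif_occurrences(seq, motif, target_offset):
        if center < flank or center + flank >= len(seq):
            continue
        sl = slice(center - flank, center + flank + 1)
        win_positions = events.positions[sl]
        feats: dict[str, np.ndarray] = {
            name: np.array([per_base[i][name] for i in range(sl.start, sl.stop)])
            for name in sig_names
        }
        feats.update(extract_error_profile(error_list, win_positions))
        windows.append(
            ReadWindow(
                read_id=events.read_id,
                chrom=events.chrom,
                strand=events.strand,
                center_position=events.positions[center],
                sequence=seq[sl],
                features=feats,
                label=label,
            )
        )
    return windows
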