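"""Synthetic nanopore reads and read scores with known ground truth.

The signal model is deliberately simple: each base identity gets a mean
current drawn once per simulation (a frozen pore table) and per-sample
Gaussian noise around it; methylation shifts the means of the centre base
and its nearest neighbours (centre +/- 2 by default) by a configurable
multiple of the per-base noise SD. Basecalling errors are independent
Bernoulli events per base per type, optionally elevated in methylated
reads to mimic the characteristic error footprint modified bases leave in
basecalled alignments. Qualities are label-conditional truncated normals.

This emulates the statistical structure the classifier assumes — shifted
current summaries and enriched error indicators around the target motif —
not the physics of a pore (no dwell times, no k-mer table, no homopolymer
artefacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .caller import PositionEvidence
from .features import ErrorRecord, RawReadEvents, ReadWindow, build_windows

BASES = "ACGT"


@dataclass
class SimulationConfig:
    l: int = 17
    n_reads: int = 1000
    coverage: int = 30
    methylation_proportion: float = 0.5
    #: shift of per-base current means (in noise-SD units) at the centre
    #: base and its +/- shift_halfwidth neighbours when methylated
    signal_shift: float = 2.0
    shift_halfwidth: int = 2
    #: per-base probability of a mismatch-or-deletion event
    error_rate_unmeth: float = 0.05
    error_rate_meth: float = 0.05
    #: mean Phred quality of correct and erroneous base calls
    quality_correct: float = 30.0
    quality_error: float = 10.0
    quality_sd: float = 3.0
    #: mean signal samples per base (minimum 3)
    samples_per_base: float = 8.0
    #: Beta shapes for direct read-score simulation
    score_shapes_meth: tuple[float, float] = (8.0, 2.0)
    score_shapes_unmeth: tuple[float, float] = (2.0, 8.0)
    motif: str = "CG"
    target_offset: int = 0
    read_pad: int = 4  # extra bases beyond the window on each side
    current_baseline: float = 90.0  # device units
    current_base_spread: float = 8.0
    current_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.methylation_proportion <= 1:
            raise ValueError("methylation_proportion must lie in [0, 1]")
        if self.signal_shift < 0:
            raise ValueError("signal_shift must be >= 0")
        for rate in (self.error_rate_unmeth, self.error_rate_meth):
            if not 0 <= rate <= 1:
                raise ValueError("error rates must lie in [0, 1]")
        if self.l % 2 == 0:
            raise ValueError("window length l must be odd")


PRESETS = {
    # strong signal shift, error channel also informative
    "separable": dict(signal_shift=2.0, error_rate_unmeth=0.05, error_rate_meth=0.20),
    # weak shift, mildly informative errors
    "hard": dict(signal_shift=0.5, error_rate_unmeth=0.05, error_rate_meth=0.08),
    # label carries no information at all
    "null": dict(signal_shift=0.0, error_rate_unmeth=0.05, error_rate_meth=0.05),
}


def preset_config(name: str, **overrides) -> SimulationConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@dataclass
class GroundTruth:
    """Per-read labels plus per-position truth derived from them."""

    read_labels: dict[str, int] = field(default_factory=dict)
    position_frequency: dict[tuple[str, str, int], float] = field(default_factory=dict)
    position_state: dict[tuple[str, str, int], str] = field(default_factory=dict)

    def record(self, read_id: str, label: int, key: tuple[str, str, int]) -> None:
        self.read_labels[read_id] = label
        self.position_frequency.setdefault(key, 0.0)

    def finalize(self, reads_at: dict[tuple[str, str, int], list[int]]) -> None:
        for key, labels in reads_at.items():
            freq = float(np.mean(labels))
            self.position_frequency[key] = freq
            self.position_state[key] = "methylated" if freq > 0 else "unmethylated"


def _pore_model(rng: np.random.Generator, cfg: SimulationConfig) -> dict[str, float]:
    """Base-identity current means, drawn once per simulation."""
    offsets = rng.uniform(-1.0, 1.0, size=4)
    return {
        base: cfg.current_baseline + cfg.current_base_spread * off
        for base, off in zip(BASES, offsets)
    }


def _read_sequence(rng: np.random.Generator, cfg: SimulationConfig, length: int) -> str:
    """Random sequence with exactly one motif occurrence, centred."""
    seq = list(rng.choice(list(BASES), size=length))
    center = length // 2
    # plant the motif so its target base sits at the centre
    start = center - cfg.target_offset
    for j, ch in enumerate(cfg.motif):
        seq[start + j] = ch
    # scrub accidental extra occurrences
    s = "".join(seq)
    k = s.find(cfg.motif)
    while k >= 0:
        if k != start:
            repl = "A" if cfg.motif[0] != "A" else "T"
            seq[k] = repl
            s = "".join(seq)
            k = s.find(cfg.motif)
        else:
            k = s.find(cfg.motif, k + 1)
    return "".join(seq)


def simulate_read(
    cfg: SimulationConfig,
    label: int,
    rng: np.random.Generator,
    pore: dict[str, float] | None = None,
    read_id: str = "read0",
    chrom: str = "sim",
    strand: str = "+",
    start: int = 0,
) -> tuple[RawReadEvents, list[ErrorRecord]]:
    """One read covering one centred motif site, with signal + error records."""
    if pore is None:
        pore = _pore_model(rng, cfg)
    length = cfg.l + 2 * cfg.read_pad
    seq = _read_sequence(rng, cfg, length)
    center = length // 2
    positions = list(range(start, start + length))

    samples_per_base = []
    for i, base in enumerate(seq):
        n = 3 + rng.poisson(max(cfg.samples_per_base - 3, 0))
        mu = pore[base]
        if label == 1 and abs(i - center) <= cfg.shift_halfwidth:
            mu += cfg.signal_shift * cfg.current_noise_sd
        samples_per_base.append(mu + cfg.current_noise_sd * rng.standard_normal(n))

    err_rate = cfg.error_rate_meth if label == 1 else cfg.error_rate_unmeth
    records = []
    for i, base in enumerate(seq):
        pos = positions[i]
        if rng.random() < err_rate:
            if rng.random() < 0.5:
                wrong = BASES[(BASES.index(base) + 1 + rng.integers(3)) % 4]
                q = max(0.0, rng.normal(cfg.quality_error, cfg.quality_sd))
                records.append(ErrorRecord(read_id, pos, "mismatch", q, wrong))
            else:
                records.append(ErrorRecord(read_id, pos, "deletion", 0.0, "N"))
        else:
            q = max(0.0, rng.normal(cfg.quality_correct, cfg.quality_sd))
            records.append(ErrorRecord(read_id, pos, "match", q, base))
        # insertions ride alongside the base call at half the error rate
        if rng.random() < err_rate / 2:
            records.append(ErrorRecord(read_id, pos, "insertion", 0.0, "N"))

    events = RawReadEvents(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        positions=positions,
        bases=list(seq),
        samples_per_base=samples_per_base,
    )
    return events, records


def simulate_dataset(
    cfg: SimulationConfig,
    balanced: bool = True,
    extended: bool = False,
) -> tuple[list[ReadWindow], GroundTruth]:
    """Simulate reads, extract windows, return them with ground truth.

    Reads are laid out over n_reads/coverage genomic sites, ``coverage``
    reads per site. With ``balanced`` the per-read labels alternate 50/50
    within each site's read stack; otherwise each read is methylated with
    probability ``methylation_proportion``.
    """
    rng = np.random.default_rng(cfg.seed)
    pore = _pore_model(rng, cfg)
    n_sites = max(1, cfg.n_reads // cfg.coverage)
    site_spacing = cfg.l + 2 * cfg.read_pad + 10

    windows: list[ReadWindow] = []
    truth = GroundTruth()
    reads_at: dict[tuple[str, str, int], list[int]] = {}
    for i in range(cfg.n_reads):
        site = i % n_sites
        start = site * site_spacing
        if balanced:
            label = i % 2
        else:
            label = int(rng.random() < cfg.methylation_proportion)
        read_id = f"r{i:06d}"
        events, records = simulate_read(
            cfg, label, rng, pore=pore, read_id=read_id, start=start
        )
        wins = build_windows(
            events, records, motif=cfg.motif, target_offset=cfg.target_offset,
            l=cfg.l, label=label, extended=extended,
        )
        for w in wins:
            key = (w.chrom, w.strand, w.center_position)
            reads_at.setdefault(key, []).append(label)
            truth.record(read_id, label, key)
        windows.extend(wins)
    truth.finalize(reads_at)
    return windows, truth


def split_dataset(
    windows: list[ReadWindow],
    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05),
    seed: int = 0,
) -> tuple[list[ReadWindow], list[ReadWindow], list[ReadWindow]]:
    """Shuffled train/validation/test split (default 90/5/5)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(windows))
    n_train = int(round(fractions[0] * len(windows)))
    n_val = int(round(fractions[1] * len(windows)))
    train = [windows[i] for i in order[:n_train]]
    val = [windows[i] for i in order[n_train : n_train + n_val]]
    test = [windows[i] for i in order[n_train + n_val :]]
    return train, val, test


def simulate_read_scores(
    n: int, component: str, shapes: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. Beta-distributed read scores for one component."""
    if component not in ("meth", "unmeth"):
        raise ValueError("component must be 'meth' or 'unmeth'")
    a, b = shapes
    if a <= 0 or b <= 0:
        raise ValueError("Beta shapes must be positive")
    return rng.beta(a, b, size=n)


def simulate_positions(
    n_positions: int,
    coverage: int,
    proportion: float,
    shapes_meth: tuple[float, float] = (8.0, 2.0),
    shapes_unmeth: tuple[float, float] = (2.0, 8.0),
    seed: int = 0,
    chrom: str = "sim",
    strand: str = "+",
) -> tuple[list[PositionEvidence], GroundTruth]:
    """Positions with round(proportion*coverage) methylated-component reads.

    Direct score-level fixture for the position callers: each position gets
    ``coverage`` read scores, the methylated fraction drawn from the
    methylated Beta component and the rest from the unmethylated one.
    """
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_meth = int(np.round(proportion * coverage))
    truth = GroundTruth()
    evidences = []
    reads_at = {}
    for p in range(n_positions):
        s_m = simulate_read_scores(n_meth, "meth", shapes_meth, rng)
        s_u = simulate_read_scores(coverage - n_meth, "unmeth", shapes_unmeth, rng)
        scores = np.concatenate([s_m, s_u])
        evidences.append(
            PositionEvidence(chrom=chrom, strand=strand, position=p, scores=scores)
        )
        key = (chrom, strand, p)
        reads_at[key] = [1] * n_meth + [0] * (coverage - n_meth)
    truth.finalize(reads_at)
    return evidences, truth
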