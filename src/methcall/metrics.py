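"""Evaluation: classification metrics, methylation-frequency accuracy,
partial-methylation mixture benchmarks and bisulfite ground-truth labeling.

Accuracy, precision, recall and F-score follow the standard confusion-table
definitions; frequency accuracy is 1 minus the L1 distance between true and
estimated per-position methylated frequencies, which penalizes read-level
false positives and false negatives symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

#: sentinel for metrics whose denominator is zero
UNDEFINED = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_calls(cls, labels: np.ndarray, calls: np.ndarray) -> "ConfusionCounts":
        labels = np.asarray(labels).astype(int)
        calls = np.asarray(calls).astype(int)
        return cls(
            tp=int(np.sum((labels == 1) & (calls == 1))),
            tn=int(np.sum((labels == 0) & (calls == 0))),
            fp=int(np.sum((labels == 0) & (calls == 1))),
            fn=int(np.sum((labels == 1) & (calls == 0))),
        )


@dataclass
class MetricsReport:
    accuracy: float | None = UNDEFINED
    precision: float | None = UNDEFINED
    recall: float | None = UNDEFINED
    f_score: float | None = UNDEFINED
    auc: float | None = UNDEFINED
    l1_accuracy: float | None = UNDEFINED
    pearson_r: float | None = UNDEFINED

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, F-score; undefined metrics stay None."""
    rep = MetricsReport()
    if c.total > 0:
        rep.accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fp > 0:
        rep.precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn > 0:
        rep.recall = c.tp / (c.tp + c.fn)
    if rep.precision is not None and rep.recall is not None and rep.precision + rep.recall > 0:
        rep.f_score = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
    return rep


def methylated_frequency(calls: np.ndarray) -> float:
    """Fraction of reads at a position called methylated."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("no reads at position")
    return float(np.mean(calls))


def l1_meth_accuracy(true_freq: float, est_freq: float) -> float:
    """1 - |true - estimated| methylated frequency; symmetric, in [0, 1]."""
    if not (0 <= true_freq <= 1 and 0 <= est_freq <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    return 1.0 - abs(true_freq - est_freq)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Area under the ROC curve; None when only one class is present.

    Equivalent to the tie-corrected Mann-Whitney U statistic normalized by
    n_pos * n_neg.
    """
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        return UNDEFINED
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def label_from_bisulfite(rep1_pct: float, rep2_pct: float) -> str:
    """Bisulfite ground-truth rule: methylated iff both replicates show >90%
    methylation; unmethylated iff both show exactly 0%; otherwise excluded."""
    for pct in (rep1_pct, rep2_pct):
        if not 0 <= pct <= 100:
            raise ValueError("bisulfite percentages must lie in [0, 100]")
    if rep1_pct > 90 and rep2_pct > 90:
        return "methylated"
    if rep1_pct == 0 and rep2_pct == 0:
        return "unmethylated"
    return "excluded"


@dataclass(frozen=True)
class MixtureDatasetSpec:
    proportions: tuple[float, ...] = tuple(np.round(np.arange(0, 1.05, 0.1), 1))
    reads_per_dataset: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.proportions):
            raise ValueError("proportions must lie in [0, 1]")


@dataclass
class MixtureDataset:
    """One partially methylated benchmark set: sampled reads plus the labels
    recording which pool each came from."""

    proportion: float
    reads: list
    labels: np.ndarray

    @property
    def true_frequency(self) -> float:
        return float(np.mean(self.labels))


def build_mixture_datasets(
    meth_pool: list, unmeth_pool: list, spec: MixtureDatasetSpec
) -> list[MixtureDataset]:
    """Sample partially methylated benchmark datasets from two read pools.

    Dataset k holds round(p_k * n) reads drawn without replacement from the
    methylated pool and n - round(p_k * n) from the unmethylated pool
    (banker's rounding). Each dataset is an independent seeded draw; no read
    appears twice within a dataset.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.reads_per_dataset
    datasets = []
    for p in spec.proportions:
        n_meth = int(np.round(p * n))  # round-half-even
        n_unmeth = n - n_meth
        if n_meth > len(meth_pool) or n_unmeth > len(unmeth_pool):
            raise ValueError(f"pool exhausted at proportion {p}")
        idx_m = rng.choice(len(meth_pool), size=n_meth, replace=False)
        idx_u = rng.choice(len(unmeth_pool), size=n_unmeth, replace=False)
        reads = [meth_pool[i] for i in idx_m] + [unmeth_pool[i] for i in idx_u]
        labels = np.concatenate([np.ones(n_meth, int), np.zeros(n_unmeth, int)])
        datasets.append(MixtureDataset(proportion=float(p), reads=reads, labels=labels))
    return datasets


def frequency_correlation(
    est_freqs: np.ndarray, ref_freqs: np.ndarray
) -> tuple[float | None, float | None, float]:
    """(Pearson r, r^2, RMSE) between estimated and reference per-position
    methylation frequencies; r is None for constant input vectors."""
    est = np.asarray(est_freqs, dtype=float)
    ref = np.asarray(ref_freqs, dtype=float)
    if est.size != ref.size or est.size < 3:
        raise ValueError("need >= 3 paired positions")
    rmse = float(np.sqrt(np.mean((est - ref) ** 2)))
    if np.std(est) == 0 or np.std(ref) == 0:
        return UNDEFINED, UNDEFINED, rmse
    r = float(np.corrcoef(est, ref)[0, 1])
    return r, r * r, rmse


def filter_positions_by_regions(
    calls: pd.DataFrame, regions: list[tuple[str, int, int]]
) -> pd.DataFrame:
    """Keep position calls whose start falls inside any (chrom, start, end)
    half-open region; plumbing for region-restricted evaluation."""
    mask = np.zeros(len(calls), dtype=bool)
    for chrom, start, end in regions:
        mask |= (
            (calls["chrom"] == chrom) & (calls["start"] >= start) & (calls["start"] < end)
        ).to_numpy()
    return calls[mask].reset_index(drop=True)
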