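"""Incremental feature selection and genome-partition cross-validation folds."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

#: the 11 candidate features ranked for selection: 7 sequence + 4 error
DEFAULT_CANDIDATES = (
    "signal_mean",
    "signal_median",
    "signal_sd",
    "signal_range",
    "signal_skew",
    "signal_kurtosis",
    "n_signals",
    "quality",
    "mismatch",
    "deletion",
    "insertion",
)


def incremental_feature_selection(
    candidates: Sequence[str],
    evaluator: Callable[[tuple[str, ...]], float],
) -> list[str]:
    """Greedy forward pass over a ranked candidate list.

    Starting from the top-ranked feature, each next candidate is added and the
    (cross-validated) evaluator score recomputed; a candidate that decreases
    the score is excluded from subsequent runs. Returns the retained subset in
    rank order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    selected = [candidates[0]]
    best = evaluator(tuple(selected))
    for cand in candidates[1:]:
        trial = evaluator(tuple(selected + [cand]))
        if trial >= best:
            selected.append(cand)
            best = trial
    return selected


def cross_validated_evaluator(
    feature_matrix: Callable[[tuple[str, ...]], np.ndarray],
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> Callable[[tuple[str, ...]], float]:
    """k-fold CV accuracy of a logistic model on a feature subset.

    A lightweight stand-in evaluator for ranking feature subsets without
    training the full network per subset; the selection operation itself is
    evaluator-agnostic.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)

    def evaluate(subset: tuple[str, ...]) -> float:
        X = feature_matrix(subset)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(X, labels):
            clf = LogisticRegression(max_iter=200)
            clf.fit(X[tr], labels[tr])
            accs.append(float(clf.score(X[te], labels[te])))
        return float(np.mean(accs))

    return evaluate


#: the five genome sections used for chromosome-scale cross-validation on
#: the ~4.7 Mb E. coli genome (half-open intervals)
ECOLI_FOLD_SECTIONS = (
    (0, 1_000_000),
    (1_000_000, 2_000_000),
    (2_000_000, 3_000_000),
    (3_000_000, 4_000_000),
    (4_000_000, 4_700_000),
)


def split_genome_folds(
    regions: Sequence[tuple[int, int]] = ECOLI_FOLD_SECTIONS,
) -> Callable[[int], int]:
    """Map a genomic position to a 1-based fold index by half-open interval.

    Train/test folds built from the returned assignment are position-disjoint
    by construction. Positions outside every interval raise KeyError.
    """
    regions = list(regions)
    for (s1, e1) in regions:
        if e1 <= s1:
            raise ValueError("empty interval")
    for i, (s1, e1) in enumerate(regions):
        for s2, e2 in regions[i + 1 :]:
            if s1 < e2 and s2 < e1:
                raise ValueError("overlapping intervals")

    def assign(position: int) -> int:
        for i, (start, end) in enumerate(regions):
            if start <= position < end:
                return i + 1
        raise KeyError(f"position {position} outside all fold intervals")

    return assign
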