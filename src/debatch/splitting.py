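"""Batch-disjoint, class-stratified repeated holdout.

Whole batches are assigned to train/valid/test so that a sample's split
membership is fully determined by its batch; assignments greedily keep
per-class sample proportions close to the global ones, and the test set
is resampled on every repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_data import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HoldoutSplit:
    """One batch-disjoint (train, valid, test) partition of batches."""

    train_batches: frozenset
    valid_batches: frozenset
    test_batches: frozenset
    repeat_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        sets = (self.train_batches, self.valid_batches, self.test_batches)
        for s in sets:
            if not s:
                raise ValueError("no split set may be empty")
        if (
            self.train_batches & self.valid_batches
            or self.train_batches & self.test_batches
            or self.valid_batches & self.test_batches
        ):
            raise ValueError("split batch sets must be pairwise disjoint")


def _class_proportions(m: OmicsMatrix, batches: Sequence) -> np.ndarray:
    """Per-class sample proportions over non-QC samples of the given batches."""
    classes = m.classes
    mask = np.isin(m.batch_labels, list(batches)) & ~m.qc_flags
    counts = np.array(
        [np.sum(m.class_labels[mask] == c) for c in classes], dtype=np.float64
    )
    total = counts.sum()
    return counts / total if total > 0 else counts


def _divergence(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.abs(p - q).sum())


def repeated_holdout(
    m: OmicsMatrix,
    n_repeats: int = 5,
    valid_frac: float = 0.2,
    test_frac: float = 0.2,
    seed: int = 0,
) -> list[HoldoutSplit]:
    """Produce `n_repeats` batch-disjoint, class-stratified splits.

    With exactly three batches and three repeats, the three rotations in
    which each batch serves once as train, valid and test are returned.
    Otherwise each repeat draws a pool of seeded random whole-batch
    assignments and keeps the one whose per-set class proportions diverge
    least from the global proportions.
    """
    batches = m.batches
    K = len(batches)
    if K < 3:
        raise ValueError(
            f"repeated holdout requires >= 3 batches so each split set is "
            f"non-empty; got K={K}"
        )
    if not (0 < valid_frac < 1 and 0 < test_frac < 1 and valid_frac + test_frac < 1):
        raise ValueError("fractions must lie in (0, 1) and sum to < 1")

    if K == 3:
        # each batch serves once as train, once as valid, once as test
        splits = []
        for r in range(n_repeats):
            splits.append(
                HoldoutSplit(
                    train_batches=frozenset([batches[r % 3]]),
                    valid_batches=frozenset([batches[(r + 1) % 3]]),
                    test_batches=frozenset([batches[(r + 2) % 3]]),
                    repeat_index=r,
                    seed=seed,
                )
            )
        return splits

    n_valid = max(1, round(valid_frac * K))
    n_test = max(1, round(test_frac * K))
    if n_valid + n_test >= K:
        n_valid = n_test = 1
    n_train = K - n_valid - n_test
    global_props = _class_proportions(m, batches)

    splits: list[HoldoutSplit] = []
    n_candidates = 50
    for r in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        best_assign, best_score = None, np.inf
        for _ in range(n_candidates):
            order = list(batches)
            rng.shuffle(order)
            assign = (
                order[:n_train],
                order[n_train : n_train + n_valid],
                order[n_train + n_valid :],
            )
            score = sum(
                _divergence(_class_proportions(m, part), global_props)
                for part in assign
            )
            if score < best_score - 1e-12:
                best_assign, best_score = assign, score
        splits.append(
            HoldoutSplit(
                train_batches=frozenset(best_assign[0]),
                valid_batches=frozenset(best_assign[1]),
                test_batches=frozenset(best_assign[2]),
                repeat_index=r,
                seed=seed,
            )
        )
    return splits


def materialize(
    split: HoldoutSplit, m: OmicsMatrix
) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix]:
    """Row-subset the matrix into (train, valid, test) views by batch."""
    known = set(m.batches)
    for b in split.train_batches | split.valid_batches | split.test_batches:
        if b not in known:
            raise ValueError(f"unknown batch in split: {b!r}")
    views = []
    for batch_set in (split.train_batches, split.valid_batches, split.test_batches):
        mask = np.isin(m.batch_labels, list(batch_set))
        view = m.subset(mask)
        missing = set(m.classes) - set(view.classes)
        if missing:
            logger.warning(
                "classes %s present in full data but absent from a split view",
                sorted(missing, key=str),
            )
        views.append(view)
    return tuple(views)  # type: ignore[return-value]
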