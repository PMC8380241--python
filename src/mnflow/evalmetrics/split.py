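"""Seeded train/test splitting, optionally stratified by class."""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np


def split_train_test(
    records: Sequence,
    fraction: float = 0.60,
    stratify: Sequence | None = None,
    seed: int = 0,
):
    """Randomly split records into (train, test) with ``fraction`` in train.

    When ``stratify`` labels are given, the split is per class with the
    training count rounded to the nearest record, so per-class proportions
    are within one record of the target. A class with fewer than 2 records
    goes entirely to train (with a warning). Disjoint and exhaustive;
    deterministic for a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = len(records)
    rng = np.random.default_rng(seed)
    if stratify is None:
        order = rng.permutation(n)
        n_train = int(round(fraction * n))
        train_idx = np.sort(order[:n_train])
        test_idx = np.sort(order[n_train:])
    else:
        labels = np.asarray([int(l) for l in stratify])
        if labels.shape[0] != n:
            raise ValueError("stratify labels must match records length")
        train_parts, test_parts = [], []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if idx.size < 2:
                warnings.warn(
                    f"class {cls} has {idx.size} record(s); assigning to train"
                )
                train_parts.append(idx)
                continue
            perm = rng.permutation(idx)
            k = int(round(fraction * idx.size))
            k = min(max(k, 1), idx.size - 1)  # both sides non-empty per class
            train_parts.append(perm[:k])
            test_parts.append(perm[k:])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], int)
    train = [records[i] for i in train_idx]
    test = [records[i] for i in test_idx]
    return train, test
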