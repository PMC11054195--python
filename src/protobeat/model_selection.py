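"""Stratified train/validation/test splitting of beat datasets."""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.model_selection import train_test_split

from .data import LabeledSequence


def split_dataset(
    data: list[LabeledSequence],
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int | None = 0,
) -> tuple[list[LabeledSequence], list[LabeledSequence], list[LabeledSequence]]:
    """Stratified random split into (train, val, test) at the given fractions.

    Subsets are disjoint and their union is the input. Classes with fewer than
    3 members cannot be stratified across three subsets; a warning is issued
    and the split falls back to unstratified for everyone.
    """
    if len(data) < 10:
        raise ValueError(f"need at least 10 sequences to split, got {len(data)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    y = np.array([s.label for s in data])
    idx = np.arange(len(data))
    counts = np.bincount(y)
    stratify = y
    if counts[counts > 0].min() < 3:
        warnings.warn(
            "a class has fewer than 3 members; splitting without stratification",
            UserWarning,
        )
        stratify = None
    f_train, f_val, f_test = fractions
    n_test = int(round(len(data) * f_test))
    n_val = int(round(len(data) * f_val))
    idx_trval, idx_test = train_test_split(
        idx, test_size=n_test, random_state=seed, stratify=stratify
    )
    strat2 = y[idx_trval] if stratify is not None else None
    idx_train, idx_val = train_test_split(
        idx_trval, test_size=n_val, random_state=seed, stratify=strat2
    )
    pick = lambda ii: [data[i] for i in ii]
    return pick(idx_train), pick(idx_val), pick(idx_test)
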