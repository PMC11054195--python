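"""Prototype layer and linear classifier head.

Class scores are linear in the similarities s_k = exp(-d_k) between the pooled
embedding and K learnable prototype vectors; d_k is the Euclidean distance in
latent space (squared-distance variant available behind a flag). Because the
map from similarities to logits is a plain matrix product z = W s, each
prototype's contribution W[c, k] * s_k to a class logit is exactly additive —
the property the explanation reports rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PrototypeMeta:
    """Bookkeeping attached to one prototype vector."""

    provenance: str = "learned"  # "learned" | "expert"
    validated: bool = False
    frozen: bool = False
    exemplar_id: str | None = None


@dataclass
class PrototypeSet:
    """K latent prototype vectors plus per-prototype metadata."""

    vectors: np.ndarray  # (K, u)
    meta: list[PrototypeMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        if self.vectors.shape[0] < 1 or not np.all(np.isfinite(self.vectors)):
            raise ValueError("prototype set needs >= 1 finite vector")
        if not self.meta:
            self.meta = [PrototypeMeta() for _ in range(self.vectors.shape[0])]
        if len(self.meta) != self.vectors.shape[0]:
            raise ValueError("metadata length must match prototype count")

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    @property
    def frozen_mask(self) -> np.ndarray:
        return np.array([m.frozen for m in self.meta], dtype=bool)


@dataclass
class Prediction:
    """Full forward-pass output kept for interpretation."""

    logits: np.ndarray      # (C,)
    probs: np.ndarray       # (C,)
    label: int
    distances: np.ndarray   # (K,)
    similarities: np.ndarray  # (K,)
    attention: np.ndarray   # (T,)
    embedding: np.ndarray   # (u,)


def prototype_distances(e: np.ndarray, P: PrototypeSet | np.ndarray,
                        squared: bool = False) -> np.ndarray:
    """Distance from one embedding to every prototype (unsquared L2 by default)."""
    vectors = P.vectors if isinstance(P, PrototypeSet) else np.atleast_2d(np.asarray(P, float))
    e = np.asarray(e, dtype=np.float64)
    if e.ndim != 1 or e.shape[0] != vectors.shape[1]:
        raise ValueError(f"embedding dim {e.shape} does not match prototypes {vectors.shape}")
    diff = vectors - e
    d2 = np.einsum("ku,ku->k", diff, diff)
    return d2 if squared else np.sqrt(d2)


def similarities(d: np.ndarray) -> np.ndarray:
    """Map distances to similarities s = exp(-d) in (0, 1], order-reversing."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return np.exp(-d)


def classify(s: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Logits z = W s over prototype similarities."""
    s = np.asarray(s, dtype=np.float64)
    W = np.atleast_2d(np.asarray(W, dtype=np.float64))
    if W.shape[1] != s.shape[0]:
        raise ValueError(f"head has {W.shape[1]} columns but got {s.shape[0]} similarities")
    return W @ s


def prototype_class_labels(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each prototype the class whose head weight on it is largest.

    Ties break toward the lowest class index (argmax convention). Returns
    (labels (K,), degenerate (K,) bool) where degenerate flags all-zero columns.
    """
    W = np.atleast_2d(np.asarray(W, dtype=np.float64))
    labels = np.argmax(W, axis=0)
    degenerate = np.all(W == 0.0, axis=0)
    return labels, degenerate
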