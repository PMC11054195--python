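"""The four-term training objective.

total = CE + lambda * R_div + lambda1 * R1 + lambda2 * R2

- CE: cross-entropy of the softmax class probabilities, summed over the batch.
- R_div: sigmoid(threshold - min pairwise squared prototype distance); pushes
  prototypes apart until their closest pair is at least sqrt(threshold) apart.
- R1 (prototypicality): sum over prototypes of the squared distance to the
  nearest encoded instance; keeps every prototype near real data.
- R2 (clustering): sum over instances of the squared distance to the nearest
  prototype; pulls embeddings into clusters around prototypes.

Each regulariser exposes value + analytic (sub)gradient; argmin selections use
the first minimiser, which is a valid subgradient at ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._network import sigmoid
from .prototypes import PrototypeSet

_EPS = 1e-12


@dataclass
class LossWeights:
    """Mixing weights of the composite objective."""

    lam_diversity: float = 0.01
    lam_prototypicality: float = 0.05
    lam_clustering: float = 0.05
    diversity_threshold: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lam_diversity, self.lam_prototypicality, self.lam_clustering) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    ce: float
    r_div: float
    r1: float
    r2: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {"ce": self.ce, "r_div": self.r_div, "r1": self.r1, "r2": self.r2,
                "total": self.total}


def _vectors(P) -> np.ndarray:
    return P.vectors if isinstance(P, PrototypeSet) else np.atleast_2d(np.asarray(P, float))


def diversity_loss(P, threshold: float = 1.0) -> float:
    """sigmoid(threshold - min_{i<j} ||p_i - p_j||^2); 0 when only one prototype exists."""
    vec = _vectors(P)
    if vec.shape[0] < 2:
        return 0.0
    d2 = _pairwise_sq(vec)
    iu = np.triu_indices(vec.shape[0], k=1)
    return float(sigmoid(np.array(threshold - d2[iu].min()))[()])


def diversity_loss_grad(P, threshold: float = 1.0) -> tuple[float, np.ndarray]:
    """Value and subgradient w.r.t. the prototype matrix (only the closest pair moves)."""
    vec = _vectors(P)
    grad = np.zeros_like(vec)
    if vec.shape[0] < 2:
        return 0.0, grad
    d2 = _pairwise_sq(vec)
    iu = np.triu_indices(vec.shape[0], k=1)
    flat = d2[iu]
    kmin = int(np.argmin(flat))
    i, j = iu[0][kmin], iu[1][kmin]
    value = float(sigmoid(np.array(threshold - flat[kmin]))[()])
    coef = -value * (1.0 - value) * 2.0
    grad[i] = coef * (vec[i] - vec[j])
    grad[j] = -grad[i]
    return value, grad


def prototypicality_loss(P, E: np.ndarray) -> float:
    """Sum over prototypes of squared distance to the nearest embedding."""
    return prototypicality_loss_grad(P, E)[0]


def prototypicality_loss_grad(P, E: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Returns (value, grad wrt P, grad wrt E)."""
    vec = _vectors(P)
    E = np.atleast_2d(np.asarray(E, dtype=np.float64))
    if E.shape[0] == 0:
        raise ValueError("prototypicality loss needs at least one embedding")
    d2 = _cross_sq(vec, E)  # (K, N)
    nearest = np.argmin(d2, axis=1)
    value = float(d2[np.arange(vec.shape[0]), nearest].sum())
    gradP = 2.0 * (vec - E[nearest])
    gradE = np.zeros_like(E)
    np.add.at(gradE, nearest, -gradP)
    return value, gradP, gradE


def clustering_loss(P, E: np.ndarray) -> float:
    """Sum over embeddings of squared distance to the nearest prototype."""
    return clustering_loss_grad(P, E)[0]


def clustering_loss_grad(P, E: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Returns (value, grad wrt P, grad wrt E)."""
    vec = _vectors(P)
    if vec.shape[0] == 0:
        raise ValueError("clustering loss needs at least one prototype")
    E = np.atleast_2d(np.asarray(E, dtype=np.float64))
    if E.shape[0] == 0:
        raise ValueError("clustering loss needs at least one embedding")
    d2 = _cross_sq(vec, E)  # (K, N)
    nearest = np.argmin(d2, axis=0)
    value = float(d2[nearest, np.arange(E.shape[0])].sum())
    gradE = 2.0 * (E - vec[nearest])
    gradP = np.zeros_like(vec)
    np.add.at(gradP, nearest, -gradE)
    return value, gradP, gradE


def cross_entropy(y_true: np.ndarray, probs: np.ndarray, reduction: str = "sum") -> float:
    """Negative log-likelihood of the true classes under predicted probabilities.

    probs rows are clipped to [eps, 1-eps] before the log; reduction is "sum"
    over the mini-batch as printed (a "mean" variant is available).
    """
    y_true = np.atleast_1d(np.asarray(y_true, dtype=np.int64))
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    C = probs.shape[1]
    if np.any(y_true < 0) or np.any(y_true >= C):
        raise ValueError(f"labels must lie in [0, {C}), got range "
                         f"[{y_true.min()}, {y_true.max()}]")
    p = np.clip(probs[np.arange(y_true.size), y_true], _EPS, 1.0 - _EPS)
    nll = -np.log(p)
    if reduction == "sum":
        return float(nll.sum())
    if reduction == "mean":
        return float(nll.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def total_loss(ce: float, r_div: float, r1: float, r2: float,
               weights: LossWeights) -> LossBreakdown:
    """Combine the four terms with the configured weights."""
    total = (ce + weights.lam_diversity * r_div
             + weights.lam_prototypicality * r1 + weights.lam_clustering * r2)
    return LossBreakdown(ce=ce, r_div=r_div, r1=r1, r2=r2, total=total)


def _pairwise_sq(V: np.ndarray) -> np.ndarray:
    diff = V[:, None, :] - V[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _cross_sq(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    diff = A[:, None, :] - B[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)
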