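"""Scikit-learn style estimator wrapping the prototype sequence network.

``PrototypeSequenceClassifier`` frames each raw series into ``n_steps`` equal
chunks, encodes them with a stacked bidirectional LSTM, attention-pools the
per-step states into one embedding, and classifies via similarities to K
learnable prototypes through a linear head. Training minimises cross-entropy
plus diversity / prototypicality / clustering regularisers with Adam, keeping
the parameter state with the best validation accuracy.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import _network
from .encoding import segment_batch
from .objectives import (
    LossBreakdown,
    LossWeights,
    clustering_loss_grad,
    cross_entropy,
    diversity_loss_grad,
    prototypicality_loss_grad,
    total_loss,
)
from .prototypes import Prediction, PrototypeMeta, PrototypeSet


def batch_loss_and_grads(
    params: dict[str, np.ndarray],
    Xf: np.ndarray,
    y: np.ndarray,
    n_layers: int,
    bidirectional: bool,
    weights: LossWeights,
    *,
    attention_tanh: bool = False,
    squared_distance: bool = False,
    ce_reduction: str = "sum",
    dropout: float = 0.0,
    drop_rng: np.random.Generator | None = None,
    extra_reg_embeddings: np.ndarray | None = None,
) -> tuple[LossBreakdown, dict[str, np.ndarray]]:
    """One full forward + analytic backward pass on a framed mini-batch.

    Xf: (B, T, n) frames, y: (B,) integer labels. Returns the loss breakdown
    and a gradient dict aligned with ``params``. ``extra_reg_embeddings`` are
    treated as constants appended to the batch embeddings when computing the
    prototypicality/clustering terms (full-training-set variant).
    """
    B = Xf.shape[0]
    H, enc_caches = _network.encoder_forward(params, Xf, n_layers, bidirectional)
    alpha, e, att_cache = _network.attention_forward(
        H, params["att_W"], params["att_b"], params["att_V"], attention_tanh
    )
    if dropout > 0.0 and drop_rng is not None:
        mask = (drop_rng.random(e.shape) >= dropout) / (1.0 - dropout)
        e_cls = e * mask
    else:
        mask = None
        e_cls = e
    d, s, z, proto_cache = _network.prototype_forward(
        e_cls, params["proto"], params["head"], squared_distance
    )
    probs = _network.softmax(z, axis=1)
    ce = cross_entropy(y, probs, ce_reduction)

    E_reg = e if extra_reg_embeddings is None else np.vstack([e, extra_reg_embeddings])
    r_div, gP_div = diversity_loss_grad(params["proto"], weights.diversity_threshold)
    r1, gP_r1, gE_r1 = prototypicality_loss_grad(params["proto"], E_reg)
    r2, gP_r2, gE_r2 = clustering_loss_grad(params["proto"], E_reg)
    breakdown = total_loss(ce, r_div, r1, r2, weights)

    # ---- backward ----
    dz = probs.copy()
    dz[np.arange(B), y] -= 1.0
    if ce_reduction == "mean":
        dz /= B
    de_cls, dP_sim, dW_head = _network.prototype_backward(dz, proto_cache)
    de = de_cls * mask if mask is not None else de_cls
    de = de + weights.lam_prototypicality * gE_r1[:B] + weights.lam_clustering * gE_r2[:B]
    dP = (dP_sim + weights.lam_diversity * gP_div
          + weights.lam_prototypicality * gP_r1 + weights.lam_clustering * gP_r2)
    dH, dattW, dattb, dattV = _network.attention_backward(de, att_cache)
    grads = _network.encoder_backward(dH, enc_caches, n_layers, bidirectional)
    grads.update({"att_W": dattW, "att_b": dattb, "att_V": dattV,
                  "proto": dP, "head": dW_head})
    return breakdown, grads


class PrototypeSequenceClassifier(ClassifierMixin, BaseEstimator):
    """Interpretable prototype-based classifier for fixed-length time series.

    Parameters
    ----------
    n_steps : int, default=30
        Number of equal-length frames each series is split into (T).
    hidden_size : int, default=16
        LSTM units per direction; the embedding dimension is
        ``hidden_size * 2`` when bidirectional.
    n_layers : int, default=3
        Stacked LSTM layers.
    bidirectional : bool, default=True
        Concatenate a time-reversed pass per layer.
    attention_dim : int, default=16
        Width of the additive-attention scoring layer.
    attention_tanh : bool, default=False
        Insert a tanh in the attention score (conventional additive form);
        off by default, matching the plain affine score.
    n_prototypes : int, default=12
        Number of prototype vectors K.
    dropout : float, default=0.1
        Dropout on the pooled embedding feeding the prototype/classifier path
        (training only).
    squared_distance : bool, default=False
        Use squared L2 for the prototype distance instead of plain L2.
    learning_rate : float, default=0.002
        Adam step size.
    batch_size : int, default=128
        Mini-batch size.
    max_epochs : int, default=30
        Training epochs; the parameters with best validation accuracy are kept.
    lam_diversity, lam_prototypicality, lam_clustering : float
        Regulariser weights (defaults 0.01, 0.05, 0.05).
    diversity_threshold : float, default=1.0
        Squared-distance threshold inside the diversity sigmoid.
    ce_reduction : {"sum", "mean"}, default="sum"
        Cross-entropy reduction over the mini-batch.
    full_set_regularizers : bool, default=False
        Evaluate R1/R2 against all training embeddings each step (recomputed
        per epoch, non-batch embeddings as constants) instead of batch-only.
    grad_clip : float, default=5.0
        Global-norm gradient clip; 0 disables.
    validation_fraction : float, default=0.1
        Fraction of the training data held out for model selection when no
        explicit validation set is passed to :meth:`fit`.
    random_state : int or None
        Seed for initialisation, splitting, batching and dropout.
    """

    def __init__(
        self,
        n_steps: int = 30,
        hidden_size: int = 16,
        n_layers: int = 3,
        bidirectional: bool = True,
        attention_dim: int = 16,
        attention_tanh: bool = False,
        n_prototypes: int = 12,
        dropout: float = 0.1,
        squared_distance: bool = False,
        learning_rate: float = 0.002,
        batch_size: int = 128,
        max_epochs: int = 30,
        lam_diversity: float = 0.01,
        lam_prototypicality: float = 0.05,
        lam_clustering: float = 0.05,
        diversity_threshold: float = 1.0,
        ce_reduction: str = "sum",
        full_set_regularizers: bool = False,
        grad_clip: float = 5.0,
        validation_fraction: float = 0.1,
        random_state: int | None = None,
    ):
        self.n_steps = n_steps
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.bidirectional = bidirectional
        self.attention_dim = attention_dim
        self.attention_tanh = attention_tanh
        self.n_prototypes = n_prototypes
        self.dropout = dropout
        self.squared_distance = squared_distance
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.lam_diversity = lam_diversity
        self.lam_prototypicality = lam_prototypicality
        self.lam_clustering = lam_clustering
        self.diversity_threshold = diversity_threshold
        self.ce_reduction = ce_reduction
        self.full_set_regularizers = full_set_regularizers
        self.grad_clip = grad_clip
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y, validation_data: tuple[np.ndarray, np.ndarray] | None = None):
        """Train from scratch on (N, L) series X with integer/str labels y."""
        X, y_idx = self._validate_Xy(X, y, fit=True)
        self._init_state(X, y_idx)
        self._train_loop(X, y_idx, self.max_epochs, validation_data)
        return self

    def fine_tune(self, X, y, epochs: int,
                  validation_data: tuple[np.ndarray, np.ndarray] | None = None):
        """Continue training the already-fitted model; frozen prototypes stay fixed."""
        check_is_fitted(self, "params_")
        X, y_idx = self._validate_Xy(X, y, fit=False)
        if epochs > 0:
            self._train_loop(X, y_idx, epochs, validation_data)
        return self

    def _validate_Xy(self, X, y, fit: bool):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (n_samples, series_length) array")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if X.shape[1] < self.n_steps:
            raise ValueError(
                f"series length {X.shape[1]} shorter than n_steps={self.n_steps}"
            )
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if fit:
            self.classes_, y_idx = np.unique(y, return_inverse=True)
            if self.classes_.size < 2:
                raise ValueError("need at least two classes")
            self.n_features_in_ = X.shape[1]
        else:
            lookup = {c: i for i, c in enumerate(self.classes_)}
            try:
                y_idx = np.array([lookup[v] for v in y], dtype=np.int64)
            except KeyError as exc:  # pragma: no cover - defensive
                raise ValueError(f"unseen label {exc.args[0]!r}") from exc
        return X, np.asarray(y_idx, dtype=np.int64)

    def _init_state(self, X: np.ndarray, y_idx: np.ndarray) -> None:
        ss = np.random.SeedSequence(self.random_state)
        init_ss, proto_ss, self._shuffle_ss, self._drop_ss, self._split_ss = ss.spawn(5)
        rng = np.random.default_rng(init_ss)
        n_frame = X.shape[1] // self.n_steps
        self.params_ = _network.init_params(
            n_frame, self.hidden_size, self.n_layers, self.bidirectional,
            self.attention_dim, self.n_prototypes, self.classes_.size, rng,
        )
        self.prototypes_ = PrototypeSet(
            self.params_["proto"],
            [PrototypeMeta() for _ in range(self.n_prototypes)],
        )
        self.history_ = []
        self._epoch_offset = 0
        # prototype init: embeddings of K randomly chosen training instances
        proto_rng = np.random.default_rng(proto_ss)
        idx = proto_rng.choice(X.shape[0], size=min(self.n_prototypes, X.shape[0]),
                               replace=X.shape[0] < self.n_prototypes)
        emb = self._embed(X[idx])
        self.params_["proto"][: emb.shape[0]] = emb
        self.prototypes_.vectors = self.params_["proto"]

    def _train_loop(self, X, y_idx, epochs, validation_data):
        if validation_data is not None:
            X_val = np.asarray(validation_data[0], dtype=np.float64)
            _, yv = self._validate_Xy(X_val, validation_data[1], fit=False)
            X_tr, y_tr = X, y_idx
        elif self.validation_fraction and self.validation_fraction > 0 and X.shape[0] >= 10:
            split_seed = int(np.random.default_rng(self._split_ss).integers(2**31))
            strat = y_idx if np.min(np.bincount(y_idx)) >= 2 else None
            X_tr, X_val, y_tr, yv = train_test_split(
                X, y_idx, test_size=self.validation_fraction,
                random_state=split_seed, stratify=strat,
            )
        else:
            X_tr, y_tr = X, y_idx
            X_val, yv = X, y_idx

        weights = LossWeights(self.lam_diversity, self.lam_prototypicality,
                              self.lam_clustering, self.diversity_threshold)
        frames = segment_batch(X_tr, self.n_steps)
        opt = _network.Adam(self.params_, lr=self.learning_rate)
        shuffle_rng = np.random.default_rng(self._shuffle_ss)
        drop_rng = np.random.default_rng(self._drop_ss)
        frozen = self.prototypes_.frozen_mask
        N = frames.shape[0]
        bs = min(self.batch_size, N)

        best_acc = self._val_accuracy(X_val, yv)
        best_params = copy.deepcopy(self.params_)
        for epoch in range(epochs):
            perm = shuffle_rng.permutation(N)
            sums = np.zeros(5)
            n_batches = 0
            extra = None
            if self.full_set_regularizers:
                extra = self._embed(X_tr)
            for start in range(0, N, bs):
                take = perm[start : start + bs]
                ex = None
                if extra is not None:
                    keep = np.ones(N, dtype=bool)
                    keep[take] = False
                    ex = extra[keep]
                breakdown, grads = batch_loss_and_grads(
                    self.params_, frames[take], y_tr[take], self.n_layers,
                    self.bidirectional, weights,
                    attention_tanh=self.attention_tanh,
                    squared_distance=self.squared_distance,
                    ce_reduction=self.ce_reduction,
                    dropout=self.dropout, drop_rng=drop_rng,
                    extra_reg_embeddings=ex,
                )
                for name, val in breakdown.as_dict().items():
                    if not np.isfinite(val):
                        raise FloatingPointError(
                            f"non-finite loss term {name!r} at epoch {epoch}"
                        )
                if self.grad_clip and self.grad_clip > 0:
                    _network.clip_global_norm(grads, self.grad_clip)
                if frozen.any():
                    grads["proto"][frozen] = 0.0
                    kept = self.params_["proto"][frozen].copy()
                opt.step(self.params_, grads)
                if frozen.any():
                    self.params_["proto"][frozen] = kept  # Adam momentum must not move them
                sums += np.array(list(breakdown.as_dict().values()))
                n_batches += 1
            means = sums / n_batches
            val_acc = self._val_accuracy(X_val, yv)
            self.history_.append({
                "epoch": self._epoch_offset + epoch,
                "ce": means[0], "r_div": means[1], "r1": means[2], "r2": means[3],
                "total": means[4], "val_accuracy": val_acc,
            })
            if val_acc >= best_acc:  # ties prefer the most recent epoch
                best_acc = val_acc
                best_params = copy.deepcopy(self.params_)
        self._epoch_offset += epochs
        for k in self.params_:
            self.params_[k] = best_params[k]
        self.prototypes_.vectors = self.params_["proto"]
        self.best_validation_accuracy_ = best_acc
        return self

    def _val_accuracy(self, X_val, y_val_idx) -> float:
        z = self._logits(self._embed(X_val))
        return float(np.mean(np.argmax(z, axis=1) == y_val_idx))

    # ------------------------------------------------------------ inference

    def _embed(self, X: np.ndarray, return_attention: bool = False):
        frames = segment_batch(np.asarray(X, dtype=np.float64), self.n_steps)
        H, _ = _network.encoder_forward(self.params_, frames, self.n_layers,
                                        self.bidirectional)
        alpha, e, _ = _network.attention_forward(
            H, self.params_["att_W"], self.params_["att_b"], self.params_["att_V"],
            self.attention_tanh,
        )
        return (e, alpha) if return_attention else e

    def _logits(self, e: np.ndarray) -> np.ndarray:
        _, _, z, _ = _network.prototype_forward(
            e, self.params_["proto"], self.params_["head"], self.squared_distance
        )
        return z

    def transform(self, X) -> np.ndarray:
        """Pooled latent embeddings, shape (n_samples, u)."""
        check_is_fitted(self, "params_")
        return self._embed(np.asarray(X, dtype=np.float64))

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        return self._logits(self._embed(np.asarray(X, dtype=np.float64)))

    def predict_proba(self, X) -> np.ndarray:
        return _network.softmax(self.decision_function(X), axis=1)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def forward(self, x: np.ndarray) -> Prediction:
        """Full forward pass on one series, returning all intermediates."""
        check_is_fitted(self, "params_")
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        e, alpha = self._embed(x, return_attention=True)
        d, s, z, _ = _network.prototype_forward(
            e, self.params_["proto"], self.params_["head"], self.squared_distance
        )
        probs = _network.softmax(z, axis=1)
        return Prediction(
            logits=z[0], probs=probs[0], label=int(np.argmax(z[0])),
            distances=d[0], similarities=s[0], attention=alpha[0], embedding=e[0],
        )

    @property
    def embedding_size_(self) -> int:
        return self.hidden_size * (2 if self.bidirectional else 1)
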