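"""Prototype projection, prediction explanations, and expert editing.

Prototypes live in latent space, so to make them human-readable each one is
projected onto its nearest training instance (optionally snapping the vector
to that instance's embedding, which makes every prototype the image of an
observable waveform). Experts can then audit the model: add a new prototype
from a chosen waveform, remove or validate existing ones, filter candidate
signals that are far from everything already represented, and prune
prototypes whose removal does not hurt validation accuracy. Every edit is
recorded in an append-only log whose replay on the same checkpoint reproduces
the same prototype set.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

from ._network import prototype_forward
from .prototypes import PrototypeMeta, prototype_class_labels


@dataclass
class EditingConfig:
    """Thresholds for the expert-editing workflow.

    candidate_distance_threshold: minimum embedding distance to every current
    prototype for a signal to qualify as a new-prototype candidate (default 2.0).
    prune_score_threshold: maximum validation-accuracy drop tolerated when
    removing a prototype (default 0.0 — removal must not hurt at all).
    """

    candidate_distance_threshold: float = 2.0
    prune_score_threshold: float = 0.0
    fine_tune_epochs: int = 5

    def __post_init__(self) -> None:
        if self.candidate_distance_threshold < 0 or self.prune_score_threshold < 0:
            raise ValueError("editing thresholds must be non-negative")


@dataclass
class ExemplarEntry:
    prototype_index: int
    exemplar_index: int
    exemplar_id: str
    distance: float
    waveform: np.ndarray
    label: int | None = None


@dataclass
class ExemplarMap:
    entries: list[ExemplarEntry]

    def __getitem__(self, k: int) -> ExemplarEntry:
        return self.entries[k]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[int | None]:
        return [e.label for e in self.entries]


@dataclass
class ExplanationRow:
    prototype_index: int
    similarity: float
    contribution: float
    prototype_class: int
    exemplar_id: str | None = None


@dataclass
class ExplanationReport:
    predicted_label: int
    logit: float
    rows: list[ExplanationRow]
    attention: np.ndarray

    def as_dict(self) -> dict:
        return {
            "predicted_label": self.predicted_label,
            "logit": self.logit,
            "rows": [dataclasses.asdict(r) for r in self.rows],
            "attention": self.attention.tolist(),
        }


@dataclass
class EditLogEntry:
    operation: str  # add | remove | validate | prune
    prototype_index: int
    pre_K: int
    post_K: int
    note: str = ""
    timestamp: str = ""
    vector: list[float] | None = None  # stored for replay of "add"
    class_hint: int | None = None

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()


@dataclass
class EditLog:
    entries: list[EditLogEntry] = field(default_factory=list)

    def append(self, entry: EditLogEntry) -> None:
        self.entries.append(entry)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(dataclasses.asdict(e)) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "EditLog":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    entries.append(EditLogEntry(**json.loads(line)))
        return cls(entries)

    def replay(self, model) -> None:
        """Re-apply every recorded edit to a model loaded from the same base checkpoint."""
        for e in self.entries:
            if e.operation == "add":
                _append_prototype(model, np.asarray(e.vector, float),
                                  PrototypeMeta(provenance="expert"))
            elif e.operation in ("remove", "prune"):
                _delete_prototype(model, e.prototype_index)
            elif e.operation == "validate":
                meta = model.prototypes_.meta[e.prototype_index]
                meta.validated = True
                meta.frozen = True
            else:  # pragma: no cover - defensive
                raise ValueError(f"unknown edit operation {e.operation!r}")


# --------------------------------------------------------------- projection


def project_prototypes(model, X_train, y_train=None, ids=None,
                       snap: bool = False) -> ExemplarMap:
    """Associate each prototype with its nearest training instance.

    Nearest is by unsquared L2 distance between the instance embedding and the
    prototype vector; ties resolve to the lowest instance index. With
    ``snap=True`` each prototype vector is overwritten by its exemplar's
    embedding, so every prototype is exactly an observable waveform's image.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    if X_train.shape[0] == 0:
        raise ValueError("projection needs a non-empty training set")
    if ids is None:
        ids = [f"train{i}" for i in range(X_train.shape[0])]
    E = model.transform(X_train)  # (N, u)
    P = model.params_["proto"]
    entries = []
    for k in range(P.shape[0]):
        dists = np.sqrt(np.sum((E - P[k]) ** 2, axis=1))
        j = int(np.argmin(dists))
        entries.append(ExemplarEntry(
            prototype_index=k,
            exemplar_index=j,
            exemplar_id=ids[j],
            distance=float(dists[j]),
            waveform=X_train[j].copy(),
            label=None if y_train is None else int(np.asarray(y_train)[j]),
        ))
        model.prototypes_.meta[k].exemplar_id = ids[j]
        if snap:
            P[k] = E[j]
    return ExemplarMap(entries)


# -------------------------------------------------------------- explanation


def explain(model, x: np.ndarray, top_m: int | None = None,
            exemplar_map: ExemplarMap | None = None) -> ExplanationReport:
    """Explain one prediction as ranked prototype contributions.

    The predicted-class logit decomposes exactly as z_c = sum_k W[c, k] s_k;
    rows report the top_m most similar prototypes with their share of that sum.
    """
    pred = model.forward(x)
    K = pred.similarities.shape[0]
    if top_m is None:
        top_m = K
    if top_m > K:
        warnings.warn(f"top_m={top_m} exceeds K={K}; clamping", UserWarning)
        top_m = K
    c = pred.label
    W = model.params_["head"]
    labels, _ = prototype_class_labels(W)
    order = np.argsort(-pred.similarities)[:top_m]
    rows = [
        ExplanationRow(
            prototype_index=int(k),
            similarity=float(pred.similarities[k]),
            contribution=float(W[c, k] * pred.similarities[k]),
            prototype_class=int(labels[k]),
            exemplar_id=(exemplar_map[k].exemplar_id if exemplar_map is not None
                         else model.prototypes_.meta[k].exemplar_id),
        )
        for k in order
    ]
    return ExplanationReport(
        predicted_label=c, logit=float(pred.logits[c]), rows=rows,
        attention=pred.attention,
    )


# ------------------------------------------------------------------ editing


def filter_candidates(X, model, dmin: float | None = None,
                      prototypes: np.ndarray | None = None):
    """Keep signals whose embedding is at least ``dmin`` from every prototype.

    Signals already well represented (closer than dmin to some prototype) are
    excluded, focusing expert attention on uncovered morphology. Returns
    (X_subset, kept_indices). With an explicitly empty prototype array, every
    signal is vacuously retained.
    """
    X = np.asarray(X, dtype=np.float64)
    if dmin is None:
        dmin = EditingConfig().candidate_distance_threshold
    P = model.params_["proto"] if prototypes is None else np.asarray(prototypes, float)
    if P.size == 0:
        return X.copy(), np.arange(X.shape[0])
    E = model.transform(X)
    dmin_per = np.min(
        np.linalg.norm(E[:, None, :] - P[None, :, :], axis=2), axis=1
    )
    kept = np.nonzero(dmin_per >= dmin)[0]
    return X[kept].copy(), kept


def _append_prototype(model, vector: np.ndarray, meta: PrototypeMeta) -> None:
    model.params_["proto"] = np.vstack([model.params_["proto"], vector[None]])
    C = model.params_["head"].shape[0]
    model.params_["head"] = np.hstack([model.params_["head"], np.zeros((C, 1))])
    model.prototypes_.vectors = model.params_["proto"]
    model.prototypes_.meta.append(meta)


def _delete_prototype(model, k: int) -> None:
    model.params_["proto"] = np.delete(model.params_["proto"], k, axis=0)
    model.params_["head"] = np.delete(model.params_["head"], k, axis=1)
    model.prototypes_.vectors = model.params_["proto"]
    del model.prototypes_.meta[k]


def add_prototype(model, series: np.ndarray, class_hint: int | None = None,
                  note: str = "", log: EditLog | None = None) -> EditLogEntry:
    """Add an expert prototype at the embedding of ``series``.

    The new head column is zero-initialised, so every prediction is unchanged
    until the next fine-tuning round — the edit is non-destructive and
    auditable. A vector duplicating an existing prototype (distance < 1e-9)
    is rejected.
    """
    e = model.transform(np.atleast_2d(np.asarray(series, float)))[0]
    dists = np.linalg.norm(model.params_["proto"] - e, axis=1)
    if np.min(dists) < 1e-9:
        raise ValueError(
            f"duplicate prototype: distance {dists.min():.2e} to prototype "
            f"{int(np.argmin(dists))} is below 1e-9"
        )
    pre_K = model.params_["proto"].shape[0]
    _append_prototype(model, e, PrototypeMeta(provenance="expert"))
    entry = EditLogEntry("add", pre_K, pre_K, pre_K + 1, note=note,
                         vector=e.tolist(), class_hint=class_hint)
    if log is not None:
        log.append(entry)
    return entry


def remove_prototype(model, k: int, force: bool = False, note: str = "",
                     log: EditLog | None = None) -> EditLogEntry:
    """Delete prototype k and its head column: z_after = z_before - W[:, k] s_k."""
    K = model.params_["proto"].shape[0]
    if not 0 <= k < K:
        raise IndexError(f"prototype index {k} out of range [0, {K})")
    if K < 2:
        raise ValueError("cannot remove the last remaining prototype")
    if model.prototypes_.meta[k].validated and not force:
        raise ValueError(f"prototype {k} is validated; pass force=True to remove")
    _delete_prototype(model, k)
    entry = EditLogEntry("remove", k, K, K - 1, note=note)
    if log is not None:
        log.append(entry)
    return entry


def validate_prototype(model, k: int, note: str = "",
                       log: EditLog | None = None) -> EditLogEntry:
    """Mark prototype k expert-validated; its vector is frozen for future training."""
    K = model.params_["proto"].shape[0]
    if not 0 <= k < K:
        raise IndexError(f"prototype index {k} out of range [0, {K})")
    meta = model.prototypes_.meta[k]
    meta.validated = True
    meta.frozen = True
    entry = EditLogEntry("validate", k, K, K, note=note)
    if log is not None:
        log.append(entry)
    return entry


def prune_prototypes(model, X_val, y_val, config: EditingConfig | None = None,
                     log: EditLog | None = None) -> list[EditLogEntry]:
    """Greedy leave-one-out pruning of uninformative prototypes.

    score(k) = val accuracy(full model) - val accuracy(model without k);
    prototypes with score <= prune_score_threshold (removal does not hurt) and
    not expert-validated are removed one at a time, most harmless first,
    re-scoring after each removal. At least one prototype per prototype-class
    label is always kept.
    """
    if config is None:
        config = EditingConfig()
    X_val = np.asarray(X_val, dtype=np.float64)
    y_val = np.asarray(y_val)
    class_index = {c: i for i, c in enumerate(model.classes_)}
    y_idx = np.array([class_index[v] for v in y_val])
    entries: list[EditLogEntry] = []
    while True:
        E = model.transform(X_val)
        _, s, z, _ = prototype_forward(E, model.params_["proto"],
                                       model.params_["head"],
                                       model.squared_distance)
        base_acc = float(np.mean(np.argmax(z, axis=1) == y_idx))
        W = model.params_["head"]
        labels, _ = prototype_class_labels(W)
        counts = np.bincount(labels, minlength=W.shape[0])
        K = W.shape[1]
        best_k, best_score = None, np.inf
        for k in range(K):
            if model.prototypes_.meta[k].validated:
                continue
            if counts[labels[k]] <= 1 or K <= 2:
                continue  # keep >= 1 prototype per represented class label
            z_wo = z - np.outer(s[:, k], W[:, k])
            acc_wo = float(np.mean(np.argmax(z_wo, axis=1) == y_idx))
            score = base_acc - acc_wo
            if score <= config.prune_score_threshold and score < best_score:
                best_k, best_score = k, score
        if best_k is None:
            break
        pre_K = K
        _delete_prototype(model, best_k)
        entry = EditLogEntry("prune", best_k, pre_K, pre_K - 1,
                             note=f"loo_score={best_score:.6f}")
        entries.append(entry)
        if log is not None:
            log.append(entry)
    return entries


def fine_tune(model, X, y, epochs: int | None = None,
              validation_data=None, config: EditingConfig | None = None):
    """Continue training after an edit, honouring frozen prototype vectors."""
    if epochs is None:
        epochs = (config or EditingConfig()).fine_tune_epochs
    return model.fine_tune(X, y, epochs, validation_data=validation_data)


def export_prototypes(model, exemplar_map: ExemplarMap, csv_path, json_path) -> None:
    """Write exemplar waveforms as CSV rows plus a JSON metadata sidecar."""
    import csv as _csv

    with open(csv_path, "w", newline="") as fh:
        wr = _csv.writer(fh)
        L = exemplar_map[0].waveform.size if len(exemplar_map) else 0
        wr.writerow([f"s{i}" for i in range(L)] + ["prototype_index"])
        for e in exemplar_map.entries:
            wr.writerow(list(e.waveform) + [e.prototype_index])
    labels, degenerate = prototype_class_labels(model.params_["head"])
    meta = [
        {
            "prototype_index": e.prototype_index,
            "exemplar_id": e.exemplar_id,
            "distance": e.distance,
            "label": e.label,
            "head_class": int(labels[e.prototype_index]),
            "degenerate_head_column": bool(degenerate[e.prototype_index]),
            "provenance": model.prototypes_.meta[e.prototype_index].provenance,
            "validated": model.prototypes_.meta[e.prototype_index].validated,
        }
        for e in exemplar_map.entries
    ]
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2)
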