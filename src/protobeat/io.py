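"""Readers and writers: dataset CSV, model checkpoints, run configs, WFDB records.

The native exchange format is plain CSV: one beat per row, samples then a
final integer ``label`` column, with the class-name map declared in a leading
``# classes:`` comment so label codes can never silently permute. Checkpoints
are a single zip archive holding a JSON manifest (shapes, config, prototype
metadata) plus an .npz of all float64 parameter arrays — round-tripping is
bit-exact. A minimal reader for single-signal format-16 WFDB records covers
the optional external ECG interface.
"""

from __future__ import annotations

import csv
import dataclasses
import io as _io
import json
import zipfile
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .data import LabeledSequence
from .prototypes import PrototypeMeta, PrototypeSet

CHECKPOINT_VERSION = 1

# ----------------------------------------------------------------- dataset CSV


def write_dataset_csv(seqs: list[LabeledSequence], path,
                      class_names: dict[str, int] | None = None) -> None:
    """Write beats as rows: ``id, s0..s{L-1}, label`` with a class-map comment."""
    if not seqs:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if class_names:
            pairs = ",".join(f"{k}={v}" for k, v in sorted(class_names.items(),
                                                           key=lambda kv: kv[1]))
            fh.write(f"# classes: {pairs}\n")
        wr = csv.writer(fh)
        L = len(seqs[0])
        wr.writerow(["id"] + [f"s{i}" for i in range(L)] + ["label"])
        for s in seqs:
            wr.writerow([s.id] + [repr(float(v)) for v in s.values] + [s.label])


def read_dataset_csv(path) -> tuple[list[LabeledSequence], dict[str, int]]:
    """Read a beat CSV back, order-preserving. Returns (sequences, class-name map)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"empty dataset file: {path}")
    lines = text.splitlines()
    class_map: dict[str, int] = {}
    start = 0
    if lines[0].startswith("# classes:"):
        for pair in lines[0].split(":", 1)[1].split(","):
            name, code = pair.strip().split("=")
            class_map[name] = int(code)
        start = 1
    rows = list(csv.reader(lines[start:]))
    if not rows:
        raise ValueError(f"no header row in {path}")
    header = rows[0]
    if "label" not in header:
        raise ValueError(f"{path}: missing 'label' column in header {header}")
    label_col = header.index("label")
    has_id = header and header[0] == "id"
    seqs = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(f"{path}: ragged row {r}: {len(row)} cells, "
                             f"expected {len(header)}")
        try:
            values = [float(v) for v in row[(1 if has_id else 0):label_col]]
            label = int(row[label_col])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell in row {r}: {exc}") from exc
        seqs.append(LabeledSequence(np.array(values), label,
                                    row[0] if has_id else f"row{r}"))
    if not seqs:
        raise ValueError(f"{path}: header but no data rows")
    return seqs, class_map


# ----------------------------------------------------------------- checkpoints


def save_checkpoint(model, path) -> None:
    """Serialise a fitted classifier: JSON manifest + npz of parameter arrays."""
    manifest = {
        "format_version": CHECKPOINT_VERSION,
        "estimator_params": model.get_params(),
        "classes": np.asarray(model.classes_).tolist(),
        "n_features_in": int(model.n_features_in_),
        "history": model.history_,
        "epoch_offset": model._epoch_offset,
        "best_validation_accuracy": getattr(model, "best_validation_accuracy_", None),
        "prototype_meta": [dataclasses.asdict(m) for m in model.prototypes_.meta],
        "array_shapes": {k: list(v.shape) for k, v in model.params_.items()},
    }
    buf = _io.BytesIO()
    np.savez(buf, **model.params_)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        zf.writestr("arrays.npz", buf.getvalue())


def load_checkpoint(path):
    """Rebuild the classifier from :func:`save_checkpoint` output, bit-exactly."""
    from .estimator import PrototypeSequenceClassifier

    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        if manifest["format_version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version "
                             f"{manifest['format_version']}")
        with zf.open("arrays.npz") as fh:
            arrays = dict(np.load(_io.BytesIO(fh.read())))
    model = PrototypeSequenceClassifier(**manifest["estimator_params"])
    model.params_ = {k: np.asarray(v, dtype=np.float64) for k, v in arrays.items()}
    model.classes_ = np.asarray(manifest["classes"])
    model.n_features_in_ = manifest["n_features_in"]
    model.history_ = manifest["history"]
    model._epoch_offset = manifest["epoch_offset"]
    if manifest.get("best_validation_accuracy") is not None:
        model.best_validation_accuracy_ = manifest["best_validation_accuracy"]
    model.prototypes_ = PrototypeSet(
        model.params_["proto"],
        [PrototypeMeta(**m) for m in manifest["prototype_meta"]],
    )
    ss = np.random.SeedSequence(model.random_state)
    _, _, model._shuffle_ss, model._drop_ss, model._split_ss = ss.spawn(5)
    return model


def write_history_csv(history: list[dict], path) -> None:
    """Per-epoch loss breakdown + validation accuracy as a training log."""
    cols = ["epoch", "ce", "r_div", "r1", "r2", "total", "val_accuracy"]
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(cols)
        for row in history:
            wr.writerow([row[c] for c in cols])


# ----------------------------------------------------------------- run config


@dataclass
class RunConfig:
    """Flat key/value configuration covering generator, model, training, editing."""

    seed: int = 0
    # synthetic data
    samples_per_beat: int = 180
    n_per_class: int = 600
    classes: tuple[str, ...] = ("N", "A", "O")
    noise_sd: float = 0.03
    # model shape
    n_steps: int = 30
    hidden_size: int = 16
    n_layers: int = 3
    bidirectional: bool = True
    attention_dim: int = 16
    attention_tanh: bool = False
    n_prototypes: int = 12
    dropout: float = 0.1
    squared_distance: bool = False
    # training
    learning_rate: float = 0.002
    batch_size: int = 128
    max_epochs: int = 30
    lam_diversity: float = 0.01
    lam_prototypicality: float = 0.05
    lam_clustering: float = 0.05
    diversity_threshold: float = 1.0
    ce_reduction: str = "sum"
    full_set_regularizers: bool = False
    grad_clip: float = 5.0
    validation_fraction: float = 0.1
    # editing
    candidate_distance_threshold: float = 2.0
    prune_score_threshold: float = 0.0
    fine_tune_epochs: int = 5

    def estimator_kwargs(self) -> dict:
        keys = [
            "n_steps", "hidden_size", "n_layers", "bidirectional", "attention_dim",
            "attention_tanh", "n_prototypes", "dropout", "squared_distance",
            "learning_rate", "batch_size", "max_epochs", "lam_diversity",
            "lam_prototypicality", "lam_clustering", "diversity_threshold",
            "ce_reduction", "full_set_regularizers", "grad_clip",
            "validation_fraction",
        ]
        kw = {k: getattr(self, k) for k in keys}
        kw["random_state"] = self.seed
        return kw

    def synthetic_config(self):
        from .synthetic import SyntheticConfig

        return SyntheticConfig(
            samples_per_beat=self.samples_per_beat, n_per_class=self.n_per_class,
            classes=tuple(self.classes), noise_sd=self.noise_sd, seed=self.seed,
        )

    def editing_config(self):
        from .editing import EditingConfig

        return EditingConfig(
            candidate_distance_threshold=self.candidate_distance_threshold,
            prune_score_threshold=self.prune_score_threshold,
            fine_tune_epochs=self.fine_tune_epochs,
        )


def load_config(path) -> RunConfig:
    """Parse a flat YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "classes" in raw:
        raw["classes"] = tuple(raw["classes"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["classes"] = list(data["classes"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ----------------------------------------------------------------- WFDB (optional)

CINC_LABEL_CODES = {"N": 0, "A": 1, "O": 2, "~": 3}


def write_wfdb_record(directory, name: str, signal: np.ndarray,
                      fs: float = 300.0, gain: float = 1000.0,
                      units: str = "mV") -> None:
    """Write a single-signal format-16 WFDB record (header + int16 .dat)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.round(np.asarray(signal, float) * gain).astype("<i2")
    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    header = (
        f"{name} 1 {fs:g} {adc.size}\n"
        f"{name}.dat 16 {gain:g}/{units} 16 0 {int(adc[0]) if adc.size else 0} 0 0 ECG\n"
    )
    (directory / f"{name}.hea").write_text(header)


def read_wfdb_record(directory, name: str) -> np.ndarray:
    """Read back a single-signal format-16 WFDB record as physical units."""
    directory = Path(directory)
    hea = directory / f"{name}.hea"
    if not hea.exists():
        raise FileNotFoundError(f"missing WFDB header: {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_tokens = lines[0].split()
    n_sig = int(rec_tokens[1])
    if n_sig != 1:
        raise ValueError(f"only single-signal records supported, got {n_sig}")
    sig_tokens = lines[1].split()
    fmt = sig_tokens[1]
    if fmt != "16":
        raise ValueError(f"only format-16 records supported, got format {fmt!r}")
    gain_spec = sig_tokens[2]
    gain_part = gain_spec.split("/")[0]
    baseline = 0
    if "(" in gain_part:
        gain_part, base = gain_part.split("(")
        baseline = int(base.rstrip(")"))
    gain = float(gain_part) if gain_part else 200.0
    adc = np.frombuffer((directory / sig_tokens[0]).read_bytes(), dtype="<i2")
    return (adc.astype(np.float64) - baseline) / gain


def read_cinc_wfdb(directory) -> list[LabeledSequence]:
    """Load a directory of challenge-style WFDB records with a REFERENCE.csv label file.

    Labels come from the four rhythm codes {N, A, O, ~}; signals are kept at
    their native sampling rate (the challenge data are 300 Hz).
    """
    directory = Path(directory)
    ref = directory / "REFERENCE.csv"
    if not ref.exists():
        raise FileNotFoundError(
            f"missing annotation file: expected {ref} with rows 'record,label'"
        )
    seqs = []
    with open(ref) as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            name, code = row[0].strip(), row[1].strip()
            if code not in CINC_LABEL_CODES:
                raise ValueError(f"unknown rhythm code {code!r} for record {name}")
            values = read_wfdb_record(directory, name)
            seqs.append(LabeledSequence(values, CINC_LABEL_CODES[code], name))
    return seqs
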