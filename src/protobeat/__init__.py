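"""protobeat: interpretable prototype learning for single-heartbeat time series.

A recurrent attention-pooled encoder maps each beat to a latent embedding;
class logits are linear in the similarities to a set of learnable prototypes,
each of which projects back to a real training waveform. Experts can edit the
prototype set (add / validate / remove / prune) and fine-tune afterwards.
"""

from .data import LabeledSequence, arrays_to_sequences, sequences_to_arrays
from .editing import (
    EditingConfig,
    EditLog,
    EditLogEntry,
    ExemplarMap,
    ExplanationReport,
    add_prototype,
    explain,
    filter_candidates,
    fine_tune,
    project_prototypes,
    prune_prototypes,
    remove_prototype,
    validate_prototype,
)
from .encoding import attend, encode, lstm_step, segment_series
from .estimator import PrototypeSequenceClassifier
from .io import (
    RunConfig,
    load_checkpoint,
    load_config,
    read_cinc_wfdb,
    read_dataset_csv,
    save_checkpoint,
    save_config,
    write_dataset_csv,
)
from .metrics import MetricsReport, evaluate
from .model_selection import split_dataset
from .objectives import (
    LossBreakdown,
    LossWeights,
    clustering_loss,
    cross_entropy,
    diversity_loss,
    prototypicality_loss,
    total_loss,
)
from .prototypes import (
    Prediction,
    PrototypeMeta,
    PrototypeSet,
    classify,
    prototype_class_labels,
    prototype_distances,
    similarities,
)
from .synthetic import (
    BeatRecipe,
    SyntheticConfig,
    WaveComponent,
    fixture_tiny,
    generate_dataset,
    synth_beat,
)

__version__ = "0.1.0"

__all__ = [
    "LabeledSequence", "arrays_to_sequences", "sequences_to_arrays",
    "PrototypeSequenceClassifier",
    "EditingConfig", "EditLog", "EditLogEntry", "ExemplarMap", "ExplanationReport",
    "add_prototype", "explain", "filter_candidates", "fine_tune",
    "project_prototypes", "prune_prototypes", "remove_prototype",
    "validate_prototype",
    "attend", "encode", "lstm_step", "segment_series",
    "RunConfig", "load_checkpoint", "load_config", "read_cinc_wfdb",
    "read_dataset_csv", "save_checkpoint", "save_config", "write_dataset_csv",
    "MetricsReport", "evaluate", "split_dataset",
    "LossBreakdown", "LossWeights", "clustering_loss", "cross_entropy",
    "diversity_loss", "prototypicality_loss", "total_loss",
    "Prediction", "PrototypeMeta", "PrototypeSet", "classify",
    "prototype_class_labels", "prototype_distances", "similarities",
    "BeatRecipe", "SyntheticConfig", "WaveComponent", "fixture_tiny",
    "generate_dataset", "synth_beat",
]
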