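# Methods

## Model

A beat of length `L` is framed into `T` equal chunks of width `n = floor(L/T)`
(trailing remainder dropped, so frames stay homogeneous); the frame sequence
is the step input of a stacked bidirectional LSTM. Per-step states of the two
directions are concatenated, so the state width is `u = 2·hidden_size`; layer
`ℓ+1` consumes layer `ℓ`'s per-step output. Additive attention scores each
step with the plain affine form `score_t = V^T(W^T h_t + b)` — no tanh inside
the score by default; `attention_tanh=True` inserts the conventional squash —
and the embedding is the softmax-weighted sum of the states, hence always a
convex combination of per-step states.

The prototype layer holds `K` free vectors in the embedding space.
Similarity is `s_k = exp(−d_k)` with `d_k` the *unsquared* Euclidean
distance (`squared_distance=True` switches to squared; the regularisers
always use squared norms). Logits are the plain product `z = W s` with no
intermediate activation and an unconstrained head `W` (no sign or sparsity
constraint); class probabilities are the softmax of `z`, which generalises
cleanly to `C ≥ 3`.

## Objective and training

`total = CE + λ·R_div + λ₁·R₁ + λ₂·R₂`, with cross-entropy **summed** over
the mini-batch (a mean-reduction flag exists, default off). The diversity
term is `σ(τ − min-pairwise-squared-distance)` over unordered prototype
pairs; with a single prototype it is defined as 0 (no pair exists). R₁/R₂
are computed against the mini-batch embeddings each step; a
`full_set_regularizers` flag evaluates them against all training embeddings
(recomputed once per epoch, non-batch embeddings treated as constants).
Dropout (default 0.1) is applied to the pooled embedding on the
classification path only; the regularisers see the clean embeddings, since
they describe geometry rather than prediction.

All gradients are hand-derived (backprop through time for the LSTM stack,
softmax-attention backward, distance/similarity chain, argmin subgradients
for the three regularisers, first minimiser at ties) and are tested against
central finite differences at 1e-4 relative tolerance. Optimisation is Adam
(lr 0.002, β = 0.9/0.999) with global-norm gradient clipping at 5.0 to guard
against recurrent blow-ups (off-switch in config). Prototypes are
initialised to the embeddings of `K` randomly chosen training beats — stabler
than Gaussian initialisation and consistent with the prototypicality
pressure. Weights are uniform in ±1/√fan-in, biases zero. Parameters with
the best validation accuracy are kept (ties prefer the most recent epoch, so
continued training at saturated accuracy still adapts parameters); there is
no early stopping. Frozen (expert-validated) prototype vectors are excluded
from updates by masking their gradients and restoring their rows after each
optimiser step, so momentum cannot move them; their head columns keep
training.

Default shape: T = 30 frames, 3 layers, 16 hidden units per direction
(u = 32), attention width 16, K = 12, batch 128, 30 epochs. Every source of
randomness (initialisation, prototype choice, batch shuffling, dropout,
validation split) fans out from one integer seed through named
sub-sequences, so runs are bit-reproducible on one thread.

## Interpretation and editing

Each prototype is projected onto its nearest training beat (unsquared L2 in
embedding space, ties to the lowest index). `snap=True` overwrites the
vector with that exemplar's embedding so every prototype is exactly the
image of an observable waveform; snapping is off during training and used
for final reporting. Explanations decompose the predicted-class logit
exactly: `z_c = Σ_k W[c,k]·s_k`, rows ranked by similarity.

Editing contracts: an added prototype gets a zero head column, so every
prediction is provably unchanged until fine-tuning — the edit is auditable;
removal subtracts exactly the dropped term `W[:,k]·s_k` from the logits;
validation freezes the vector. Candidate filtering keeps signals whose
embedding is at least `dmin` (default 2.0) from every current prototype —
the threshold operates in embedding space because prototypes only exist
there. Pruning scores each unvalidated prototype by its leave-one-out
validation-accuracy delta, the most literal reading of "contribution",
cheap at desk scale; prototypes whose removal does not hurt (score ≤ 0 by
default) are removed greedily one at a time with re-scoring, never dropping
below one prototype per represented class label. Edits append to a JSON-lines
log whose replay against the same checkpoint reproduces the prototype set,
metadata, and (absent fine-tuning) the predictions.

## Synthetic data

The generator emulates three single-beat morphologies at 300 Hz, 180 samples
(0.6 s): normal sinus (Gaussian P wave, narrow biphasic QRS as a tall R lobe
plus negative S lobe, Gaussian T), atrial fibrillation (no P; 2–3 summed
5–9 Hz low-amplitude sinusoids as a fibrillatory baseline; wider QRS
amplitude swings reflecting irregular ventricular filling), and "other"
(P present, one deformation drawn per beat: widened low QRS, inverted T, or
a supplementary notch peak). White Gaussian noise (sd 0.03) is added.
Component timings are fractions of the beat duration, so the generator works
at any length. Every beat is fully determined by its recipe (component
parameters + noise seed), which is returned for ground-truth checks. The
default task is 600 beats per class; a nearest-centroid classifier on raw
waveforms exceeds 0.80 held-out accuracy, so the learning task is solvable
by construction.

What the generator does *not* emulate: beat-to-beat context (RR intervals —
the single-beat scope is deliberate), baseline wander, electrode noise
classes, multi-lead morphology, or the segmentation step that extracts beats
from continuous recordings. Passing tests therefore demonstrate that the
architecture, objective, and editing operations behave as specified on a
solvable beat-classification task — not clinical-grade AF detection.
A minimal reader for single-signal format-16 WFDB records (plus the
challenge-style `REFERENCE.csv` label file) lets the same pipeline ingest
real single-lead ECG exports; it is optional and never exercised by the
training path.

## Problem sizes used in the test suite

Unit and property tests run on toy shapes (K ≤ 10, N ≤ 50, u ≤ 8) and a
deterministic 60-beat noise-free two-class fixture (90 samples per beat).
End-to-end recovery runs the full 1800-beat three-class task at the default
settings for three seeds; the regulariser-effect comparison uses 200 beats
per class and 10 epochs, sizes chosen as the smallest at which the effects
are visible above run-to-run noise.

## Known limitations

- Single-threaded numpy training: fine at desk scale (seconds per epoch on
  the default task), not meant for the ~120k-beat scale of real corpora.
- The leave-one-out prune score is evaluated on a finite validation set;
  with small validation sets many prototypes tie at score 0 and pruning can
  be aggressive; negative score thresholds are rejected, so the remedy is a
  larger validation set.
- Binary cross-entropy is the categorical form specialised to C = 2; no
  class weighting or focal variants.
- The unsquared-distance gradient is undefined at d = 0; the subgradient 0
  is used (an embedding exactly on a prototype receives no pull from that
  prototype for that term).
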