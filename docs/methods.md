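# Methods

## Problem and cohort definition

An *unplanned readmission* is a return ICU admission beginning within
(0, 30] days after the hospital discharge of an index ICU stay, for a
patient with no other ICU stay in the preceding year. The package builds
this cohort from eight MIMIC-III-schema tables. Windows are measured in
elapsed time (30 days = 720 h) with an inclusive boundary: a gap of
exactly 30.0 days labels positive. The boundary convention is a package
choice; "within 30 days" does not fix it, and the probability of an exact
tie is zero for continuous timestamps.

Inclusion rules, applied conjunctively (so the surviving set is
independent of rule order): age ≥ 18 at ICU admission; ICU length of stay
between 1 and 30 days inclusive; at least one measurement of each of the
12 lab concepts and at least five of each of the 5 chart concepts; no
death during the stay or within 30 days after hospital discharge (the
death window is anchored on hospital discharge, matching the label
anchor). Age is floored elapsed years at ICU admission with
de-identification-shifted ages capped at 90. "First stay per year" is a
rolling 365-day exclusion on ICU admission times, not a calendar rule,
matching the motivation of excluding recently hospitalized patients; and
only the first ICU stay of each hospital admission is an index candidate —
later stays in the same admission count solely as readmission targets.

Folds are patient-level (a patient's stays never straddle train and
test), stratified on "any positive stay", with 12.5 % of each fold's
training patients held out, stratified, as the validation set for the
training protocol. The validation fraction is a package default; the
protocol requires a validation set but its size is otherwise
unconstrained.

## Knowledge base and temporal abstraction

The bundled knowledge base covers 17 readmission-related concepts (12
low-frequency lab tests, 5 high-frequency chart items), each with a
normal range, a gradient threshold Δ, and a stable-window in hours.
Values are discretized into 3 named states per concept — below / within /
above the normal range, with domain names where standard (Hypothermia /
Normal / Fever for body temperature; Severe / Moderate / Mild for the
Glasgow Coma Scale, whose integer scale puts the upper cutoff at 13 so
that 12 remains in the normal band). State intervals are half-open and
lower-inclusive; users may supply their own YAML with up to 6 states per
concept. One printed chloride bound is encoded as 96–106 mEq/L.

Gradient abstraction labels each consecutive pair of measurements
Increasing, Decreasing or Stable by the sign of the difference; it starts
at the second observation (length n−1), since the first point has no
predecessor. The default `simple` mode uses the sign rule alone. The
`thresholded` mode additionally calls a change Stable when its magnitude
is at most Δ *and* the elapsed gap is within the stable window; the
knowledge base tabulates Δ and the stable window but the sign rule alone
does not consume them, so both modes are exposed rather than guessing a
single intended combination.

Interpolation onto the union grid of observation times is temporal-linear
with the standard weighting — the nearer neighbour in time receives the
larger weight — implemented via `np.interp` and oracle-tested against the
two-point line equation. Outside a concept's observed range the nearest
observed value is carried, so no grid row is dropped. Interpolation
commutes with discretization at observed points.

Two model layouts are produced. The *flattened univariate* layout merges
all (timestamp, concept, symbol) events into one temporally ordered
sequence of concept-qualified symbols (ties at equal timestamps break by
the knowledge-base concept order, states before gradients), index-encoded
against a fixed vocabulary (17 × 3 states + 17 × 3 gradients + 1 pad =
103 symbols by default), truncated from the start (most recent events
kept) and padded at the end. The *interpolated multivariate* layout keeps
a per-grid-time vector: the concatenation of each concept's state one-hot
(plus gradient one-hots when enabled), which bypasses the symbol
embedding since it is already vector-valued.

## Models

**BIRNN.** Token indices embed into ⌊D^(1/4)⌋ dimensions (D the
vocabulary size). Two GRUs run over the embedded sequence, the second on
the time-reversed input; their per-timestep outputs are concatenated.
Padded steps are gated so they neither update the recurrent state nor
receive attention mass — necessary because the reversed pass consumes the
padding first. Attention is a learned affine map to one scalar per
timestep, soft-normalized over valid positions, returning the weighted
sum (a fixed-width pooled vector; the following affine layer forces a
fixed-size output, and an all-padding sample falls back to uniform
weights). The pooled vector, optionally concatenated with a static
modality vector (demographics one-hot), maps affinely to a single score.
Default hidden size is 64 per GRU (32 or 24 in desk-scale experiment
configs); hidden sizes are package choices.

**Text scorer.** A two-layer, single-head, width-32 transformer encoder
with learned positional embeddings, residual attention and feed-forward
blocks with layer normalization, masked mean pooling and an affine head.
It is randomly initialized and fine-tuned through the same protocol,
exercising the chunk-scoring and aggregation path at desk scale;
pretrained clinical weights can be dropped in through the same
`TextScorer` interface (`score_chunks: NoteChunks → probabilities`).
Notes are cleaned (lower-cased, bracketed de-identification spans
removed, whitespace collapsed, digits kept), tokenized by an injected
tokenizer (tests use whitespace tokenization), and split into greedy
fixed-length chunks — default 318 content tokens, leaving room for
special tokens under a 512-token encoder limit; chunks partition the
token sequence exactly. Chunk training labels inherit the note label;
at evaluation the n chunk probabilities aggregate to
`(P_max + P_mean·n/2)/(1 + n/2)`, which always lies between the chunk
mean and the chunk max.

**Fusion.** Component models contribute their pre-classifier vectors
(BIRNN: the post-attention pooled vector; text model: its pooled encoder
state; demographics: the raw one-hot), which are concatenated and mapped
by one affine head; all parameters train jointly. Demographics joins at
this fusion point rather than as per-timestep copies. When notes join a
fusion model, the first chunk of each note feeds the text component — a
desk-scale simplification, since the synthetic notes fit one chunk.

**Tabular baseline.** A seeded random forest on the concatenated ICD-9
bag-of-codes and demographics one-hot.

All neural components run on a small tape-based reverse-mode autodiff
engine over numpy arrays written for this package; the GRU is a fused
kernel with hand-written backprop-through-time, verified against
numerical differentiation in the test suite. The optimizer is
adaptive-moment gradient descent (Adam) with standard moment defaults;
the protocol's learning-rate schedule multiplies its step size.

## Training protocol

Binary cross-entropy, batch size 64. Every `eval_every_steps` optimizer
steps the validation AUPRC is computed; on improvement over the best
value so far the model is checkpointed and the patience counter resets,
otherwise the learning rate is multiplied by the decay (0.9 for text
models from 2·10⁻⁵, 0.97 from 10⁻³ otherwise) and the counter
increments. Training stops when the counter *exceeds* 7 (the eighth
consecutive non-improvement stops it), and the last saved checkpoint is
returned; if no evaluation ever improved, the initial parameters are
returned with a warning. The learning rate never resets on improvement —
decay reads as monotone annealing — while the counter does. A safety cap
of `max_steps` (default 20 epochs' worth of batches) guards
non-terminating runs. Class-imbalance weighting is off by default with an
optional positive-class weight.

## Evaluation

AUROC and AUPRC are computed on raw scores (pairwise-concordance and
step-wise precision–recall integration semantics, via scikit-learn, with
independent brute-force oracles in the tests); precision, recall and F1
use a threshold chosen on validation predictions as the candidate
(midpoints of sorted distinct scores, plus the minimum) maximizing F1,
ties resolving to the lowest threshold — the "optimal threshold" criterion
is a package choice. A model is *conclusively better* than another when
it strictly exceeds it on at least three of the five metrics, applied to
cross-fold means; the rule is implemented exactly as stated even though
a 3-of-5 advantage can coexist with a stated "no conclusive winner" in
narrative comparisons. Cross-fold summaries report the sample mean and
the (n−1) standard deviation as "mean ± std" to four decimals.

## Synthetic EHR generator

The generator emulates the statistical structure the pipeline consumes:
eight referentially consistent tables; 5 chart concepts sampled roughly
hourly and 12 lab concepts roughly daily with ±30 % gap jitter and
configurable per-concept missingness (a floor of 5 chart / 1 lab
measurements per index stay keeps index stays filter-complete);
length-of-stay uniform in a configurable range (default 1.5–8 days);
demographics from fixed category sets; ICD-9 sequences over a bundled
200-code vocabulary with invented-but-plausible long titles; and
sectioned, template-based discharge notes with MIMIC-style bracketed
de-identification placeholders.

Each patient draws a latent label at the configured readmission rate
(default 0.11). Positives receive a follow-up ICU admission 1–29.5 days
after hospital discharge; negatives receive one at > 31 days with
probability 0.3 or none. Follow-up stays are short (< 1 day) and carry no
measurements, so they act purely as readmission targets and never enter
the index cohort — which is why cohort label assignment recovers the
latent labels exactly.

Per-modality signal is injected scaled by `signal_strength`: risk ICD-9
codes are over-sampled (base rate 0.12, plus 0.20 per unit signal) and
risk phrases injected into notes (probability 0.25 per unit signal per
phrase). For charts, `chart_signal_target="level"` shifts the positive
class's latent trajectories by 0.35 normal-band-widths per unit signal —
a mean shift before discretization, so both state and gradient
abstractions can carry it; `"trend"` instead adds a within-band sawtooth
drift (amplitude capped inside the normal range) whose consecutive
differences are predominantly positive, putting the signal in the
gradients while leaving the state distribution (near-)uninformative —
the condition under which the gradient abstraction's added value is
measured. All trajectories include per-patient baseline offsets and
measurement noise so classes overlap realistically. All randomness flows
from a single seeded generator; identical configurations produce
byte-identical tables (timestamps are floored to whole seconds so tables
round-trip losslessly through CSV).

What the generator does *not* emulate: clinically coherent correlation
between concepts, diagnoses and note content; real clinical language;
non-stationary measurement practice; informative missingness. Passing
end-to-end tests therefore demonstrates that the pipeline recovers
planted signal of each kind under realistic sampling structure — not
clinical-grade performance on real data.

## Desk-scale problem sizes

The end-to-end benchmarks run 2,000 patients, hidden size 24, flattened
sequences truncated to the 96 most recent events, evaluation every 40
steps with a 280-step cap — sizes chosen so the full pipeline runs in
minutes on one CPU while leaving the protocol semantics (stop loss 7,
decay rates, checkpointing) untouched. Headline cross-fold tables on
real MIMIC-III (and the published cohort counts 14,837 patients / 15,424
stays) require credentialed access and GPU-scale fine-tuning and are out
of scope; the acceptance script instead verifies the in-table arithmetic
and the pipeline's signal-recovery behaviour.

## Known limitations

* The gradient mode actually used with the tabulated Δ/stable-window
  columns is ambiguous in the source description; both `simple` and
  `thresholded` modes are provided and default to `simple`.
* Chunk-level validation AUPRC drives checkpointing for the note model;
  patient-level aggregation happens at threshold selection and test time.
* The multivariate interpolated layout truncates to the most recent grid
  rows, which discards early-stay dynamics for very long stays.
* The numpy engine is single-threaded and sized for desk-scale
  experiments, not GPU-scale reproduction.
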