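# Methods

This note documents the models implemented in `bioidtn`, the choices made
where the design was genuinely open, what the synthetic benchmark does and
does not establish, and known limitations.

## Task and data model

The pipeline assigns knowledge-base identifiers to protein/gene mentions in
short text passages (figure-caption-like documents). Offsets are 0-based,
half-open, in Unicode characters; the strict-match evaluator compares these
character offsets (on ASCII text they coincide with byte offsets). Spans
are stored sorted; every reader and writer validates that a span's surface
equals the corresponding text slice, and malformed annotations are reported
rather than dropped.

Mentions not aligned to token boundaries are snapped *outward* to the
covering tokens before BIO encoding — a recall-favouring choice, logged as
a warning. BIO (not BIOES) is used throughout. The default tokenizer splits
on whitespace and punctuation, keeping punctuation as tokens; POS and chunk
tags come from a deterministic stub provider (a stable hash of the
lowercased token into a fixed inventory) so the pipeline runs with no
external tagger. Real taggers plug in through the same provider interface.

## Knowledge features and candidate retrieval

Knowledge features tag tokens covered by a greedy left-to-right longest
match against KB variant terms (maximal munch; length ties resolved
leftmost-first). Variant index keys are lowercased token sequences stored
in both the full form and a bracket-stripped form, so "VEGF" recalls
"VEGF (human)" while exact forms still dominate scoring.

Candidate ID generation treats the mention as a query. The published
approach delegates ranking to remote KB search APIs; those are unusable in
a hermetic run, so retrieval here is a deterministic local cascade — exact
variant match (score 4) > exact canonical-mention match (3) >
case-insensitive normalized match (2) > token-overlap Jaccard (0–1) — with
lexicographic entity-ID tie-breaks and the top 5 kept. The cascade sits
behind a small interface so an API-backed ranker can be swapped in; results
are pure functions of (query, KB).

## Recognizer

Per-token features are the concatenation `[x_w; x_c; x_pos; x_chunk; x_kf;
x_elmo]` with full-scale default dimensions 200/50/25/10/15 and a
contextual part of configurable width. The character vector is the
concatenated final states of a character-level BiLSTM (25 per direction).
The contextual provider interface yields one vector per biLM layer per
token; the bundled default is a deterministic stub (a seeded random
projection of a growing window of word vectors, tanh-squashed), which
exercises the layer-combination math — a learned scale γ times a
softmax-weighted layer sum — without a pre-trained language model. The
combination parameters (γ, layer logits) are trained with the tagger.

Emissions are `P = V tanh(W h + b)` over BiLSTM states (default 100 hidden
units per direction); the CRF transition matrix has k+2 states including
start/end. The log-likelihood uses the forward recursion in log space
(finite for |P|,|T| ≤ 50); decoding is Viterbi with ties resolved toward
the lowest tag index. Training uses RMSProp (lr 1e-3), mini-batch 8,
dropout 0.5 applied at the two standard sites (concatenated embedding,
BiLSTM output), an 80/20 train/validation split when no validation set is
given, model selection by validation strict F1, and early stopping with
patience 5. Word embeddings are fine-tuned per task.

Post-processing applies two rules to a fixed point (hence idempotent):
spans with an unclosed opening bracket extend to the closing bracket
(within 40 characters), and exact same-document repeats of an
already-predicted surface are re-tagged at word boundaries. The published
rule sets this approximates are not fully specified; both rules live behind
one function.

## ID embeddings

The KB is viewed as a bipartite graph — mentions on one side, IDs on the
other, variants as edges — under two premises: an ID is the sum of its
variants, and a mention is the sum of its variants. Mention vectors are
initialized as the mean word vector of their constituent words (UNK for
fully out-of-vocabulary mentions, logged). Encoding distributes each
mention over its edges with per-edge diagonal matrices E(i,j); the
constraint Σ_j E(i,j) = I is enforced *structurally* by parameterizing each
mention's E diagonals as a per-dimension softmax over its edges, so it
holds exactly after every optimization step (verified to 1e-6 in tests).
Decoding uses unconstrained diagonal matrices D(j,i). The loss

    α · ‖m̄(i) − m(i)‖² + β · ‖E(i,j) m(i) − D(j,i) s(j)‖²   (α = β = 0.5)

uses the squared L2 norm: the unsquared norm is not differentiable at zero,
and the squared form is the smooth standard for reconstruction objectives
while preserving "zero iff exact reconstruction". The optimizer and
iteration count are open choices: full-batch gradient descent (lr 0.05,
300 epochs by default), jointly over E and D, seeded and bit-reproducible.
With singleton structure (one variant per mention and ID) the identity
parameters are an attainable optimum and training reaches loss < 1e-4.

Sibling IDs reached through one mention are distinguishable in embedding
space only through their *other* variants — exactly the structure of the
canonical example, where the ambiguous ID also owns aliases. The synthetic
generator therefore attaches alias variants to ambiguously-reached IDs
first (see below).

## Disambiguator

Each candidate is scored from the mention's left and right contexts — the
nearest n2 = 10 non-stopword, non-punctuation tokens per side, shorter
sides padded with a reserved zero vector — encoded by one of five sequence
encoders (LSTM, GRU, BiLSTM, BiGRU, hierarchical ConvNet with four
same-padded conv layers, kernel width 3, 64 maps per layer, summary
`[u1;u2;u3;u4]` of max-pooled layer outputs). Context token vectors
concatenate the word vector with a contextual-stub vector, since contextual
representations feed the disambiguator as well.

Knowledge-based attention scores each hidden state against the candidate
ID embedding, `e_t = tanh(W_a h_t + V_a s + b_a)` with the printed 1×d
parameter shapes, making e_t (and the gate value g) scalar; self-attention
drops the `V_a s` term. A consequence of the scalar score worth noting:
the candidate term contributes a per-sequence constant inside the tanh, so
in the near-linear regime the two attention variants behave almost
identically — ties between them are expected at desk scale. The gate
`g = σ(W_g o^L + V_g o^R + b_g)` produces a convex combination of the side
summaries; the classifier is a two-layer ReLU network over `[z; s]` with a
two-way softmax. One gate parameter set is shared across candidates.

Training: cross-entropy over correct/corrupt samples, Adagrad, mini-batch
8. Negatives are drawn uniformly without replacement from the candidate
set minus the gold ID, n_neg = 2 per positive by default (the number of
negatives is an open choice). Assignment picks the argmax-scored candidate
(ties by retrieval order), falling back to `GENERIC:<type>` for empty
candidate sets or best scores below a configurable `nil_threshold`
(default 0.5, the softmax majority — when the generic ID applies to
non-empty candidate sets is otherwise unspecified).

## Evaluation

Recognition: strict (identical offsets and type) and overlap (any character
overlap, same type) matching, with greedy leftmost one-to-one pairing. The
matching protocol is isolated so an alternative matcher can be swapped in;
on non-overlapping gold spans the greedy pairing attains the optimal
matching (property-tested). Normalization scores (span, ID) pairs, only for
non-generic predicted IDs; micro pools global counts, macro averages
per-document P/R/F1 with equal weight (the per-document reading of an
ambiguous published phrasing; a per-label reading would differ).
Zero-denominator rates report 0 with an explicit flag, never NaN.

The error taxonomy partitions every erroneous assignment into exactly one
of four categories: recognition false positives, recognition false
negatives, recognized mentions whose gold ID was not retrieved (missed ID),
and recognized mentions whose gold ID was retrieved but not chosen
(incorrect ID); percentages are rounded to two decimals.

The learning-curve model `F1(n) = i + j·mⁿ` (m ∈ (0,1); i the asymptote)
is fitted by profiling: for fixed m the model is linear in (i, j), so the
residual is scanned over a fixed m-grid and refined with bounded scalar
minimization — deterministic, with zero residual (≤ 1e-10) on noiseless
generated points.

## Synthetic benchmark

The generator emits a KB whose ambiguity rate (mean distinct-ID count over
polysemous mentions) and synonymy rate (mean distinct-variant count over
multi-variant IDs) hit configurable targets up to integer rounding, using
species-qualified variants ("gnaa (human)" vs "gnaa (pig)") for ambiguity
and alias variants for synonymy, aliases going to ambiguously-reached IDs
first. Documents intersperse entity occurrences (KB variant surfaces) with
filler words, stop words and punctuation; each gold ID's planted keyword
follows the mention with probability `planted_signal_strength` (0.95 in the
benchmark preset), and distractor keywords of *non-candidate* IDs are
injected so candidate-conditioned attention has something to ignore — at
full signal strength a keyword rule is Bayes-optimal by construction.

Desk-scale preset: 30 IDs, 200 documents of ~20 tokens, 32-dimensional
vectors; recognizer with 32 hidden units and up to 8 epochs; disambiguator
with 24 hidden units, 40 epochs, and Adagrad lr 0.03 — the learning rate is
scaled up from the full-scale default because the preset yields roughly two
orders of magnitude fewer gradient steps per epoch than a corpus-scale run.
These sizes keep the full benchmark under a few minutes on one CPU.

What passing the benchmark shows: the tagger can learn dictionary-backed
entity recognition; the dictionary features carry recall for surfaces
unseen in training; the autoencoder embeddings make sibling IDs separable;
the context model recovers a planted lexical signal and beats a
random-candidate baseline end to end. What it does not show: performance on
real biomedical text, whose entity surface distribution, context statistics
and KB coverage are far harsher than the generator's (no misspellings,
no nested or discontinuous mentions, no cross-species ambiguity beyond the
qualifier pattern, perfectly faithful annotations).

## Numerical and engineering notes

All neural components run on a compact reverse-mode autodiff engine over
numpy (`bioidtn.nn`) with gradient correctness checked against finite
differences; models are bit-reproducible given a seed, and the pipeline
derives per-stage seeds from one global seed. Log-space computations guard
the CRF partition and softmaxes; sigmoid inputs are clipped at ±60; gradient
norms are clipped at 5. Checkpoints are single-file numpy archives with the
configuration embedded as JSON.

## Limitations

Single-passage documents (no sentence splitting beyond the rule-based
default, no full-text handling); single entity type by default (multi-type
is configurable); no species inference or cross-document coherence; the
local retrieval cascade approximates, but does not replicate, remote KB
search ranking; the contextual stub shares only the interface and the
combination math with a real pre-trained language model.
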