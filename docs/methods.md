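# Methods

This note documents the model implemented by `cnerkit`, the choices made
where the design was genuinely open, what the synthetic corpus generator
does and does not emulate, and the numerical conventions the tests rely on.

## Task and model

The task is character-level clinical named entity recognition (CNER):
given a sentence of Chinese-style characters from an electronic medical
record (EMR), assign each character a BIO label over six entity types —
disease (DIS), exam (EXA), test (TES), operation (OPE), drug (DRU) and
anatomy (ANA) — and recover typed character spans.

The tagger is a pipeline of four stages:

1. **Input representation.** Each character's vector is the sum of a
   trainable token embedding, a segment embedding (identically zero for the
   single-sentence inputs used here), and a position encoding

       PE(pos, 2i)   = sin(pos / 10000^(2i/d_model))
       PE(pos, 2i+1) = cos(pos / 10000^(2i/d_model)).

   A learned position table is available by configuration
   (`position_mode="learned"`) because both conventions are common; the
   fixed sinusoidal form is the default. A pretrained contextual embedder
   (e.g. an ALBERT encoder) can be plugged in through
   `ExternalEmbedderAdapter`, which enforces the one-vector-per-character
   contract and projects to `d_model` when dimensions differ; pretraining
   itself is out of scope. Dropout (inverted, training-time only) is
   applied between the embedding and the encoder.

2. **Iterated dilated convolutions (IDCNN).** One block of three 1-D
   convolutions with kernel size K=3 and dilation widths (1, 1, 2) is
   applied 4 times, each iteration feeding on the previous output, with the
   block's parameters **shared across iterations** — so the parameter count
   is independent of the iteration count while the receptive field grows
   linearly:

       r = 1 + iterations * sum_layers (K - 1) * dilation  =  33

   for the default configuration. The convolutions use "same" zero padding
   (the boundary convention is not dictated by the architecture; same
   padding keeps sequence length fixed), ReLU activation, and padding
   positions are re-zeroed after every layer. The kernel size is a
   configuration choice (K=3 default); the layers *within* a block do not
   share parameters with each other, only across iterations. A quoted
   exponential receptive-field formula for 2-D image dilated convolutions,
   (2^(i+2)-1)^2, does not type-check for 1-D text; it is exposed only as
   the documented reference calculator `image_receptive_field`.

3. **Multi-head self-attention (MHA).** With Y the encoder output and
   Q = K = V = Y,

       Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V
       head_i = Attention(Y W_i^Q, Y W_i^K, Y W_i^V),
       MHA(Y) = concat(head_1 ... head_h) W^O,

   with h = 4 heads and d_k = d_v = d_model / h by default (d_k is a free
   choice; the equal-split convention is standard). Masked (padding) keys
   receive an additive logit of −1e9, which underflows to exactly zero
   weight after the softmax; padding-query outputs are defined as zero
   vectors. The layer is *bare*: no residual connection or layer
   normalization by default, matching the architecture as specified
   (`residual=True` adds a plain additive skip; see "MHA ablation" below
   for the practical consequence).

4. **CRF decoding.** A linear emission layer maps the encoder output to
   per-character label scores P; a linear-chain CRF with transition matrix
   W augmented by START/STOP boundary states scores a label sequence as

       S(X, y) = sum_i P[i, y_i] + W[START, y_1]
                 + sum_i W[y_i, y_{i+1}] + W[y_n, STOP].

   Training minimizes the mean per-sentence negative log-likelihood,
   −S(X,y) + log Z, with log Z computed by the forward algorithm in log
   space (log-sum-exp stabilized). Gradients are the standard
   forward–backward marginals minus observed counts. Decoding uses Viterbi;
   ties break toward the lowest label index at the latest differing
   position (so an all-zero score matrix decodes to all-O, label 0).
   Training always uses the unconstrained learned W; at decode time, hard
   BIO constraints (an I-X may only follow B-X/I-X of the same type,
   sequences may not open with I-X) are imposed by default by adding −1e4
   to illegal transitions. The finite constant avoids NaN arithmetic while
   exceeding any learnable score gap by orders of magnitude.

The whole stack, including backpropagation through every layer and the
Adagrad/RMSprop/Adam/RAdam optimizers and the Lookahead slow-weights
wrapper, is implemented in NumPy. Correctness of the hand-written gradients
is guarded by central-difference checks (CRF alone within 1e-4; the full
model within 1e-3 — probed at eps = 1e-6, small enough that the probe does
not cross ReLU breakpoints, which would otherwise contaminate the
finite-difference estimate).

## Tagging and corpus conventions

* Spans are 0-based, half-open [start, end): round-trip-safe arithmetic.
* "O" has index 0, so zero-initialized predictions are the null label.
* Gold data is decoded with `policy="strict"` (ill-formed runs are an
  error); predictions with `policy="repair"` (a dangling I-X opens a new
  mention), since a model may emit ill-formed runs when hard constraints
  are disabled.
* Documents are cut at the ideographic full stop `。`, the period staying
  with its sentence; windows longer than `max_len` (128) are hard-split,
  backing off to the nearest gap between mentions, and a mention that
  itself exceeds `max_len` is split and flagged rather than silently
  destroyed. An annotation straddling a period boundary is an error.
* Span-annotated files declare their offset dialect via `end_exclusive`;
  category names map to type codes through a configurable dictionary
  (the six CCKS-2019 Chinese names are built in).

## Reference configuration and defaults

| parameter | default | note |
|---|---|---|
| d_model | 128 | embedding size |
| filters | 128 | IDCNN channels; must equal MHA d_model |
| kernel_size | 3 | unstated in the architecture; standard choice |
| dilations / iterations | (1,1,2) / 4 | shared-parameter block |
| heads | 4 | h ∈ {1,2,4,8,16} sweepable via the CLI |
| dropout | 0.5 | between embedding and IDCNN |
| batch_size | 20 | |
| max_len | 128 | characters per window |
| learning_rate | 1e-3 | see below |
| optimizer | adam | adagrad, rmsprop, radam, lookahead_adam available |
| patience | 5 | early stopping on dev F1; epochs and the dev protocol are package choices, not inherited ones |

The conventional fine-tuning rate 3e-5 presumes a pretrained contextual
embedder; with the from-scratch trainable token table used here it trains
impractically slowly, so the package default is 1e-3 (3e-3 is used in the
scaled-down experiment configurations below, where the corpora are small
and convergence speed dominates).

Tests and the acceptance script run **scaled-down models** (d_model 32,
filters 32 or 16) and synthetic corpora of 10–1,500 sentences so that every
training path executes in minutes on one CPU; these sizes are the package's
own study conditions.

## Synthetic corpus generator

The generator produces labeled sentences whose structure mirrors what the
architecture is built to exploit, with no real patient text:

* background (non-entity) and entity characters drawn from **disjoint**
  blocks of the Unicode private-use area, so no test can depend on real
  Chinese lexical statistics (a readable single-character ASCII mode exists
  for documentation);
* per-type entity lexicons with heterogeneous length ranges (operations
  and diseases longest), sampled once per spec seed;
* **nested look-alikes** (`p_nested_lookalike`, default 0.3): an operation
  entry equals a disease entry plus a fixed suffix, so the type decision
  requires context past the shared prefix — the gastric-cancer /
  radical-gastrectomy confusion pattern;
* **parenthetical supplements** (`p_parenthetical`, default 0.15):
  full-width brackets with background text adjacent to long entities,
  stressing boundary decisions;
* **co-occurring dependent pairs** (`p_cooccur`, default 0.2): a disease
  and its derived operation placed in one sentence at least
  `cooccur_min_gap` (10) characters apart;
* every sentence ends with `。`; entity placement is sequential, so gold
  spans never overlap and always survive strict decoding.

Splits are generated from disjoint seed offsets of one spec, never by
shuffling a common pool, so held-out evaluation cannot leak memorized
sentences.

**What passing on this corpus does not show:** the generator has uniform
type frequencies, near-independent background characters, closed small
lexicons and no orthographic or segmentation ambiguity. Results on it
demonstrate that the architecture, gradients, and training loop work — not
that the model reaches any particular accuracy on real clinical text,
which is distributed only on request by the corresponding dataset holders.

## MHA ablation

The ablation scaffold (`use_mha=False`) retrains the identical stack
without the attention layer. On the co-occurrence-heavy synthetic corpus
at desk scale, the bare (residual-free) MHA layer *slows convergence*: its
output at every position is a softmax-weighted average of value
projections, and early in training — when attention is near-uniform — this
averages away the position-local features the emission layer needs, a
well-known reason transformer blocks carry residual connections. The
no-MHA encoder therefore leads while both models are far from
convergence; the gap narrows as training proceeds. The comparison
reported by the acceptance script and test suite uses the number of epochs
its corpus size affords on one CPU and reports the signed difference of
mean dev F1 over three seeds; see the decisions record for the observed
numbers at larger budgets.

## Known limitations

* No BIOES/BILOU schemes; no overlapping or discontinuous mentions
  (nesting appears in the error taxonomy, not the modeling target).
* The CRF is first-order (adjacent labels only); no n-best decoding.
* Single-threaded NumPy training: practical for the scaled-down study
  conditions, not for 128-dimensional models on real corpora.
* The external-embedder adapter is a contract plus projection; no
  pretrained weights ship with the package.
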