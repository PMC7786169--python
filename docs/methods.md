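# Methods

## Problem and data model

A workflow is a directed acyclic graph whose nodes are analysis tools and
whose edges feed one tool's output into the next. The package consumes a
flat edge table (workflow id, parent tool, child tool, three quality
flags) plus a monthly tool-usage table, both as tab-separated text. Tool
ids are canonicalized by stripping repository paths and trailing
versions, so sequences produced by different versions of a tool merge;
this is a deliberate choice — the learning target is tool identity, not
version. Workflows whose recorded edges contain a cycle are corrupt by
definition and are dropped with a warning rather than repaired.

A workflow is *shared* when it is published, not deleted and not
erroneous; everything else is non-shared. The flag propagates to labels:
a candidate next tool observed in any shared workflow for a given context
is a shared label, and shared membership wins when the same label is also
seen in non-shared workflows.

## Decomposition into training samples

Each DAG is decomposed into **every contiguous directed subpath of at
least two tools** — equivalently, every window of every maximal
source-to-sink path. The alternative (prefixes of maximal paths only)
was rejected because fragments that start mid-workflow carry real signal
and the minimum-length-2 rule implies full fragment enumeration. For a
fragment of n ≤ 25 tools the first n − 1 form the subsequence and the
n-th is a label; longer fragments are discarded. Labels are pooled per
unique subsequence, so samples are multi-label. The train/test split is
uniform over *unique* subsequences (default 80/20), which guarantees a
context never appears on both sides of the split.

## Encoding

Tools are indexed 1..V in lexicographic order (deterministic rebuilds);
index 0 is reserved for padding. Subsequences become integer vectors of
fixed length 25 padded with trailing zeros; label sets become multi-hot
bit vectors of length V. The combined (shared OR non-shared) matrix is
the training target; the shared/non-shared distinction only matters at
ranking and evaluation time.

## Usage weights

For every tool with usage data, a support vector regression is fitted to
its 12 trailing monthly counts (the month ordinal 1..12 is the only
feature). The six (kernel ∈ {rbf, poly, linear}) × (degree ∈ {2, 3})
combinations are compared by 5-fold cross-validated mean squared error,
and the winning regressor predicts month 13, clipped below at zero. The
tool's class weight is ln(1 + forecast): the logarithm compresses a
usage distribution that spans orders of magnitude (forecasts of 10, 10³
and 10⁵ give weights within a factor of six) so heavy tools cannot
monopolize the loss. The log base, the +1 offset and the zero/missing
case are not dictated by the underlying method description; ln(1 + x)
with a floor of 1.0 (also the default for tools without any usage data)
keeps every weight finite and strictly positive so no label's loss
contribution vanishes. An all-zero series short-circuits to a forecast
of 0 rather than attempting a degenerate fit.

## Class-balanced sampling

Fragment label frequencies are heavily skewed. Each training batch is
drawn in two uniform stages: first a label tool uniformly from the set of
all label tools, then a training sequence uniformly from the list of
sequences carrying that label. Sampling is with replacement (rare labels
are oversampled within an epoch — flattening is impossible without it),
and an epoch consists of floor(n_train / batch_size) batches. Multi-label
samples are indexed under every one of their labels.

## Network and training

Architecture: embedding of (V + 1) × d with the padding row frozen at
zero → dropout → GRU (h units, ELU candidate activation, returns
sequences) → dropout → GRU (h units, ELU) → dropout → dense V-unit
sigmoid layer. The GRU uses the standard update/reset gating
(h_t = z·h_{t−1} + (1 − z)·h̃); padded timesteps carry the hidden state
through unchanged, so the final state equals the state at the last real
token.

The loss is the usage-weighted binary cross-entropy over the combined
label vector, averaged over the V label positions and over the batch,
with predictions clipped into [1e−7, 1 − 1e−7] before the logarithm
(numerical necessity). It is minimized with RMSProp (ρ = 0.9,
ε = 1e−7). Forward pass, backpropagation through time and the optimizer
are implemented directly on NumPy arrays; gradients are verified against
central finite differences in the test suite, and the loss against a
scalar reference loop at 1e−10. Dropout masks and batch draws derive from
the run seed, so single-threaded runs are exactly reproducible.

Default training configuration for desk-scale corpora (hundreds of
unique samples, vocabularies of a few dozen tools): embedding 32, 64 GRU
units, dropout 0.1 at all three sites, learning rate 0.02, batch size 8,
10 epochs. Batch size scales with corpus size — the batching rule is
floor(n/batch) batches per epoch, so a corpus of a few hundred samples
needs small batches to get a useful number of updates; production-scale
corpora (10⁵ sequences) would use batches of 100–256 and the same code
path.

Hyperparameters can be tuned by sequential model-based (Bayesian)
optimization: a Gaussian-process surrogate (Matérn ν = 2.5) with
expected-improvement acquisition over a configurable search space,
spending the first third of the evaluation budget (default 20
evaluations) on random exploration. Each evaluation trains a short model
on 80% of the tuning split and scores validation loss on the rest. A
tree-structured Parzen estimator would serve equally; the GP surrogate
was chosen because it needs no dependencies beyond scikit-learn.

## Evaluation

precision@k is the fraction of the k top-scoring tools that are true
labels (ties broken by ascending tool index for determinism). Means are
computed separately for shared and non-shared label sets; a sample with
no labels in a category is *excluded* from that category's mean rather
than scored zero — this keeps the worked 1/2 = 0.5 example exact while
not penalizing undefined cases. The usage metric is the mean summed tool
weight of the top-k predictions. `run_experiments` repeats
split → train → evaluate with distinct seeds and reports per-epoch means
and standard deviations across runs.

## Inference

A query sequence is encoded and scored in one forward pass; candidates
are partitioned by a persisted shared-capable map (tools that ever
occurred as shared labels during extraction), each block sorted by
descending score, shared block first, truncated to the requested length.
The network outputs a single score vector, so *some* category source is
needed at inference time; the persisted map is the simplest one that is
stable across model reloads. When no map is available the full ranking is
returned flagged non-shared. Administrator overrides replace the ranked
list for a given last tool; extra (e.g. newly installed) tools are
appended, flagged `override`.

## Model store

One HDF5 file with three groups: `network` (all parameter arrays plus the
JSON-encoded configuration), `vocabulary` (the tool dictionary in index
order, plus the shared-capable flags), and `tool_weights` (sparse
index/value pairs plus the default weight). Arrays are stored at full
float64 precision, so reloaded models reproduce predictions bitwise. A
store missing any group is rejected as corrupt.

## Synthetic corpus

Real workflow corpora are private server databases, so the package ships
a generator with exactly enumerable ground truth. Tools are partitioned
into `n_layers` layers; each non-terminal tool is wired to `fanout`
successors in the next layer (drawn once per seed); a workflow is a
random walk from a start tool, branching into two successors with
probability `p_branch` at each step. Layering forbids back edges, so
every graph is acyclic by construction, and the successor map *is* the
ground truth. Defaults (40 tools, 5 layers, fanout 2, 400 workflows,
p_branch 0.25, 80% shared) yield roughly 200 unique training contexts
and ~21 fragments per workflow, and give every non-start tool at least
one appearance as a label — the property the uniform sampler relies on.
Usage tables draw a trend per tool (constant, linearly increasing,
linearly decreasing to exactly zero, or bursty) with Poisson noise.

What the generator does *not* emulate: real tool catalogues are not
layered (cycles of practice like "map → filter → re-map" exist as longer
chains), skip connections between distant layers, heavy-tailed workflow
lengths, and the 10³-fold label imbalance of production corpora. Passing
the synthetic recovery test therefore demonstrates that the pipeline can
learn a known compatibility structure from realistic-shaped inputs — not
that it reaches any particular precision on a production corpus.

## Numerical and design notes

- Sigmoid is evaluated in its two numerically stable branches; ELU uses
  `expm1` on the negative branch.
- Embedding row 0 (padding) is initialized to zero and excluded from
  gradient updates.
- Recurrent matrices are initialized orthogonally, input and output
  matrices Glorot-uniform, biases zero.
- Splits, dropout, batch draws and tuning all derive child seeds from a
  single integer via `numpy` seed sequences (kept below 2³¹).
- Training aborts with a diagnostic on a non-finite loss rather than
  continuing silently.

## Known limitations

- Training is CPU-bound pure NumPy: fine for desk-scale corpora
  (seconds) but hours at the 10⁵-sequence scale; the architecture and
  store format would carry over unchanged to an accelerated backend.
- The canonicalization rule assumes repository-style ids with the tool
  name in the second-to-last path segment.
- The shared-capable map is global per tool, not per context: a tool
  that is a shared label anywhere ranks in the shared block everywhere.
- `tune_hyperparameters` optimizes validation loss, not precision@k;
  the two usually but not always agree.
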