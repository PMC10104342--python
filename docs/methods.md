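# Methods

## Model and sampling semantics

A simulation model is a directed acyclic graph G = (V, E). Each node v has
a generating function f_v and a set of keyword bindings; a binding is
either a literal or a reference to another node (its parent). `build_graph`
derives the edge set from the references, rejects duplicate names,
unresolved references, self-loops, and cycles (cycle detection and
topological ordering are delegated to networkx), and expands plates.
Sampling is forward sampling: for each sample, nodes are evaluated once
each in topological order, with parent values passed as native Python
objects. There is no vectorization over the batch — functions are called
once per node per sample — so return values of any type and size are
supported without coercion. Topological ties are broken by declaration
order, making node evaluation order, column order, and output bytes
deterministic for a given graph and seed.

### Randomness contract

One master seed initializes a single `numpy.random.Generator` for the run.
Any generating function that declares a parameter named `rng` receives this
generator; functions that draw randomness from anywhere else are still
legal but forfeit the byte-identical reproducibility guarantee. All shipped
samplers (`dagforge.stdlib`, the example simulators) follow the contract.

### Selection

With a selection node present, sampling becomes rejection sampling:
candidates are drawn by ordinary forward sampling, the selection predicate
is evaluated at the node's position in the topological order, and a false
result discards the candidate. Sampling repeats until `n_samples` are
retained (predictable output size) or `max_rejection_attempts` candidates
(default 10,000 × n_samples) have been drawn, at which point the engine
raises with the acceptance rate observed so far — a near-zero acceptance
probability is a modelling error worth surfacing, not something to loop on
forever. Nodes earlier in the topological order than the selection node are
evaluated per candidate even if they are not its ancestors; this keeps the
semantics exactly "per-sample forward sampling plus a filter". The retained
sample follows the normalized conditional distribution; for the Bernoulli
example (accept X=1 surely, X=0 with probability 1/2) the retained
P(X=1) is (0.5·1)/(0.5·1 + 0.5·0.5) = 2/3, which the tests check
empirically.

At most one selection node is allowed per graph (and one stratify node):
composing several selections is ambiguous (joint vs. sequential
conditioning), so the builder rejects it.

### Missingness

A missing node names an underlying standard node and a truth-valued mask
node; its per-sample value is the underlying value where the mask is false
and a dedicated `MISSING` sentinel where it is true. The sentinel is a
singleton object distinct from `NaN`, so missing strings, arrays, and other
objects are representable; it serializes to an empty CSV field. MCAR, MAR,
and MNAR are obtained by making the mask depend on nothing, on observed
parents, or on the underlying value itself. A mask may not itself be a
missing/selection/stratify node — chained missingness is an extension
point, currently rejected. Both the underlying column and its masked
counterpart are written when the underlying node is observed; hide the
truth column with `observed=False`.

### Stratification

A stratify node computes a per-sample label; `stratify_rows` partitions the
retained rows by label (first-occurrence order) and the writer emits
`<csv_name>_<label>.csv` per stratum. Labels are sanitized to
`[A-Za-z0-9._-]` tokens; labels with no safe characters raise. Distinct
labels that sanitize to the same token merge — acceptable for file naming,
documented here as a deliberate simplification.

### Plates

Only flat plates are supported: all nodes tagged with the same plate id are
jointly replicated k times as `name_1..name_k`, with references between
same-plate nodes rewritten replicate-locally. References from outside a
plate into it are rejected as unresolved (there is no broadcast semantics);
nested and intersecting plates are out of scope. Mixture distributions are
a pattern, not a node kind: a categorical indicator node plus a node
dispatching on it (`dagforge.stdlib.mixture`).

## Output format

CSV (RFC 4180, UTF-8, header row) with one column per observed node in
topological order. Strings are written verbatim, integers and floats
canonically (`repr` of the float, so round-trips are exact), the missing
sentinel as an empty field, and small containers as JSON literals in the
cell. Values larger than `sidecar_threshold` (default 1,024 items or
characters) cannot reasonably live in a cell: numeric arrays go to `.npy`
sidecar files and sequence sets to FASTA (records `seq1..seqm`, written via
Biopython), with the relative path in the cell. Per-node custom serializers
override all of this.

## YAML dialect

The schema (`docs/yaml_schema.md`) is this package's own dialect: a
`graph` section mapping node names to `{function, kwargs, kind, observed,
plate, underlying, mask}` and an `instructions` section with run
parameters. A kwargs string equal to a declared node name is a parent
reference; the reserved prefix `raw:` forces literal interpretation; no
references are recognized inside nested containers. Unknown keys are
rejected by default and downgraded to warnings under `--lax`, protecting
against silent typos in node names. Functions are resolved in a
user-populated registry first, then by dotted-path import, so scripts can
use unpackaged local functions via `register_function`. `emit_yaml` writes
the plate-expanded graph back to a document that parses to an equal graph;
callables without a recoverable qualified name (lambdas, closures) are
rejected.

## Example simulators: what they emulate, and what they do not

**Coin toss.** Per-sample heads probability uniform on [0,1], toss count
uniform on {10..20}. The per-sequence heads fraction rank-correlates with
the sample's own probability — the property the end-to-end test checks.

**Shape images.** V, C, R, H in [0,1] are the independent firing
probabilities of a vertical bar, circle, rectangle, and horizontal bar
drawn (pixels set to 1.0) on a 64×64 zero background, at randomized
positions/sizes; the letters-to-shapes mapping is this package's mnemonic
convention. Bars span the full image extent with width 2–5; rectangles are
4 to size/3 on each side; circles have radius 4 to size/4 and are rasterized
by the pixel-center rule (a pixel is inside iff its integer coordinate is
within the radius), chosen so a brute-force per-pixel oracle can verify the
disc exactly. Fired shapes and their geometry are returned as ground truth.
These are synthetic stimuli for method benchmarking, not photographic
images: no noise, occlusion ordering effects (later shapes overwrite), or
intensity variation.

**Immune repertoires.** One repertoire is m = 500 DNA sequences with
lengths uniform on [30, 60] nt. Age drives diversity through a clone pool:
pool size = max(10, round(m·exp(−age/τ))) with τ = 50 years, sequences
drawn from the pool with replacement — expected distinct-clone count is
monotone non-increasing in age, the simplest mechanism with the documented
direction (repertoires become less diverse with age). Protocol bias is a
position-independent substitution: with probability 0.15 per position
(protocol `gc_rich`) a nucleotide is redrawn from a GC-heavy target
distribution; protocol `standard` applies none, so composition differences
vanish when bias is disabled. Disease implants the motif GATCGA into a
Bernoulli(0.2) subset of sequences at a uniform random valid offset,
overwriting; bias is applied before implantation so the implanted motif is
always intact. For healthy repertoires the expected motif occurrence count
has the closed form Σ_s (L_s − k + 1)/4^k, the oracle used in tests. These
defaults were fixed once as field-plausible benchmark settings; none of
V(D)J recombination, germline gene usage, or clonal expansion dynamics is
modelled, so passing tests demonstrate calibration of the stated
mechanisms, not biological realism.

## Numerical and design choices

- Truthiness of selection/mask values uses Python `bool()`; numpy bools and
  0/1 integers behave identically.
- `randint` in `dagforge.stdlib` is inclusive on both ends (toss counts 10
  and 20 both occur).
- Probability/weight validation tolerates 1e-9 absolute error on sums.
- Problem sizes in tests and in `scripts/acceptance.py` follow the study
  settings: n = 1,000 for the worked example, n = 10,000 for calibration
  checks (3-standard-error bands), 50 patients/arm for enrichment, 20
  replicates for the age sign test; the script completes in seconds.
- Degenerate inputs: empty spec lists, empty tables, and zero-acceptance
  selections raise immediately with context rather than producing empty
  output.

## Known limitations

No interventions/counterfactual surgery, no structure or parameter
learning, no time-series (dynamic) models, no nested plates, no streaming
or parallel sampling. Per-sample function calls cost Python-call overhead;
for very large n with cheap nodes a vectorized engine would be faster, but
per-sample calling is the semantic contract that makes arbitrary value
types possible.
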