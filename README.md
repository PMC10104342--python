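# dagforge

DAG-based data simulation with unconstrained variable types and functional
relations.

## The problem

Simulation studies in machine learning, causal inference, and biostatistics
need generators with full control of ground truth. Directed acyclic graphs
(DAGs) are the standard way to encode dependence structure — each variable
is a node, each arrow a direct dependence — but most DAG simulation
libraries restrict variables to numeric scalars and relations to
conditional probability tables or (generalized) linear forms. That rules
out exactly the data modern methods are built for: images, sequences, sets
of sequences.

`dagforge` drops those restrictions. A model is a DAG whose every node is
computed by an arbitrary Python callable of its parents' values, which are
passed as **native Python objects** — a node can return a string, a numpy
array, or a set of DNA sequences just as easily as a float. Sampling is
standard forward sampling: after validating acyclicity, nodes are evaluated
in topological order, once per sample,

x_v = f_v(x_pa(v); rng)    for v in topological order,

which covers both the Bayesian-network view (f_v samples from a conditional
distribution) and the structural-causal-model view (f_v is deterministic in
its parents plus exogenous noise drawn from `rng`).

Beyond standard nodes, three special node kinds emulate real-world data
collection:

- **Selection** — a per-sample accept/reject predicate; rejected candidates
  are redrawn, so the retained sample follows the selection-biased
  conditional distribution (rejection sampling);
- **Missing** — a masked copy of another node: where a truth-valued mask
  node fires, the value is replaced by a missing sentinel (empty CSV
  field), supporting MCAR/MAR/MNAR mechanisms depending on what the mask
  depends on;
- **Stratify** — a per-sample label that partitions the output into one CSV
  file per stratum.

Flat plates replicate a tagged node set k times (i.i.d.), and an `observed`
flag keeps latent nodes out of the output. Models can be built in Python or
declared in a succinct YAML dialect (see `docs/yaml_schema.md`) and run
from the command line.

## Worked example: coin-toss sequences

Each sample has its own heads probability `p ~ Uniform(0,1)` and toss count
`n ~ Uniform{10..20}`; the observable is the H/T string of `n` tosses.

```python
from dagforge import NodeRef, NodeSpec, SimulationConfig, build_graph, simulate
from dagforge.examples.coin_toss import coin_toss_sequence
from dagforge.stdlib import randint, uniform

graph = build_graph([
    NodeSpec("ProbHeads", uniform, {"low": 0.0, "high": 1.0}),
    NodeSpec("NumTosses", randint, {"low": 10, "high": 20}),
    NodeSpec("Sequence", coin_toss_sequence,
             {"p_heads": NodeRef("ProbHeads"), "n_tosses": NodeRef("NumTosses")}),
], name="coin_toss")

table = simulate(graph, SimulationConfig(n_samples=1000, seed=1))
seqs = table.columns["Sequence"]
print(seqs[:3])
print(min(len(s) for s in seqs), max(len(s) for s in seqs))
```

prints

```
['HTHHTHTHTTHTHHHHHH', 'HHTTHHHHTHHHTHTHHHHH', 'HHHHHHHHHHHH']
10 20
```

— three simulated toss strings (each row also carries its `ProbHeads` and
`NumTosses`), and the observed length range covering the full 10–20 bound.
The same model ships as YAML and runs from the shell:

```bash
dagforge run src/dagforge/examples/specs/coin_toss.yaml --seed 1 --outdir out/
dagforge render src/dagforge/examples/specs/coin_toss.yaml -o coin.dot
```

Two runs with the same seed produce byte-identical CSVs.

## Example simulators

- `dagforge.examples.coin_toss` — the model above.
- `dagforge.examples.shapes` — metadata scalars V, C, R, H give the
  probabilities that a Vertical bar, Circle, Rectangle, and Horizontal bar
  are overlaid (value 1.0) on a black 64×64 background, with the fired
  shapes and their geometry returned as ground truth.
- `dagforge.examples.airr` — per-patient adaptive immune receptor
  repertoires (sets of 30–60 nt DNA sequences): disease implants a motif
  into a fraction of sequences, age shrinks the clone pool (less diverse
  repertoires), and the sequencing protocol biases nucleotide composition.
  Repertoires are written as per-patient FASTA sidecar files.

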