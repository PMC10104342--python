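# YAML simulation document schema

A document is a mapping with an optional `name` and two required sections.
Unknown keys anywhere are errors in strict mode (default) and warnings in
lax mode (`--lax` on the CLI, `lax=True` in `parse_yaml`).

```yaml
name: my_model            # optional; graph name (default "model")

graph:                    # required; node-name -> node entry
  <NodeName>:
    function: pkg.mod.fn  # dotted path; required unless kind is "missing"
    kwargs:               # optional; argument bindings (see reference rule)
      param: value
    kind: standard        # optional; standard | selection | missing | stratify
    observed: true        # optional; false hides the column from output
    plate:                # optional; flat i.i.d. replication
      id: patients
      count: 5
    underlying: X         # missing-kind only: node whose values are masked
    mask: M               # missing-kind only: truth-valued mask node

instructions:             # required
  n_samples: 1000         # required; positive integer
  seed: 1                 # optional; master seed (omit for nondeterministic)
  output_dir: out         # optional; default "."
  csv_name: data          # optional; default "simulated"
  max_rejection_attempts: 100000   # optional; default 10000 * n_samples
```

## Reference rule

A `kwargs` value that is a **string exactly equal to a declared node name**
is a parent reference: the node receives that parent's value each sample.
Any other value is a literal. To pass the literal string `"A"` while a node
named `A` exists, write `raw:A` — the `raw:` prefix is stripped and the
rest is always literal. References are recognized only in top-level kwargs
strings, never inside nested lists or mappings.

## Function resolution

Dotted names are looked up first in the user registry
(`dagforge.register_function`), then by import, trying progressively
shorter module prefixes (`pkg.mod.Class.method` works). The resolved object
must be callable. If the callable declares a parameter named `rng`, the
engine passes its seeded `numpy.random.Generator`.

## Node kinds

- `standard` — a data column (unless `observed: false`).
- `selection` — must return a truth value; false discards the candidate
  sample. At most one per graph; contributes no column.
- `missing` — no `function`/`kwargs`; requires `underlying` and `mask`,
  both standard nodes. The column holds the underlying value where the
  mask is false and an empty field where it is true.
- `stratify` — returns a per-sample label; rows are written to
  `<csv_name>_<label>.csv` per sanitized label. At most one per graph;
  contributes no column.
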