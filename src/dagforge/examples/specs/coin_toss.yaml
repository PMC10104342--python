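name: coin_toss
graph:
  ProbHeads:
    function: dagforge.stdlib.uniform
    kwargs: {low: 0.0, high: 1.0}
  NumTosses:
    function: dagforge.stdlib.randint
    kwargs: {low: 10, high: 20}
  Sequence:
    function: dagforge.examples.coin_toss.coin_toss_sequence
    kwargs: {p_heads: ProbHeads, n_tosses: NumTosses}
instructions:
  n_samples: 1000
  seed: 1
  output_dir: .
  csv_name: coin_toss
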