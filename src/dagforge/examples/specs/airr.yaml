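name: airr_repertoires
graph:
  DiseaseState:
    function: dagforge.examples.airr.sample_disease_state
    kwargs: {prevalence: 0.5}
  Age:
    function: dagforge.examples.airr.sample_age
    kwargs: {low: 0.0, high: 100.0}
  Protocol:
    function: dagforge.examples.airr.sample_protocol
  Repertoire:
    function: dagforge.examples.airr.airr_repertoire
    kwargs: {disease_state: DiseaseState, age: Age, protocol: Protocol}
instructions:
  n_samples: 20
  seed: 7
  output_dir: .
  csv_name: airr
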