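name: shape_images
graph:
  V:
    function: dagforge.stdlib.uniform
    kwargs: {low: 0.0, high: 1.0}
  C:
    function: dagforge.stdlib.uniform
    kwargs: {low: 0.0, high: 1.0}
  R:
    function: dagforge.stdlib.uniform
    kwargs: {low: 0.0, high: 1.0}
  H:
    function: dagforge.stdlib.uniform
    kwargs: {low: 0.0, high: 1.0}
  Image:
    function: dagforge.examples.shapes.shape_image_pixels
    kwargs: {v: V, c: C, r: R, h: H}
instructions:
  n_samples: 25
  seed: 3
  output_dir: .
  csv_name: shapes
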