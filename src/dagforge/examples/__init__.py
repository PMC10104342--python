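"""Ready-to-run example simulators: coin-toss sequences, shape images,
and immune-receptor repertoires. Each ships with a YAML model under
``specs/`` and plain functions usable as node functions."""

from importlib import resources
from pathlib import Path

from . import airr, coin_toss, shapes  # noqa: F401


def spec_path(name: str) -> Path:
    """Absolute path to a shipped YAML model: 'coin_toss', 'shapes' or 'airr'."""
    path = resources.files(__package__) / "specs" / f"{name}.yaml"
    return Path(str(path))
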