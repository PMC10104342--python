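"""Value serialization for CSV output.

Values are held natively in memory until written. Scalars are written
canonically; the missing sentinel becomes an empty field; small containers
become quoted JSON literals; values larger than a size threshold go to
per-sample sidecar files (``.npy`` for numeric tensors, FASTA for sequence
sets) with the relative path in the cell.
"""

from __future__ import annotations

import json
import numbers
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class _MissingType:
    """Singleton sentinel for masked entries.

    Distinct from ``float('nan')`` so missing strings and objects are
    representable; rendered as an empty CSV field.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False

    def __reduce__(self):
        return (_MissingType, ())


MISSING = _MissingType()


class SequenceSet(Sequence):
    """An ordered collection of biological sequence strings.

    Serialized to a FASTA sidecar (records ``seq1 .. seqm``) when larger
    than the sidecar threshold.
    """

    def __init__(self, sequences: list[str]):
        self.sequences = list(sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, index):
        return self.sequences[index]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, SequenceSet):
            return self.sequences == other.sequences
        return NotImplemented

    def __repr__(self) -> str:
        return f"{type(self).__name__}({len(self)} sequences)"

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    def to_fasta(self, path: Path) -> None:
        records = (
            SeqRecord(Seq(seq), id=f"seq{i + 1}", description="")
            for i, seq in enumerate(self.sequences)
        )
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")


def _is_sequence_set(value) -> bool:
    return isinstance(value, SequenceSet) or (
        isinstance(value, (list, tuple))
        and len(value) > 0
        and all(isinstance(item, str) for item in value)
    )


def serialize_cell(
    value,
    *,
    node_name: str,
    row_index: int,
    sidecar_dir: Path | None,
    threshold: int = 1024,
) -> str:
    """Convert one native value to its CSV cell text.

    ``sidecar_dir`` is created lazily when the first oversized value is
    met; the returned cell then holds the sidecar path relative to the
    directory containing the CSV file.
    """
    if value is MISSING:
        return ""
    if isinstance(value, str):
        return value
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, numbers.Integral):
        return str(int(value))
    if isinstance(value, numbers.Real):
        return repr(float(value))

    if _is_sequence_set(value):
        seqset = value if isinstance(value, SequenceSet) else SequenceSet(list(value))
        if seqset.total_length() > threshold and sidecar_dir is not None:
            sidecar_dir.mkdir(parents=True, exist_ok=True)
            path = sidecar_dir / f"{node_name}_row{row_index}.fasta"
            seqset.to_fasta(path)
            return str(Path(sidecar_dir.name) / path.name)
        return json.dumps(list(seqset))

    if isinstance(value, np.ndarray):
        if value.size > threshold and sidecar_dir is not None:
            sidecar_dir.mkdir(parents=True, exist_ok=True)
            path = sidecar_dir / f"{node_name}_row{row_index}.npy"
            np.save(path, value)
            return str(Path(sidecar_dir.name) / path.name)
        return json.dumps(value.tolist())

    if isinstance(value, (list, tuple, dict)):
        try:
            return json.dumps(value)
        except TypeError:
            return str(value)

    return str(value)
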