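"""Forward sampling over a validated graph.

The engine walks the graph's topological order once per sample, calling
each node's generating function with its parent values (passed as native
Python objects, untranscoded). A selection node turns the walk into
rejection sampling: candidates failing the predicate are discarded and
redrawn until ``n_samples`` are retained or the rejection budget is
exhausted. Missing nodes mask their underlying node's values; a stratify
node labels each retained row for partitioned output.

All randomness derives from one ``numpy.random.Generator`` seeded by the
run config. Generating functions that declare a parameter named ``rng``
receive that generator; functions that ignore it sacrifice reproducibility.
"""

from __future__ import annotations

import csv
import inspect
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional

import numpy as np
import pandas as pd

from .errors import (
    FunctionEvaluationError,
    LabelError,
    RejectionBudgetExceededError,
)
from .graph import Graph, NodeRef, NodeSpec, topological_order
from .serialize import MISSING, serialize_cell

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Run parameters.

    ``max_rejection_attempts`` defaults to 10,000 x n_samples; it bounds the
    number of candidate draws when a selection node is present.
    ``serializers`` maps node names to custom value-to-text converters used
    by :func:`write_csv`. ``sidecar_threshold`` is the item/character count
    above which non-scalar values are written to sidecar files.
    """

    n_samples: int
    seed: Optional[int] = None
    output_dir: Path = Path(".")
    csv_name: str = "simulated"
    max_rejection_attempts: Optional[int] = None
    serializers: dict[str, Callable[[Any], str]] = field(default_factory=dict)
    sidecar_threshold: int = 1024

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        self.output_dir = Path(self.output_dir)
        if self.max_rejection_attempts is None:
            self.max_rejection_attempts = 10_000 * self.n_samples
        if self.max_rejection_attempts < self.n_samples:
            raise ValueError("max_rejection_attempts must be >= n_samples")


@dataclass
class SampleTable:
    """In-memory simulation result: one column per observed node.

    Column order equals topological order restricted to observed nodes;
    values are native Python objects (possibly non-scalar); masked entries
    hold the :data:`dagforge.serialize.MISSING` sentinel. ``labels`` carries
    the per-row stratify labels when the graph has a stratify node.
    """

    columns: dict[str, list]
    labels: Optional[list] = None

    @property
    def n_rows(self) -> int:
        if not self.columns:
            return 0
        return len(next(iter(self.columns.values())))

    def __len__(self) -> int:
        return self.n_rows

    def to_dataframe(self) -> pd.DataFrame:
        """View as a pandas DataFrame (MISSING entries become None)."""
        cleaned = {
            name: [None if v is MISSING else v for v in values]
            for name, values in self.columns.items()
        }
        return pd.DataFrame(cleaned, columns=list(self.columns))

    def row_subset(self, indices: list[int]) -> "SampleTable":
        return SampleTable(
            columns={
                name: [values[i] for i in indices]
                for name, values in self.columns.items()
            },
            labels=[self.labels[i] for i in indices] if self.labels else None,
        )


@dataclass
class StratifiedOutput:
    """Partition of a SampleTable by stratum label."""

    strata: dict[str, SampleTable]

    def total_rows(self) -> int:
        return sum(t.n_rows for t in self.strata.values())


def _accepts_rng(func: Callable) -> bool:
    try:
        params = inspect.signature(func).parameters
    except (TypeError, ValueError):  # builtins without introspectable signature
        return False
    return "rng" in params


def _call_node(
    spec: NodeSpec,
    values: dict[str, Any],
    rng: np.random.Generator,
    sample_index: int,
):
    kwargs = {
        key: values[val.name] if isinstance(val, NodeRef) else val
        for key, val in spec.kwargs.items()
    }
    if "rng" not in kwargs and _accepts_rng(spec.func):
        kwargs["rng"] = rng
    try:
        return spec.func(**kwargs)
    except Exception as exc:
        raise FunctionEvaluationError(spec.name, sample_index, exc) from exc


def simulate(graph: Graph, config: SimulationConfig) -> SampleTable:
    """Draw ``config.n_samples`` retained samples by forward sampling.

    Each sample is generated node-by-node in topological order; literal
    bindings are passed as-is and NodeRef bindings as the parent's value
    for that sample. When a selection node is present, candidates failing
    it are rejected and redrawn (see module docstring); the selection node
    contributes no output column, nor does a stratify node.

    Raises
    ------
    FunctionEvaluationError
        wrapping a user-function failure, with node name and sample index.
    RejectionBudgetExceededError
        when ``max_rejection_attempts`` candidates were drawn before
        ``n_samples`` were accepted.
    """
    rng = np.random.default_rng(config.seed)
    order = topological_order(graph)
    ordered_specs = [graph[name] for name in order]
    has_selection = graph.selection_node is not None
    has_stratify = graph.stratify_node is not None

    column_names = [
        s.name
        for s in ordered_specs
        if s.kind in ("standard", "missing") and s.observed
    ]
    columns: dict[str, list] = {name: [] for name in column_names}
    labels: list = [] if has_stratify else None

    logger.info("simulating %d samples over nodes: %s", config.n_samples, order)

    retained = 0
    attempts = 0
    while retained < config.n_samples:
        if has_selection and attempts >= config.max_rejection_attempts:
            raise RejectionBudgetExceededError(retained, attempts)
        attempts += 1
        values: dict[str, Any] = {}
        label = None
        accepted = True
        for spec in ordered_specs:
            if spec.kind == "missing":
                mask_value = values[spec.mask]
                values[spec.name] = (
                    MISSING if bool(mask_value) else values[spec.underlying]
                )
            elif spec.kind == "selection":
                if not bool(_call_node(spec, values, rng, retained)):
                    accepted = False
                    break
            elif spec.kind == "stratify":
                label = _call_node(spec, values, rng, retained)
                values[spec.name] = label
            else:
                values[spec.name] = _call_node(spec, values, rng, retained)
        if not accepted:
            continue
        for name in column_names:
            columns[name].append(values[name])
        if has_stratify:
            labels.append(label)
        retained += 1

    if has_selection:
        logger.info(
            "selection: accepted %d of %d candidates (rate %.3f)",
            retained,
            attempts,
            retained / attempts,
        )
    return SampleTable(columns=columns, labels=labels)


_LABEL_UNSAFE = re.compile(r"[^A-Za-z0-9._-]+")


def sanitize_label(label) -> str:
    """Reduce a stratum label to a file-name-safe token.

    Raises :class:`LabelError` if nothing safe remains.
    """
    token = _LABEL_UNSAFE.sub("_", str(label)).strip("_")
    if not token or set(token) <= {".", "_"}:
        raise LabelError(f"stratum label {label!r} has no file-name-safe form")
    return token


def stratify_rows(table: SampleTable, graph: Graph) -> StratifiedOutput:
    """Partition the table's rows by their stratify label.

    Strata appear in order of first occurrence; the stratify node itself
    contributes no data column. Labels are sanitized to file-name-safe
    tokens (distinct labels that sanitize to the same token are merged
    into one stratum).
    """
    if graph.stratify_node is None:
        raise ValueError(f"graph {graph.name!r} has no stratify node")
    if table.labels is None:
        raise ValueError("table carries no stratify labels")
    groups: dict[str, list[int]] = {}
    for i, label in enumerate(table.labels):
        groups.setdefault(sanitize_label(label), []).append(i)
    return StratifiedOutput(
        strata={
            token: table.row_subset(indices) for token, indices in groups.items()
        }
    )


def write_csv(
    table: SampleTable,
    config: SimulationConfig,
    stratum_label: Optional[str] = None,
) -> Path:
    """Write the table as an RFC-4180 CSV file and return its path.

    Header = observed node names in column order; missing sentinel becomes
    an empty field; strings are written verbatim; non-scalar values follow
    the rules in :mod:`dagforge.serialize`. A stratified run passes the
    stratum label, producing ``<csv_name>_<label>.csv``.
    """
    if table.n_rows == 0:
        raise ValueError("refusing to write an empty table")
    stem = config.csv_name if stratum_label is None else f"{config.csv_name}_{stratum_label}"
    config.output_dir.mkdir(parents=True, exist_ok=True)
    path = config.output_dir / f"{stem}.csv"
    sidecar_dir = config.output_dir / f"{stem}_files"

    names = list(table.columns)
    try:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(names)
            for i in range(table.n_rows):
                row = []
                for name in names:
                    value = table.columns[name][i]
                    if name in config.serializers and value is not MISSING:
                        row.append(config.serializers[name](value))
                    else:
                        row.append(
                            serialize_cell(
                                value,
                                node_name=name,
                                row_index=i,
                                sidecar_dir=sidecar_dir,
                                threshold=config.sidecar_threshold,
                            )
                        )
                writer.writerow(row)
    except OSError as exc:
        raise OSError(f"failed writing CSV to {path}: {exc}") from exc
    return path


def run_simulation(
    graph: Graph, config: SimulationConfig
) -> tuple[SampleTable, list[Path]]:
    """Simulate, stratify if the graph calls for it, and write CSV file(s).

    Returns the in-memory table and the written paths. This is the
    one-call entry point used by the CLI.
    """
    table = simulate(graph, config)
    if graph.stratify_node is not None:
        stratified = stratify_rows(table, graph)
        paths = []
        for token, subtable in stratified.strata.items():
            paths.append(write_csv(subtable, config, stratum_label=token))
            logger.info("stratum %s: %d rows", token, subtable.n_rows)
        return table, paths
    path = write_csv(table, config)
    logger.info("wrote %d rows to %s", table.n_rows, path)
    return table, [path]
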