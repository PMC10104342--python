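"""YAML dialect for specifying simulations.

A simulation document has two required sections plus an optional model
name::

    name: coin_toss                # optional graph name
    graph:                         # node-name -> node entry
      ProbHeads:
        function: dagforge.stdlib.uniform
        kwargs: {low: 0.0, high: 1.0}
      NumTosses:
        function: dagforge.stdlib.randint
        kwargs: {low: 10, high: 20}
      Sequence:
        function: mypkg.funcs.coin_toss_sequence
        kwargs: {p_heads: ProbHeads, n_tosses: NumTosses}
    instructions:
      n_samples: 1000
      seed: 1
      output_dir: out
      csv_name: coin_toss

Node entry keys: ``function`` (dotted path, required except for
``kind: missing``), ``kwargs``, ``kind`` (standard/selection/missing/
stratify, default standard), ``observed`` (default true), ``plate``
(``{id, count}``), and for missing nodes ``underlying`` and ``mask``.

Reference rule: a kwargs value that is a string exactly matching a
declared node name is a parent reference; every other value is a literal.
The reserved prefix ``raw:`` forces literal interpretation of the rest of
the string (so the literal string "A" next to a node named A is written
``raw:A``). References are recognized only in top-level kwargs strings,
never inside nested lists or mappings.

Function names are resolved against the user registry
(:func:`register_function`) first, then by dotted-path import. Unknown
keys anywhere are rejected unless ``lax=True``, which downgrades them to
warnings.
"""

from __future__ import annotations

import importlib
import warnings
from typing import Any, Callable, Optional

import yaml

from .engine import SimulationConfig
from .errors import (
    FunctionResolutionError,
    SchemaError,
    UnserializableFunctionError,
)
from .graph import Graph, NodeRef, NodeSpec, build_graph

RAW_PREFIX = "raw:"

_REGISTRY: dict[str, Callable] = {}


def register_function(func: Callable = None, *, name: Optional[str] = None):
    """Register a callable so YAML documents can reference it by name.

    Usable as a decorator. The registered name defaults to the function's
    qualified dotted name; registry entries shadow import resolution.
    """
    def _register(f: Callable) -> Callable:
        key = name or f"{f.__module__}.{f.__qualname__}"
        _REGISTRY[key] = f
        return f

    return _register(func) if func is not None else _register


def clear_registry() -> None:
    _REGISTRY.clear()


def resolve_function(dotted: str) -> Callable:
    """Resolve a dotted name to a callable: registry first, then import.

    Import resolution tries progressively shorter module prefixes, so both
    ``pkg.module.func`` and ``pkg.module.Class.method`` work.
    """
    if dotted in _REGISTRY:
        return _REGISTRY[dotted]
    parts = dotted.split(".")
    for split in range(len(parts) - 1, 0, -1):
        module_name = ".".join(parts[:split])
        try:
            module = importlib.import_module(module_name)
        except ImportError:
            continue
        obj: Any = module
        try:
            for attr in parts[split:]:
                obj = getattr(obj, attr)
        except AttributeError:
            continue
        if not callable(obj):
            raise FunctionResolutionError(f"{dotted!r} resolved but is not callable")
        return obj
    raise FunctionResolutionError(
        f"cannot resolve function {dotted!r}: not in the registry and not importable"
    )


_NODE_KEYS = {"function", "kwargs", "kind", "observed", "plate",
              "underlying", "mask"}
_INSTRUCTION_KEYS = {"n_samples", "seed", "output_dir", "csv_name",
                     "max_rejection_attempts"}
_TOP_KEYS = {"name", "graph", "instructions"}


def _check_keys(mapping: dict, allowed: set, path: str, lax: bool) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        msg = f"unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        if lax:
            warnings.warn(f"{path}: {msg}", stacklevel=3)
        else:
            raise SchemaError(msg, path=path)


def _require_mapping(obj, path: str) -> dict:
    if not isinstance(obj, dict):
        raise SchemaError(f"expected a mapping, got {type(obj).__name__}", path=path)
    return obj


def _parse_kwargs(raw: dict, node_names: set, path: str) -> dict:
    kwargs: dict[str, Any] = {}
    for param, value in raw.items():
        if isinstance(value, str):
            if value.startswith(RAW_PREFIX):
                kwargs[param] = value[len(RAW_PREFIX):]
            elif value in node_names:
                kwargs[param] = NodeRef(value)
            else:
                kwargs[param] = value
        else:
            kwargs[param] = value
    return kwargs


def parse_yaml(text: str, lax: bool = False) -> tuple[Graph, SimulationConfig]:
    """Parse a simulation document into a validated Graph and config.

    Raises :class:`SchemaError` for structural problems (with the YAML path
    of the offending entry), :class:`FunctionResolutionError` for
    unresolvable function names, and the ``build_graph`` errors for graph
    problems.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"invalid YAML: {exc}") from exc
    doc = _require_mapping(doc, "<document>")
    _check_keys(doc, _TOP_KEYS, "<document>", lax)
    if "graph" not in doc:
        raise SchemaError("missing required section", path="graph")
    if "instructions" not in doc:
        raise SchemaError("missing required section", path="instructions")

    graph_section = _require_mapping(doc["graph"], "graph")
    if not graph_section:
        raise SchemaError("graph section declares no nodes", path="graph")
    node_names = set(graph_section)

    specs: list[NodeSpec] = []
    for node_name, entry in graph_section.items():
        path = f"graph.{node_name}"
        entry = _require_mapping(entry, path)
        _check_keys(entry, _NODE_KEYS, path, lax)
        kind = entry.get("kind", "standard")

        plate = None
        if "plate" in entry:
            plate_entry = _require_mapping(entry["plate"], f"{path}.plate")
            _check_keys(plate_entry, {"id", "count"}, f"{path}.plate", lax)
            if "id" not in plate_entry or "count" not in plate_entry:
                raise SchemaError("plate needs 'id' and 'count'", path=f"{path}.plate")
            plate = (str(plate_entry["id"]), int(plate_entry["count"]))

        if kind == "missing":
            for key in ("underlying", "mask"):
                if key not in entry:
                    raise SchemaError(f"missing node needs {key!r}", path=path)
            specs.append(
                NodeSpec(
                    name=node_name,
                    kind="missing",
                    underlying=str(entry["underlying"]),
                    mask=str(entry["mask"]),
                    observed=bool(entry.get("observed", True)),
                    plate=plate,
                )
            )
            continue

        if "function" not in entry:
            raise SchemaError("node entry needs a 'function'", path=path)
        func = resolve_function(str(entry["function"]))
        raw_kwargs = entry.get("kwargs", {}) or {}
        raw_kwargs = _require_mapping(raw_kwargs, f"{path}.kwargs")
        specs.append(
            NodeSpec(
                name=node_name,
                func=func,
                kwargs=_parse_kwargs(raw_kwargs, node_names, f"{path}.kwargs"),
                kind=kind,
                observed=bool(entry.get("observed", True)),
                plate=plate,
            )
        )

    instructions = _require_mapping(doc["instructions"], "instructions")
    _check_keys(instructions, _INSTRUCTION_KEYS, "instructions", lax)
    if "n_samples" not in instructions:
        raise SchemaError("missing required key", path="instructions.n_samples")
    n_samples = instructions["n_samples"]
    if not isinstance(n_samples, int) or n_samples < 1:
        raise SchemaError(
            f"n_samples must be a positive integer, got {n_samples!r}",
            path="instructions.n_samples",
        )
    config = SimulationConfig(
        n_samples=n_samples,
        seed=instructions.get("seed"),
        output_dir=instructions.get("output_dir", "."),
        csv_name=str(instructions.get("csv_name", "simulated")),
        max_rejection_attempts=instructions.get("max_rejection_attempts"),
    )
    graph = build_graph(specs, name=str(doc.get("name", "model")))
    return graph, config


def _qualified_name(func: Callable) -> str:
    for key, registered in _REGISTRY.items():
        if registered is func:
            return key
    module = getattr(func, "__module__", None)
    qualname = getattr(func, "__qualname__", None)
    if not module or not qualname or "<" in qualname:
        raise UnserializableFunctionError(
            f"callable {func!r} has no recoverable qualified name "
            "(lambdas and closures cannot be written to YAML)"
        )
    dotted = f"{module}.{qualname}"
    try:
        resolved = resolve_function(dotted)
    except FunctionResolutionError as exc:
        raise UnserializableFunctionError(
            f"callable {func!r}: qualified name {dotted!r} does not resolve "
            "back to it; register it with register_function first"
        ) from exc
    if resolved is not func:
        raise UnserializableFunctionError(
            f"qualified name {dotted!r} resolves to a different object than {func!r}"
        )
    return dotted


def _emit_value(value, node_names: set):
    if isinstance(value, NodeRef):
        return value.name
    if isinstance(value, str) and (value in node_names or value.startswith(RAW_PREFIX)):
        return RAW_PREFIX + value
    return value


def emit_yaml(graph: Graph, config: SimulationConfig) -> str:
    """Serialize a graph + config back to a document that parses to an
    equivalent pair (round-trip property).

    Raises :class:`UnserializableFunctionError` for callables without a
    recoverable qualified name.
    """
    node_names = set(graph.node_names())
    graph_section: dict[str, dict] = {}
    for spec in graph.nodes:
        entry: dict[str, Any] = {}
        if spec.kind != "standard":
            entry["kind"] = spec.kind
        if spec.kind == "missing":
            entry["underlying"] = spec.underlying
            entry["mask"] = spec.mask
        else:
            entry["function"] = _qualified_name(spec.func)
            if spec.kwargs:
                entry["kwargs"] = {
                    k: _emit_value(v, node_names) for k, v in spec.kwargs.items()
                }
        if not spec.observed:
            entry["observed"] = False
        if spec.plate is not None:
            entry["plate"] = {"id": spec.plate[0], "count": spec.plate[1]}
        graph_section[spec.name] = entry

    instructions: dict[str, Any] = {"n_samples": config.n_samples}
    if config.seed is not None:
        instructions["seed"] = config.seed
    instructions["output_dir"] = str(config.output_dir)
    instructions["csv_name"] = config.csv_name

    doc = {"name": graph.name, "graph": graph_section, "instructions": instructions}
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)
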