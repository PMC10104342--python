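"""Stock generating functions for common node distributions.

All samplers accept the engine-supplied ``rng`` (a seeded
``numpy.random.Generator``), so models built from them are reproducible.
They return plain Python scalars, not 0-d numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, DomainError


def constant(value, rng=None):
    """Return ``value`` unchanged for every sample."""
    return value


def uniform(low: float = 0.0, high: float = 1.0, rng=None) -> float:
    """Continuous uniform draw on [low, high)."""
    if high < low:
        raise DomainError(f"uniform: high ({high}) < low ({low})")
    return float(rng.uniform(low, high))


def randint(low: int, high: int, rng=None) -> int:
    """Integer uniform draw on [low, high], both ends inclusive."""
    if high < low:
        raise DomainError(f"randint: high ({high}) < low ({low})")
    return int(rng.integers(low, high + 1))


def bernoulli(p: float, rng=None) -> int:
    """0/1 draw with success probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"bernoulli: p={p} outside [0, 1]")
    return int(rng.random() < p)


def normal(loc: float = 0.0, scale: float = 1.0, rng=None) -> float:
    """Gaussian draw with mean ``loc`` and standard deviation ``scale``."""
    if scale < 0:
        raise DomainError(f"normal: scale must be >= 0, got {scale}")
    return float(rng.normal(loc, scale))


def choice(options: list, p: list | None = None, rng=None):
    """Draw one element of ``options``, uniformly or with weights ``p``."""
    if not options:
        raise DomainError("choice: options list is empty")
    if p is not None:
        if len(p) != len(options):
            raise ConfigError(
                f"choice: {len(p)} weights for {len(options)} options"
            )
        if abs(sum(p) - 1.0) > 1e-9:
            raise ConfigError(f"choice: weights sum to {sum(p)}, not 1")
    index = rng.choice(len(options), p=p)
    return options[int(index)]


def linear(x: float, slope: float = 1.0, intercept: float = 0.0,
           noise_sd: float = 0.0, rng=None) -> float:
    """``slope * x + intercept`` plus optional Gaussian noise."""
    if noise_sd < 0:
        raise DomainError(f"linear: noise_sd must be >= 0, got {noise_sd}")
    noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
    return slope * float(x) + intercept + noise


def mixture(component, rng=None, **component_funcs):
    """Dispatch to one of several generating functions by component label.

    The documented mixture-distribution pattern: pair a categorical
    component-indicator node (e.g. :func:`choice`) with a node whose
    function is ``mixture``, binding ``component`` to the indicator and
    each ``component_funcs[label]`` to a zero-argument callable (or use
    ``functools.partial`` to freeze parameters).
    """
    key = str(component)
    if key not in component_funcs:
        raise DomainError(
            f"mixture: no component function for label {key!r}; "
            f"have {sorted(component_funcs)}"
        )
    func = component_funcs[key]
    import inspect

    try:
        if "rng" in inspect.signature(func).parameters:
            return func(rng=rng)
    except (TypeError, ValueError):
        pass
    return func()
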