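"""Immune-repertoire simulator: patient metadata control sequence patterns.

Each simulated patient carries an adaptive immune receptor repertoire
(AIRR): a set of variable-length DNA sequences. Three metadata variables
shape it:

* ``disease_state`` — diseased patients have a fixed disease motif
  implanted into a fraction of their sequences at a uniform random offset,
  the ground-truth signal for benchmarking repertoire classifiers;
* ``age`` — repertoires lose diversity with age: sequences are drawn with
  replacement from a clone pool whose size shrinks exponentially in age,
  so older patients repeat clones more often;
* ``protocol`` — the sequencing protocol biases nucleotide composition via
  a position-independent substitution toward a protocol-specific target
  distribution.

Sequences are manipulated internally as int arrays over {0,1,2,3} = ACGT
and converted to strings on return.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigError, DomainError
from ..serialize import SequenceSet

NUCLEOTIDES = "ACGT"
_NUC_ARRAY = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)


class Repertoire(SequenceSet):
    """One patient's set of DNA sequences (serialized as FASTA sidecars)."""


@dataclass
class ProtocolBias:
    """Position-independent substitution: each nucleotide is replaced with
    probability ``strength`` by a draw from ``target`` (probabilities over
    A, C, G, T)."""

    strength: float = 0.0
    target: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigError(f"bias strength {self.strength} outside [0, 1]")
        if abs(sum(self.target) - 1.0) > 1e-9:
            raise ConfigError(f"bias target {self.target} does not sum to 1")


@dataclass
class RepertoireParams:
    """Generator settings for one repertoire.

    Defaults: 500 sequences of 30-60 nt; disease motif GATCGA implanted
    into a fraction 0.2 of a diseased patient's sequences; clone-pool size
    max(pool_min, round(n_sequences * exp(-age / tau))) with tau = 50
    years; protocols 'standard' (no bias) and 'gc_rich' (15% substitution
    toward a GC-heavy target).
    """

    n_sequences: int = 500
    length_range: tuple[int, int] = (30, 60)
    motif: str = "GATCGA"
    implant_fraction: float = 0.2
    pool_min: int = 10
    tau: float = 50.0
    protocols: dict[str, ProtocolBias] = field(
        default_factory=lambda: {
            "standard": ProtocolBias(),
            "gc_rich": ProtocolBias(strength=0.15, target=(0.1, 0.4, 0.4, 0.1)),
        }
    )

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid length range {self.length_range}")
        if len(self.motif) > lo:
            raise ConfigError(
                f"motif {self.motif!r} ({len(self.motif)} nt) is longer than "
                f"the minimum sequence length {lo}"
            )
        if set(self.motif) - set(NUCLEOTIDES):
            raise ConfigError(f"motif {self.motif!r} not over alphabet ACGT")
        if not 0.0 <= self.implant_fraction <= 1.0:
            raise ConfigError(
                f"implant_fraction {self.implant_fraction} outside [0, 1]"
            )
        if self.n_sequences < 1 or self.pool_min < 1 or self.tau <= 0:
            raise ConfigError("n_sequences, pool_min and tau must be positive")


def clone_pool_size(age: float, params: RepertoireParams) -> int:
    """Number of distinct clones available at ``age`` years:
    ``max(pool_min, round(n_sequences * exp(-age / tau)))`` — monotone
    non-increasing in age."""
    return max(params.pool_min, round(params.n_sequences * np.exp(-age / params.tau)))


def _motif_to_ints(motif: str) -> np.ndarray:
    return np.array([NUCLEOTIDES.index(ch) for ch in motif], dtype=np.int8)


def airr_repertoire(
    disease_state: int,
    age: float,
    protocol: str,
    params: RepertoireParams | None = None,
    rng: np.random.Generator | None = None,
) -> Repertoire:
    """Simulate one patient's repertoire conditioned on metadata.

    Pipeline: draw a clone pool of uniform-random sequences (pool size set
    by ``age``), sample ``n_sequences`` clones with replacement, apply the
    protocol's substitution bias, then — for diseased patients — implant
    the disease motif into a Bernoulli(``implant_fraction``) subset at a
    uniform random valid offset. Bias precedes implantation so the
    implanted motif is always intact.
    """
    params = params or RepertoireParams()
    if age < 0:
        raise DomainError(f"age must be >= 0, got {age}")
    if int(disease_state) not in (0, 1):
        raise DomainError(f"disease_state must be 0 or 1, got {disease_state!r}")
    if protocol not in params.protocols:
        raise DomainError(
            f"unknown protocol {protocol!r}; configured: "
            f"{sorted(params.protocols)}"
        )
    rng = rng if rng is not None else np.random.default_rng()

    lo, hi = params.length_range
    pool_size = clone_pool_size(age, params)
    pool_lengths = rng.integers(lo, hi + 1, size=pool_size)
    pool = [rng.integers(0, 4, size=length).astype(np.int8)
            for length in pool_lengths]

    draws = rng.integers(0, pool_size, size=params.n_sequences)
    seqs = [pool[i].copy() for i in draws]

    bias = params.protocols[protocol]
    if bias.strength > 0:
        target = np.asarray(bias.target)
        for seq in seqs:
            hit = rng.random(seq.shape[0]) < bias.strength
            n_hit = int(hit.sum())
            if n_hit:
                seq[hit] = rng.choice(4, size=n_hit, p=target)

    if int(disease_state) == 1 and params.implant_fraction > 0:
        motif = _motif_to_ints(params.motif)
        k = motif.shape[0]
        for seq in seqs:
            if rng.random() < params.implant_fraction:
                offset = int(rng.integers(0, seq.shape[0] - k + 1))
                seq[offset:offset + k] = motif

    texts = [
        _NUC_ARRAY[seq].tobytes().decode("ascii") for seq in seqs
    ]
    return Repertoire(texts)


@dataclass
class PatientParams:
    """Population distributions for patient metadata."""

    prevalence: float = 0.5
    age_range: tuple[float, float] = (0.0, 100.0)
    protocol_freqs: dict[str, float] = field(
        default_factory=lambda: {"standard": 0.5, "gc_rich": 0.5}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError(f"prevalence {self.prevalence} outside [0, 1]")
        total = sum(self.protocol_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"protocol frequencies sum to {total}, must sum to 1"
            )


def patient_metadata(
    rng: np.random.Generator, params: PatientParams | None = None
) -> tuple[int, float, str]:
    """Draw one patient's (disease_state, age, protocol) independently."""
    params = params or PatientParams()
    disease_state = int(rng.random() < params.prevalence)
    age = float(rng.uniform(*params.age_range))
    labels = list(params.protocol_freqs)
    freqs = [params.protocol_freqs[label] for label in labels]
    protocol = labels[int(rng.choice(len(labels), p=freqs))]
    return disease_state, age, protocol


def sample_disease_state(rng, prevalence: float = 0.5) -> int:
    """Node function: Bernoulli disease indicator."""
    if not 0.0 <= prevalence <= 1.0:
        raise DomainError(f"prevalence {prevalence} outside [0, 1]")
    return int(rng.random() < prevalence)


def sample_age(rng, low: float = 0.0, high: float = 100.0) -> float:
    """Node function: uniform patient age in years."""
    if low < 0 or high < low:
        raise DomainError(f"invalid age range [{low}, {high}]")
    return float(rng.uniform(low, high))


def sample_protocol(rng, freqs: dict[str, float] | None = None) -> str:
    """Node function: categorical protocol label."""
    freqs = freqs or {"standard": 0.5, "gc_rich": 0.5}
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"protocol frequencies sum to {total}, must sum to 1")
    labels = list(freqs)
    return labels[int(rng.choice(len(labels), p=[freqs[l] for l in labels]))]
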