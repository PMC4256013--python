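"""Probit choice models for sequential two-tone comparison.

All models map a trial's stimuli (and, for the history-sensitive ones, the
recent stimulus history) to the probability of responding "first tone
higher" through the standard normal CDF.

The history-sensitive decision variable is a linear combination of the
current first tone, the first tones of the K most recent trials, the
current second tone, and the running mean of first tones in the block —
the "memory trace".  With the weight on the second tone fixed at −1 and
the remaining weights summing to +1 the model is invariant to a common
shift of all log-frequencies, i.e. it compares the second tone to a
contraction of the first tone toward the block's stimulus history.

Missing history early in a block self-anchors to the current first tone:
any lag term without a completed trial behind it, and the memory trace
before any trial has completed, take the value of the current x1.  This
keeps the weight sum at zero on every trial, so trial 1 reduces exactly
to the history-free (naive) model rather than inheriting an arbitrary
offset of order weight × log-frequency.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "ModelTag",
    "ContractionWeights",
    "ObserverParams",
    "MemoryState",
    "default_weights",
    "naive_weights",
    "empty_memory",
    "update_memory",
    "p_first_higher_full",
    "p_first_higher_memory_trace",
    "p_first_higher_naive",
    "p_first_higher_response_bias",
    "sample_response",
]


class ModelTag(enum.Enum):
    FULL_LN = "full-ln"
    MEMORY_TRACE = "memory-trace"
    NAIVE = "naive"
    RESPONSE_BIAS = "response-bias"


@dataclass(frozen=True)
class ContractionWeights:
    """Fixed linear weights of the history-sensitive decision variable.

    a0 multiplies the current first tone, ``a_hist[k]`` the first tone of
    the (k+1)-th most recent completed trial, b the current second tone,
    and c the running mean of past first tones.
    """

    a0: float
    a_hist: tuple[float, ...]
    b: float
    c: float

    @property
    def k(self) -> int:
        return len(self.a_hist)

    @property
    def weight_sum(self) -> float:
        return self.a0 + sum(self.a_hist) + self.b + self.c

    def drive(self, mem: "MemoryState", x1: float, x2: float) -> float:
        """Linear decision variable; missing history self-anchors to x1."""
        s = self.a0 * x1 + self.b * x2
        hist = mem.x1_history
        for k, a in enumerate(self.a_hist):
            s += a * (hist[k] if k < len(hist) else x1)
        s += self.c * (mem.m if mem.n_seen > 0 else x1)
        return s


def default_weights(
    contraction: float = 0.35,
    decay: float = 0.6,
    k: int = 3,
    trace_fraction: float = 0.5,
) -> ContractionWeights:
    """Default contraction weights.

    ``contraction`` is the total weight moved from the current first tone
    onto its history (the contraction fraction gamma); ``trace_fraction``
    of it goes to the running-mean trace and the rest is spread over the
    ``k`` most recent first tones with geometrically decaying weights
    (ratio ``decay``).  b is fixed at −1 and a0 = 1 − gamma, so the
    weights sum to zero and the model is shift-invariant in log-frequency.

    These are package defaults chosen to produce contraction of realistic
    strength; they are configuration, not fitted constants.
    """
    if not 0.0 <= contraction < 1.0:
        raise ValueError("contraction must be in [0, 1)")
    c = trace_fraction * contraction
    hist_mass = contraction - c
    if k > 0:
        raw = np.array([decay**i for i in range(k)])
        a_hist = tuple(hist_mass * raw / raw.sum())
    else:
        a_hist = ()
        c = contraction
    return ContractionWeights(a0=1.0 - contraction, a_hist=a_hist, b=-1.0, c=c)


def naive_weights() -> ContractionWeights:
    """Weights that reduce the history model to the naive comparator."""
    return ContractionWeights(a0=1.0, a_hist=(), b=-1.0, c=0.0)


@dataclass(frozen=True)
class MemoryState:
    """Running history of first tones within a block.

    ``m`` is the mean of the first-tone log-frequencies of all completed
    trials (the memory trace), ``x1_history`` holds the last ``capacity``
    of them, most recent first.
    """

    capacity: int
    m: float = 0.0
    n_seen: int = 0
    x1_history: tuple[float, ...] = ()


def empty_memory(capacity: int = 3) -> MemoryState:
    if capacity < 0:
        raise ValueError("capacity must be >= 0")
    return MemoryState(capacity=capacity)


def update_memory(mem: MemoryState, x1: float) -> MemoryState:
    """Fold one completed trial's first tone into the memory state."""
    if not math.isfinite(x1):
        raise ValueError("x1 must be finite")
    n = mem.n_seen + 1
    # incremental (Welford) form: exact under a constant input stream
    m = mem.m + (x1 - mem.m) / n if mem.n_seen else x1
    hist = (x1,) + mem.x1_history
    return replace(mem, m=m, n_seen=n, x1_history=hist[: mem.capacity])


def p_first_higher_full(
    weights: ContractionWeights, mem: MemoryState, x1: float, x2: float
) -> float:
    """History model with noise absorbed into the weight scale."""
    return float(ndtr(weights.drive(mem, x1, x2)))


def p_first_higher_memory_trace(
    weights: ContractionWeights,
    sigma: float,
    mem: MemoryState,
    x1: float,
    x2: float,
) -> float:
    """One-free-parameter model: fixed weights, fitted noise sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(ndtr(weights.drive(mem, x1, x2) / sigma))


def p_first_higher_naive(sigma: float, x1: float, x2: float) -> float:
    """History-free comparator: Phi((x1 - x2) / sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(ndtr((x1 - x2) / sigma))


def p_first_higher_response_bias(
    sigma: float, beta: float, x1: float, x2: float
) -> float:
    """Naive comparator plus a constant response bias beta."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(ndtr((x1 - x2) / sigma + beta))


@dataclass(frozen=True)
class ObserverParams:
    """A complete stochastic observer: model family plus its parameters.

    ``weights`` is required for FULL_LN and MEMORY_TRACE, ``sigma`` for
    every family except FULL_LN (whose noise lives in the weight scale),
    and ``beta`` is used by RESPONSE_BIAS only.
    """

    model_tag: ModelTag
    weights: Optional[ContractionWeights] = None
    sigma: Optional[float] = None
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.model_tag in (ModelTag.FULL_LN, ModelTag.MEMORY_TRACE):
            if self.weights is None:
                raise ValueError(f"{self.model_tag} requires weights")
        if self.model_tag is not ModelTag.FULL_LN:
            if self.sigma is None or self.sigma <= 0:
                raise ValueError(f"{self.model_tag} requires sigma > 0")

    @property
    def memory_capacity(self) -> int:
        return self.weights.k if self.weights is not None else 0

    def p_first_higher(self, mem: MemoryState, x1: float, x2: float) -> float:
        tag = self.model_tag
        if tag is ModelTag.FULL_LN:
            return p_first_higher_full(self.weights, mem, x1, x2)
        if tag is ModelTag.MEMORY_TRACE:
            return p_first_higher_memory_trace(self.weights, self.sigma, mem, x1, x2)
        if tag is ModelTag.NAIVE:
            return p_first_higher_naive(self.sigma, x1, x2)
        if tag is ModelTag.RESPONSE_BIAS:
            return p_first_higher_response_bias(self.sigma, self.beta, x1, x2)
        raise ValueError(f"unknown model {tag!r}")  # pragma: no cover


def sample_response(probability: float, rng: np.random.Generator) -> bool:
    """Bernoulli draw of a "first tone higher" response."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return bool(rng.random() < probability)
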