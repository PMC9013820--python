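"""Box-Muller normal random-variate generation.

The simulator's stochastic layer is deliberately explicit: a seedable
uniform source on the open interval (0, 1) and the Box-Muller transform

    x = sqrt(-2 ln U1) * sin(2 pi U2)

which maps two independent uniforms to one standard normal deviate.
Durations and counts throughout the package are drawn as ``mu + sigma * x``
from a :class:`NormalSpec`.  Each deviate consumes exactly two fresh
uniforms (the sine branch only); an optional paired mode also returns the
cosine-branch deviate for callers that want both at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalSpec",
    "UniformSource",
    "standard_normal",
    "standard_normal_pair",
    "sample_normal",
]

# Smallest nudge keeping uniforms strictly inside (0, 1): ln(0) diverges.
_EPS = np.finfo(float).tiny


@dataclass(frozen=True)
class NormalSpec:
    """Mean and standard deviation of a normally distributed duration.

    Parameters
    ----------
    mu : float
        Mean, in minutes for service times (the package convention).
    sigma : float
        Standard deviation, same units as ``mu``; must be >= 0.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma}")


class UniformSource:
    """Seedable stream of uniforms on the open interval (0, 1).

    Wraps a 64-bit PCG64 generator; raw draws on [0, 1) are nudged to the
    open interval so the Box-Muller logarithm never sees 0.  The number of
    uniforms handed out is tracked in :attr:`calls`, which lets tests verify
    the two-uniforms-per-deviate discipline.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._gen = np.random.Generator(np.random.PCG64(self.seed))
        self.calls = 0

    def next(self) -> float:
        """Return one uniform in (0, 1)."""
        self.calls += 1
        u = self._gen.random()
        return u if u > 0.0 else _EPS

    def next_batch(self, n: int) -> np.ndarray:
        """Return ``n`` uniforms in (0, 1), identical to ``n`` calls of :meth:`next`."""
        if n < 0:
            raise ValueError("n must be >= 0")
        self.calls += n
        u = self._gen.random(n)
        # PCG64 emits the same stream element-wise as scalar draws.
        return np.where(u > 0.0, u, _EPS)


def _check_uniform(u: float, name: str) -> None:
    if not (0.0 < u < 1.0):
        raise ValueError(f"{name} must lie in the open interval (0,1), got {u}")


def standard_normal(u1: float, u2: float) -> float:
    """Box-Muller transform (sine branch): one N(0,1) deviate from two uniforms."""
    _check_uniform(u1, "u1")
    _check_uniform(u2, "u2")
    return math.sqrt(-2.0 * math.log(u1)) * math.sin(2.0 * math.pi * u2)


def standard_normal_pair(u1: float, u2: float) -> tuple[float, float]:
    """Classic paired Box-Muller: (sine, cosine) deviates from one uniform pair."""
    _check_uniform(u1, "u1")
    _check_uniform(u2, "u2")
    r = math.sqrt(-2.0 * math.log(u1))
    return r * math.sin(2.0 * math.pi * u2), r * math.cos(2.0 * math.pi * u2)


def sample_normal(
    spec: NormalSpec,
    n: int,
    source: UniformSource,
    positive_only: bool = False,
) -> np.ndarray:
    """Draw ``n`` variates ``mu + sigma * x`` with Box-Muller ``x``.

    Each accepted deviate consumes exactly one fresh pair of uniforms.  With
    ``positive_only`` values <= 0 are rejected and redrawn (rejection, not
    clamping, so the shape of the distribution on the positive support is
    preserved); rejected draws consume additional uniform pairs.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    out = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        u = source.next_batch(2 * pending.size)
        u1, u2 = u[0::2], u[1::2]
        x = np.sqrt(-2.0 * np.log(u1)) * np.sin(2.0 * np.pi * u2)
        vals = spec.mu + spec.sigma * x
        out[pending] = vals
        if not positive_only:
            break
        pending = pending[vals <= 0.0]
        if pending.size and spec.mu <= 0 and spec.sigma == 0:
            raise ValueError("positive_only is unsatisfiable for a degenerate spec with mu <= 0")
    return out


def draw_normal(spec: NormalSpec, source: UniformSource, positive_only: bool = False) -> float:
    """Single variate convenience wrapper around :func:`sample_normal`."""
    return float(sample_normal(spec, 1, source, positive_only=positive_only)[0])
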