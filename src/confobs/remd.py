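"""Replica-exchange temperature ladders and Hamiltonian scaling factors.

A geometric ladder places n replica temperatures between T_min and T_max
with a constant ratio, T_i = T_min * (T_max/T_min)^(i/(n-1)); in
solute-tempering style Hamiltonian replica exchange each rung's
interactions are scaled by lambda_i = T_ref / T_i, so the reference rung
(lambda = 1) runs the unmodified potential and higher rungs feel an
effectively hotter surface. The scaling convention lambda = T_ref/T is
the standard solute-tempering choice; only the temperature list itself
is a directly checkable quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LadderSpec:
    """Ordered replica temperatures (K) and their scaling factors."""

    t_min: float
    t_max: float
    n_replicas: int
    temperatures: np.ndarray
    scaling_factors: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.size != self.n_replicas:
            raise ValueError("temperature count must equal n_replicas")
        if not (np.isclose(t[0], self.t_min) and np.isclose(t[-1], self.t_max)):
            raise ValueError("ladder endpoints must equal t_min and t_max")
        if self.t_max > self.t_min:
            if np.any(np.diff(t) <= 0):
                raise ValueError("temperatures must be strictly increasing")
            ratios = t[1:] / t[:-1]
            if np.ptp(ratios) > 1e-9:
                raise ValueError("ladder must have a constant ratio (geometric)")
        if not np.isclose(self.scaling_factors[0], 1.0):
            raise ValueError("reference rung must have scaling factor 1")

    def rounded_temperatures(self, decimals: int = 3) -> np.ndarray:
        """Interface representation: rounded to match printed tables."""
        return np.round(self.temperatures, decimals)


def geometric_ladder(t_min: float, t_max: float, n: int) -> LadderSpec:
    """Geometric-progression temperature ladder from t_min to t_max.

    T_i = t_min * (t_max/t_min)^(i/(n-1)), i = 0..n-1. Full precision is
    kept internally; round at the interface via
    :meth:`LadderSpec.rounded_temperatures`.
    """
    if t_min > t_max:
        raise ValueError("t_min must not exceed t_max")
    if n < 1 or (n < 2 and t_min != t_max):
        raise ValueError("need n >= 2 replicas (n = 1 only for a degenerate range)")
    if t_min == t_max:
        temps = np.full(n, float(t_min))
    else:
        i = np.arange(n)
        temps = t_min * (t_max / t_min) ** (i / (n - 1))
    ladder = LadderSpec(
        t_min=float(t_min), t_max=float(t_max), n_replicas=n,
        temperatures=temps, scaling_factors=t_min / temps,
    )
    return ladder


def scaling_factors(ladder: LadderSpec, t_ref: float | None = None) -> np.ndarray:
    """Solute-tempering scaling factors lambda_i = t_ref / T_i.

    Defaults t_ref to the ladder minimum, making the first rung the
    unscaled reference (lambda = 1); lambda is strictly decreasing along
    an increasing ladder and lambda_i * T_i = t_ref identically.
    """
    if t_ref is None:
        t_ref = ladder.t_min
    return t_ref / np.asarray(ladder.temperatures, dtype=float)


def aggregate_time_us(n_replicas: int, per_replica_ns: float) -> float:
    """Total simulated time over all replicas, in microseconds."""
    if n_replicas < 1 or per_replica_ns <= 0:
        raise ValueError("replica count and duration must be positive")
    return n_replicas * per_replica_ns / 1000.0
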