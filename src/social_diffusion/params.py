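"""Parameter containers for the inertia/trend-seeking coordination game.

Every agent weighs three payoff summands — social coordination (``b``),
inertia (``k``) and trend-seeking (``r``) — constrained to a convex
combination ``b + k + r = 1``, and revises its strategy through noisy
best response (logit learning) with rationality ``beta``.  A population
is a committed minority (frozen on the alternative strategy) plus regular
agents split into two behavioural classes, explorers and non-explorers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgentClassParams",
    "PopulationSpec",
    "PopulationState",
    "EXPLORER_PARAMS",
    "NONEXPLORER_PARAMS",
]

_CONVEX_TOL = 1e-9


@dataclass(frozen=True)
class AgentClassParams:
    """Payoff weights and rationality for one behavioural class.

    Parameters
    ----------
    b : float
        Coordination weight in [0, 1]: payoff share for matching the
        strategy played by others.
    k : float
        Inertia weight in [0, 1]: payoff bonus for repeating one's own
        current strategy (status-quo bias).
    r : float
        Trend-seeking weight in [0, 1]: payoff bonus proportional to the
        population trend term (sensitivity to dynamic norms).
    beta : float
        Rationality (inverse noise) of the logit choice rule; ``beta = 0``
        is fully random choice.  Must be finite and non-negative — a
        committed agent is represented by freezing its strategy, never by
        an infinite ``beta``.
    """

    b: float
    k: float
    r: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("b", "k", "r"):
            val = getattr(self, name)
            if not math.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val!r}")
        if abs(self.b + self.k + self.r - 1.0) > _CONVEX_TOL:
            raise ValueError(
                f"payoff weights must satisfy b + k + r = 1, got {self.b + self.k + self.r!r}"
            )
        if not math.isfinite(self.beta) or self.beta < 0:
            raise ValueError(f"beta must be finite and >= 0, got {self.beta!r}")


#: Calibrated explorer class: low inertia, strong trend-seeking.
EXPLORER_PARAMS = AgentClassParams(b=0.48, k=0.10, r=0.42, beta=7.8)

#: Calibrated non-explorer class: strong inertia, weak trend-seeking.
NONEXPLORER_PARAMS = AgentClassParams(b=0.42, k=0.42, r=0.16, beta=7.8)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PopulationSpec:
    """Composition of a well-mixed population.

    Agents are laid out in a fixed deterministic order:
    ``[committed | explorers | non-explorers]``.  The explorer count is
    the round-half-up of ``rho_e * (n - committed_count)``.
    """

    n: int
    committed_count: int
    rho_e: float
    explorer_params: AgentClassParams = EXPLORER_PARAMS
    nonexplorer_params: AgentClassParams = NONEXPLORER_PARAMS

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("population needs at least 2 agents")
        if not 0 <= self.committed_count < self.n:
            raise ValueError(
                f"committed_count must be in [0, n), got {self.committed_count}"
            )
        if not 0.0 <= self.rho_e <= 1.0:
            raise ValueError(f"rho_e must be in [0, 1], got {self.rho_e!r}")

    @property
    def regular_count(self) -> int:
        return self.n - self.committed_count

    @property
    def explorer_count(self) -> int:
        return _round_half_up(self.rho_e * self.regular_count)

    @property
    def nonexplorer_count(self) -> int:
        return self.regular_count - self.explorer_count

    @property
    def committed_mask(self) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        mask[: self.committed_count] = True
        return mask

    def class_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-agent (b, k, r, beta) arrays in the fixed agent order.

        Committed agents never evaluate payoffs; their slots carry the
        explorer values purely as placeholders.
        """
        b = np.empty(self.n)
        k = np.empty(self.n)
        r = np.empty(self.n)
        beta = np.empty(self.n)
        splits = [
            (slice(0, self.committed_count), self.explorer_params),
            (
                slice(self.committed_count, self.committed_count + self.explorer_count),
                self.explorer_params,
            ),
            (slice(self.committed_count + self.explorer_count, self.n), self.nonexplorer_params),
        ]
        for sl, p in splits:
            b[sl], k[sl], r[sl], beta[sl] = p.b, p.k, p.r, p.beta
        return b, k, r, beta


@dataclass
class PopulationState:
    """Strategy configuration at round ``t``.

    ``x_curr`` and ``x_prev`` are binary vectors (0 = status quo,
    1 = alternative); the trend term reads both.  Committed agents are
    pinned at 1 by ``committed_mask``.
    """

    t: int
    x_curr: np.ndarray
    x_prev: np.ndarray
    committed_mask: np.ndarray

    def __post_init__(self) -> None:
        self.x_curr = np.asarray(self.x_curr, dtype=np.int8)
        self.x_prev = np.asarray(self.x_prev, dtype=np.int8)
        self.committed_mask = np.asarray(self.committed_mask, dtype=bool)
        n = self.x_curr.shape[0]
        if n < 2:
            raise ValueError("population needs at least 2 agents")
        if self.x_prev.shape != (n,) or self.committed_mask.shape != (n,):
            raise ValueError("state vectors must share one length")
        for name, vec in (("x_curr", self.x_curr), ("x_prev", self.x_prev)):
            if not np.isin(vec, (0, 1)).all():
                raise ValueError(f"{name} entries must be binary")
        if not (self.x_curr[self.committed_mask] == 1).all():
            raise ValueError("committed agents must play the alternative (1)")

    @property
    def n(self) -> int:
        return self.x_curr.shape[0]

    @property
    def adopter_fraction(self) -> float:
        return float(self.x_curr.mean())
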