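"""Decision kernel: trend term, payoffs, logit choice and one synchronous step.

The per-round update is: every regular (non-committed) agent computes the
payoffs of the two strategies from the current configuration and the
previous one, then redraws its strategy from the log-linear (logit)
distribution; committed agents stay on the alternative.  Updates are
synchronous with all-to-all visibility.
"""

from __future__ import annotations

import numpy as np

from .params import AgentClassParams, PopulationSpec, PopulationState

__all__ = [
    "trend_term",
    "payoffs",
    "choice_probability",
    "adoption_probabilities",
    "synchronous_step",
]


def _check_binary(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if not np.isin(x, (0, 1)).all():
        raise ValueError(f"{name} entries must be binary")
    return x.astype(np.int64)


def trend_term(v: int, x_curr: np.ndarray, x_prev: np.ndarray) -> float:
    """Population trend seen by agent ``v``.

    Returns ``0.5 * (1 + (1/(n-1)) * sum_{w != v} (x_w(t) - x_w(t-1)))``,
    a value in [0, 1]: above one half iff the fraction of adopters among
    the other agents increased in the previous step; exactly one half when
    nothing changed.
    """
    x_curr = _check_binary(x_curr, "x_curr")
    x_prev = _check_binary(x_prev, "x_prev")
    n = x_curr.shape[0]
    if n < 2 or x_prev.shape[0] != n:
        raise ValueError("need two equal-length vectors with n >= 2")
    if not 0 <= v < n:
        raise ValueError(f"agent index {v} out of range")
    diff = x_curr - x_prev
    others = diff.sum() - diff[v]
    return 0.5 * (1.0 + others / (n - 1))


def payoffs(v: int, state: PopulationState, params: AgentClassParams) -> tuple[float, float]:
    """Payoff pair ``(pi0, pi1)`` of agent ``v`` in ``state``.

    ``pi1 = b/(n-1) * sum_{w != v} x_w + k * x_v + r * xhat_v`` and
    ``pi0`` is its mirror image; since ``b + k + r = 1`` the pair always
    sums to one.  Committed agents never evaluate payoffs.
    """
    if state.committed_mask[v]:
        raise ValueError("committed agents do not evaluate payoffs")
    n = state.n
    others_adopting = int(state.x_curr.sum()) - int(state.x_curr[v])
    xhat = trend_term(v, state.x_curr, state.x_prev)
    pi1 = (
        params.b * others_adopting / (n - 1)
        + params.k * float(state.x_curr[v])
        + params.r * xhat
    )
    return 1.0 - pi1, pi1


def choice_probability(pi0: float, pi1: float, beta: float):
    """Probability of choosing the alternative under logit learning.

    Evaluates ``exp(beta*pi1) / (exp(beta*pi0) + exp(beta*pi1))`` in the
    numerically stable logistic form ``1 / (1 + exp(-beta*(pi1 - pi0)))``.
    Accepts scalars or arrays; strictly inside (0, 1) for finite beta.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.isfinite(beta).all() or (beta < 0).any():
        raise ValueError("beta must be finite and >= 0")
    diff = np.asarray(pi1, dtype=float) - np.asarray(pi0, dtype=float)
    out = 1.0 / (1.0 + np.exp(-beta * diff))
    return out if out.ndim else float(out)


def adoption_probabilities(state: PopulationState, spec: PopulationSpec) -> np.ndarray:
    """Vector of per-agent probabilities of playing 1 next round.

    Committed slots are reported as exactly 1.  This is the vectorised
    heart of :func:`synchronous_step`, exposed so closed-form per-step
    probabilities can be inspected directly.
    """
    x = state.x_curr.astype(np.int64)
    d = x - state.x_prev.astype(np.int64)
    n = state.n
    b, k, r, beta = spec.class_arrays()
    others_adopting = x.sum() - x
    xhat = 0.5 * (1.0 + (d.sum() - d) / (n - 1))
    pi1 = b * others_adopting / (n - 1) + k * x + r * xhat
    # pi0 = 1 - pi1 by the convex-combination identity, so pi1 - pi0 = 2*pi1 - 1
    p1 = 1.0 / (1.0 + np.exp(-beta * (2.0 * pi1 - 1.0)))
    p1[state.committed_mask] = 1.0
    return p1


def synchronous_step(
    state: PopulationState,
    spec: PopulationSpec,
    rng: np.random.Generator,
    uniforms: np.ndarray | None = None,
) -> PopulationState:
    """Advance the population one round.

    One uniform variate is consumed per regular agent, in fixed agent
    order, so trajectories are bit-reproducible per seed.  ``uniforms``
    may supply those variates explicitly (length = number of regular
    agents), which is how the scalar-loop oracle and the vectorised path
    are compared.
    """
    regular = ~state.committed_mask
    n_regular = int(regular.sum())
    if uniforms is None:
        uniforms = rng.random(n_regular)
    else:
        uniforms = np.asarray(uniforms, dtype=float)
        if uniforms.shape != (n_regular,):
            raise ValueError("need one uniform variate per regular agent")
    p1 = adoption_probabilities(state, spec)
    x_next = state.x_curr.copy()
    x_next[regular] = (uniforms < p1[regular]).astype(np.int8)
    return PopulationState(
        t=state.t + 1,
        x_curr=x_next,
        x_prev=state.x_curr,
        committed_mask=state.committed_mask,
    )
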