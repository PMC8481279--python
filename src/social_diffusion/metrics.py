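"""Diffusion observables: diffusion time, take-off time, transition time
and per-agent switching rates.

All times are 0-based round indices; ``t = 0`` is the initial state.  The
diffusion time ``T*`` is the first round at which the adopter fraction of
the whole population (committed minority included) reaches the full-
diffusion threshold (0.99 by default).  The take-off time ``T̄`` is the
*last* round at or before ``T*`` at which the fraction is still at or
below the take-off threshold (0.4 by default) — after ``T̄`` the fraction
never dips back below the threshold, which makes the pair ``(T̄, ΔT)``
with ``ΔT = T* − T̄`` a delay/explosiveness signature of the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiffusionSummary",
    "diffusion_time",
    "takeoff_time",
    "transition_time",
    "switching_rates",
    "empirical_switching_rate",
    "summarize_trajectory",
]


@dataclass(frozen=True)
class DiffusionSummary:
    """Observables of one run.

    ``t_star``/``t_bar`` are reported at the step cap for censored runs
    (``censored=True``); ``delta_t`` is then undefined and stored as NaN.
    ``y`` holds per-regular-agent switching rates.  ``takeoff_at_start``
    flags the degenerate case of an initial fraction already above the
    take-off threshold (the supremum set is empty and ``t_bar = 0``).
    """

    t_star: int
    t_bar: int
    delta_t: float
    censored: bool
    y: np.ndarray
    takeoff_at_start: bool = False


def diffusion_time(fractions: np.ndarray, threshold: float = 0.99) -> int | None:
    """First round at which the adopter fraction reaches ``threshold``.

    ``fractions[t]`` is the population-wide adopter fraction at round t.
    Returns ``None`` if the threshold is never reached (censored run).
    """
    fractions = np.asarray(fractions, dtype=float)
    hits = np.nonzero(fractions >= threshold)[0]
    return int(hits[0]) if hits.size else None


def takeoff_time(
    fractions: np.ndarray,
    t_star: int | None,
    threshold: float = 0.4,
) -> tuple[int, bool]:
    """Last round ``t <= T*`` with adopter fraction at or below ``threshold``.

    For censored runs pass ``t_star=None``: the supremum is then taken over
    the whole recorded window.  Returns ``(t_bar, empty_supremum)`` where
    the flag marks a fraction series that starts above the threshold.
    """
    fractions = np.asarray(fractions, dtype=float)
    end = len(fractions) - 1 if t_star is None else t_star
    window = fractions[: end + 1]
    below = np.nonzero(window <= threshold)[0]
    if below.size == 0:
        return 0, True
    return int(below[-1]), False


def transition_time(t_star: int, t_bar: int) -> int:
    """Transition (explosiveness) time ``ΔT = T* − T̄`` of an uncensored run."""
    if t_star < t_bar:
        raise ValueError("t_star must be >= t_bar")
    return t_star - t_bar


def switching_rates(
    switch_counts: np.ndarray,
    final_x: np.ndarray,
    t_star: int,
    regular_mask: np.ndarray,
) -> np.ndarray:
    """Per-regular-agent switching rates of an uncensored run.

    ``y_v = (#switches_v − 1) / T*`` with the final revision into the
    all-alternative configuration discounted.  The discount applies to
    agents that finished on the alternative; an agent still on the status
    quo at ``T*`` (possible because full diffusion is declared at 99%)
    made no final switch, so its raw count is used.
    """
    if t_star < 1:
        raise ValueError("switching rates undefined for T* = 0")
    counts = np.asarray(switch_counts, dtype=float)[regular_mask]
    ended_on_alt = np.asarray(final_x)[regular_mask] == 1
    discounted = counts - ended_on_alt.astype(float)
    return np.maximum(discounted, 0.0) / t_star


def empirical_switching_rate(path: np.ndarray, horizon: int = 24) -> float:
    """Switching rate of one participant in a no-diffusion trial.

    ``y_v = (1/horizon) * sum_t |x_v(t) − x_v(t−1)|`` over consecutive
    *observed* rounds — no final-switch discount, because no final switch
    into full consensus occurred.  Missing rounds (NaN) break the chain
    of comparisons: a switch cannot be attributed to an unobserved round.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 1 or path.shape[0] == 0:
        raise ValueError("path must be a non-empty 1-D array")
    observed = path[~np.isnan(path)]
    if not np.isin(observed, (0.0, 1.0)).all():
        raise ValueError("path entries must be 0, 1 or NaN")
    if path.shape[0] != horizon:
        raise ValueError(
            f"path length {path.shape[0]} does not match the declared "
            f"{horizon}-round horizon (missed rounds must be NaN entries)"
        )
    switches = 0
    prev = None
    for val in path:
        if np.isnan(val):
            prev = None
            continue
        if prev is not None and val != prev:
            switches += 1
        prev = val
    return switches / horizon


def summarize_trajectory(traj, takeoff_threshold: float | None = None) -> DiffusionSummary:
    """Full :class:`DiffusionSummary` of a simulated trajectory.

    ``traj`` is a :class:`~social_diffusion.simulate.Trajectory`.  The
    take-off threshold defaults to the one in the trajectory's config and
    may be overridden (robustness checks at 0.35 / 0.45).
    """
    cfg = traj.config
    thr = cfg.takeoff_threshold if takeoff_threshold is None else takeoff_threshold
    t_star = diffusion_time(traj.fractions, cfg.full_diffusion_threshold)
    censored = t_star is None
    t_bar, empty = takeoff_time(traj.fractions, t_star, thr)
    regular = ~traj.spec.committed_mask
    if censored:
        cap = len(traj.fractions) - 1
        return DiffusionSummary(
            t_star=cap,
            t_bar=t_bar,
            delta_t=float("nan"),
            censored=True,
            y=np.full(regular.sum(), np.nan),
            takeoff_at_start=empty,
        )
    y = switching_rates(traj.switch_counts, traj.final_x, max(t_star, 1), regular) \
        if t_star >= 1 else np.full(regular.sum(), np.nan)
    return DiffusionSummary(
        t_star=t_star,
        t_bar=t_bar,
        delta_t=float(transition_time(t_star, t_bar)),
        censored=False,
        y=y,
        takeoff_at_start=empty,
    )
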