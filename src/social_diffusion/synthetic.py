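"""Synthetic multi-round group trials emulating the 12-seat experiment.

Each generated trial has 8-10 simulated human participants plus enough
committed-minority bots to fill 12 seats.  Stage I forms a status quo:
participants start from uniformly random choices and update through the
inertia/trend-seeking logit model, while all but one committed bot chase
the previous-round participant majority and one contrarian bot opposes
it; the strategy on which participants and the majority bots converge is
relabelled 0.  Stage II starts the following round: every committed bot
pushes the alternative (1) until full visible consensus or the 24-round
cap.  Irregular behaviours — seat dropouts, per-round missed responses,
totally stubborn participants — are injected at configurable rates.

Stage I human dynamics are a modelling stand-in: their only contract is
structural plausibility of the records, not fidelity to human play.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import choice_probability
from .params import AgentClassParams, EXPLORER_PARAMS, NONEXPLORER_PARAMS
from .trials import (
    GROUP_SIZE,
    MAX_ROUNDS,
    ROLE_COMMITTED,
    ROLE_DROPOUT,
    ROLE_PARTICIPANT,
    TrialRecord,
)

__all__ = ["TrialGeneratorConfig", "generate_trial", "generate_dataset"]


@dataclass(frozen=True)
class TrialGeneratorConfig:
    """Study conditions for one synthetic trial.

    ``n_participants`` of 8, 9 or 10 implies 4, 3 or 2 committed bots
    (12 seats total); ``None`` draws the group size uniformly per trial.
    Default irregularity rates mirror the experiment's incidence: 32 of
    180 recruits dropped out (``dropout_rate=0.18``), missed responses
    were rare (``missed_round_rate=0.01`` per participant-round), and
    totally stubborn players were exceptional (``stubborn_rate=0.01``).
    The default explorer share among participants is 0.62, the share
    observed in the cleaned experimental data (74 of 119).
    """

    n_participants: int | None = 9
    explorer_fraction: float = 0.62
    explorer_params: AgentClassParams = EXPLORER_PARAMS
    nonexplorer_params: AgentClassParams = NONEXPLORER_PARAMS
    dropout_rate: float = 0.18
    missed_round_rate: float = 0.01
    stubborn_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_participants is not None and self.n_participants not in (8, 9, 10):
            raise ValueError("n_participants must be 8, 9, 10 or None")
        for name in ("explorer_fraction", "dropout_rate", "missed_round_rate", "stubborn_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _majority_of_others(row: np.ndarray, seat: int) -> float:
    others = np.delete(row, seat)
    return 1.0 if others.mean() > 0.5 else 0.0


def _logit_choice(seat: int, x_curr: np.ndarray, x_prev: np.ndarray,
                  params: AgentClassParams, u: float) -> float:
    n = x_curr.shape[0]
    others = x_curr.sum() - x_curr[seat]
    d = (x_curr - x_prev)
    xhat = 0.5 * (1.0 + (d.sum() - d[seat]) / (n - 1))
    pi1 = params.b * others / (n - 1) + params.k * x_curr[seat] + params.r * xhat
    p1 = choice_probability(1.0 - pi1, pi1, params.beta)
    return 1.0 if u < p1 else 0.0


def generate_trial(config: TrialGeneratorConfig, seed) -> TrialRecord:
    """Generate one trial; ``seed`` may be an int or a SeedSequence.

    If Stage I fails to converge within the 24-round cap (the experiment
    saw status-quo formation within 1-3 rounds in 18 of 20 trials), the
    record is emitted with ``stage2_start=None``.
    """
    rng = np.random.default_rng(seed)
    n_part = config.n_participants or int(rng.choice((8, 9, 10)))
    n_committed = GROUP_SIZE - n_part
    human_seats = list(range(n_part))
    committed_seats = list(range(n_part, GROUP_SIZE))

    roles = []
    stubborn: set[int] = set()
    params: dict[int, AgentClassParams] = {}
    for s in human_seats:
        if rng.random() < config.dropout_rate:
            roles.append(ROLE_DROPOUT)
            continue
        roles.append(ROLE_PARTICIPANT)
        if rng.random() < config.stubborn_rate:
            stubborn.add(s)
        is_explorer = rng.random() < config.explorer_fraction
        params[s] = config.explorer_params if is_explorer else config.nonexplorer_params
    roles.extend([ROLE_COMMITTED] * n_committed)
    contrarian = committed_seats[0]

    recorded = np.full((MAX_ROUNDS, GROUP_SIZE), np.nan)
    visible = np.full((MAX_ROUNDS, GROUP_SIZE), np.nan)

    # Round 1: free choices everywhere (no information on screen yet).
    for s in range(GROUP_SIZE):
        visible[0, s] = float(rng.integers(2))
        if roles[s] == ROLE_PARTICIPANT:
            recorded[0, s] = visible[0, s]
        elif roles[s] == ROLE_COMMITTED:
            recorded[0, s] = visible[0, s]
        else:  # dropout bot: its plays are recorded bot moves
            recorded[0, s] = visible[0, s]

    stage2_start: int | None = None
    consensus_round: int | None = None
    last_round = MAX_ROUNDS

    for t in range(1, MAX_ROUNDS):  # rounds 2..24, row index t
        x_curr = visible[t - 1]
        x_prev = visible[t - 2] if t >= 2 else x_curr
        in_stage2 = stage2_start is not None

        for s in committed_seats:
            if in_stage2:
                visible[t, s] = 1.0  # matrices are already relabelled: alternative = 1
            else:
                part_majority = 1.0 if visible[t - 1, human_seats].mean() > 0.5 else 0.0
                visible[t, s] = (1.0 - part_majority) if s == contrarian else part_majority
            recorded[t, s] = visible[t, s]
        for s in human_seats:
            if roles[s] == ROLE_DROPOUT:
                visible[t, s] = _majority_of_others(visible[t - 1], s)
                recorded[t, s] = visible[t, s]
            elif s in stubborn:
                # stubborn players never move from their first choice
                visible[t, s] = visible[0, s]
                recorded[t, s] = visible[t, s]
            elif rng.random() < config.missed_round_rate:
                visible[t, s] = _majority_of_others(visible[t - 1], s)
                # recorded stays NaN: the participant made no decision
            else:
                choice = _logit_choice(s, x_curr, x_prev, params[s], rng.random())
                visible[t, s] = choice
                recorded[t, s] = choice

        if not in_stage2:
            # Stage I ends when all humans and all but one committed bot coincide.
            human_vals = visible[t, human_seats]
            committed_vals = visible[t, committed_seats]
            for s_val in (0.0, 1.0):
                if (human_vals == s_val).all() and (committed_vals == s_val).sum() == n_committed - 1:
                    stage2_start = t + 2  # next round, 1-based
                    if s_val == 1.0:
                        # relabel so the status quo that just formed is 0
                        recorded[: t + 1] = 1.0 - recorded[: t + 1]
                        visible[: t + 1] = 1.0 - visible[: t + 1]
                    break
        else:
            if (visible[t] == 1.0).all():
                consensus_round = t + 1
                last_round = t + 1
                break

    if stage2_start is None or stage2_start > MAX_ROUNDS:
        return TrialRecord(
            trial_id="synthetic",
            strategies=recorded[:last_round],
            roles=roles,
            stage2_start=None,
            consensus_round=None,
        )

    return TrialRecord(
        trial_id="synthetic",
        strategies=recorded[:last_round],
        roles=roles,
        stage2_start=stage2_start,
        consensus_round=consensus_round,
    )


def generate_dataset(
    n_trials: int,
    config: TrialGeneratorConfig,
    seed: int | None = None,
) -> list[TrialRecord]:
    """Independent trials from deterministically derived child seeds."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_trials)
    trials = []
    for i, child in enumerate(children):
        trial = generate_trial(config, child)
        trial.trial_id = f"synthetic-{i:03d}"
        trials.append(trial)
    return trials
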