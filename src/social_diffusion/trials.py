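"""Multi-round trial records: cleaning, switch counting and the
explorer/non-explorer classification.

A trial is one 12-seat group playing up to 24 rounds: 8-10 human
recruits plus 2-4 committed-minority bots.  Stage I establishes a status
quo (strategy 0); from ``stage2_start`` the committed bots push the
alternative (strategy 1).  Recruits may behave irregularly — drop out
before the game (a majority-following bot takes the seat), miss more
than 20% of rounds, or be totally stubborn — and are then excluded from
parameter-bearing statistics.  Regular participants are classified as
explorers or non-explorers from a behavioural discriminant built on how
often they switched and whether switches joined the minority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "ParticipantStats",
    "ClassStats",
    "visible_strategies",
    "identify_irregulars",
    "filter_trials",
    "empirical_t_star",
    "count_switch_events",
    "behavioural_discriminant",
    "classify",
    "class_summary",
    "process_trials",
]

ROLE_PARTICIPANT = "participant"
ROLE_COMMITTED = "committed_bot"
ROLE_DROPOUT = "dropout_bot"
_ROLES = {ROLE_PARTICIPANT, ROLE_COMMITTED, ROLE_DROPOUT}

MAX_ROUNDS = 24
GROUP_SIZE = 12
MISSED_ROUNDS_THRESHOLD = 0.20
IRREGULAR_TRIAL_THRESHOLD = 1 / 3


@dataclass(eq=False)
class TrialRecord:
    """One group's round-by-seat strategy matrix.

    ``strategies`` has shape (rounds, seats) with entries 0, 1 or NaN
    (missed round); rounds are 1-based externally, row ``t-1`` holds
    round ``t``.  ``stage2_start`` is the first round in which the
    committed bots play the alternative; ``consensus_round`` is the round
    at which all 12 visible strategies coincide (game over), or None.
    """

    trial_id: str
    strategies: np.ndarray
    roles: list[str]
    stage2_start: int | None
    consensus_round: int | None = None

    def __post_init__(self) -> None:
        self.strategies = np.asarray(self.strategies, dtype=float)
        if self.strategies.ndim != 2:
            raise ValueError("strategies must be a rounds x seats matrix")
        n_rounds, n_seats = self.strategies.shape
        if n_rounds < 1 or n_rounds > MAX_ROUNDS:
            raise ValueError(f"rounds must be in [1, {MAX_ROUNDS}], got {n_rounds}")
        if len(self.roles) != n_seats:
            raise ValueError("one role per seat required")
        if any(r not in _ROLES for r in self.roles):
            raise ValueError(f"roles must be in {_ROLES}")
        vals = self.strategies[~np.isnan(self.strategies)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("strategy entries must be 0, 1 or NaN")
        if self.stage2_start is not None:
            committed = [i for i, r in enumerate(self.roles) if r == ROLE_COMMITTED]
            stage2 = self.strategies[self.stage2_start - 1 :, committed]
            if not (stage2[~np.isnan(stage2)] == 1).all():
                raise ValueError("committed bots must play 1 from stage2_start on")

    @property
    def n_rounds(self) -> int:
        return self.strategies.shape[0]

    @property
    def n_seats(self) -> int:
        return self.strategies.shape[1]

    @property
    def recruit_seats(self) -> list[int]:
        """Seats occupied by human recruits (dropout-bot seats included)."""
        return [i for i, r in enumerate(self.roles) if r != ROLE_COMMITTED]


def visible_strategies(trial: TrialRecord) -> np.ndarray:
    """Group-visible strategy matrix with missed rounds filled in.

    A participant who misses a round is replaced, for the group's
    information, by a bot playing the majority of the *other* players in
    the previous round (status quo on a first-round miss; ties go to the
    status quo).  This mirrors what the group actually observed.
    """
    vis = trial.strategies.copy()
    n_rounds, n_seats = vis.shape
    for t in range(n_rounds):
        for s in range(n_seats):
            if np.isnan(vis[t, s]):
                if t == 0:
                    vis[t, s] = 0.0
                else:
                    others = np.delete(vis[t - 1], s)
                    others = others[~np.isnan(others)]
                    vis[t, s] = 1.0 if others.size and others.mean() > 0.5 else 0.0
    return vis


def identify_irregulars(trial: TrialRecord) -> dict[int, str]:
    """Irregularity label per recruit seat.

    ``dropout`` — never played (the seat role is a dropout bot or every
    round is missing); ``missed_rounds`` — missing in more than 20% of
    the trial's rounds; ``totally_stubborn`` — plays the status quo in
    every round *and* keeps it for two consecutive rounds while all other
    players are on the alternative; ``none`` — regular participant.
    """
    vis = visible_strategies(trial)
    labels: dict[int, str] = {}
    for seat in trial.recruit_seats:
        path = trial.strategies[:, seat]
        missing = np.isnan(path)
        if trial.roles[seat] == ROLE_DROPOUT or missing.all():
            labels[seat] = "dropout"
            continue
        if missing.mean() > MISSED_ROUNDS_THRESHOLD:
            labels[seat] = "missed_rounds"
            continue
        always_status_quo = (path[~missing] == 0).all()
        if always_status_quo:
            others = np.delete(vis, seat, axis=1)
            rest_all_alt = (others == 1).all(axis=1) & (~missing) & (path == 0)
            consecutive = bool((rest_all_alt[:-1] & rest_all_alt[1:]).any())
            if consecutive:
                labels[seat] = "totally_stubborn"
                continue
        labels[seat] = "none"
    return labels


def filter_trials(
    trials: list[TrialRecord],
    labels: list[dict[int, str]] | None = None,
) -> tuple[list[TrialRecord], list[bool]]:
    """Apply the trial-exclusion rule.

    A trial is removed iff it has at least one participant who missed
    rounds *and* more than a third of its recruits behaved irregularly.
    Returns the retained trials and a per-trial ``retained`` mask.
    """
    if labels is None:
        labels = [identify_irregulars(t) for t in trials]
    retained, mask = [], []
    for trial, lab in zip(trials, labels):
        n_recruits = len(trial.recruit_seats)
        n_irregular = sum(1 for v in lab.values() if v != "none")
        has_missed = any(v == "missed_rounds" for v in lab.values())
        remove = has_missed and (n_irregular / n_recruits > IRREGULAR_TRIAL_THRESHOLD)
        mask.append(not remove)
        if not remove:
            retained.append(trial)
    return retained, mask


def empirical_t_star(trial: TrialRecord, labels: dict[int, str]) -> tuple[int, bool]:
    """Consensus round of the regular participants, and whether reached.

    ``T*`` is the first round at which every regular participant plays
    the alternative (irregular seats may lag behind or be hardcoded);
    24 when no such round exists.  Returns ``(t_star, diffused)``.
    """
    regular = [s for s, v in labels.items() if v == "none"]
    if not regular:
        return MAX_ROUNDS, False
    sub = trial.strategies[:, regular]
    all_alt = np.nan_to_num(sub, nan=0.0).min(axis=1) == 1
    if trial.stage2_start is not None:
        all_alt[: trial.stage2_start - 1] = False  # the push starts in Stage II
    hits = np.nonzero(all_alt)[0]
    if hits.size:
        return int(hits[0]) + 1, True
    return MAX_ROUNDS, False


def count_switch_events(
    trial: TrialRecord,
    seat: int,
    t_star: int,
    diffused: bool,
    info: str = "previous",
) -> tuple[int, int, int, int]:
    """Count one participant's switches and classify each one.

    A switch at round ``t`` is classified against the strategies of the
    other players in the participant's information set — by default the
    *previous* round (what was on screen when the choice was made;
    ``info="current"`` uses the same round instead).  A switch to a
    strategy held by a strict minority of the other players increments
    ``min_count``, a strict majority increments ``maj_count``, an exact
    tie neither.  Comparisons skip missing rounds.  ``sw`` is the raw
    switch count less one when the group reached full consensus on the
    alternative (the final revision into consensus is discounted).

    Returns ``(sw, min_count, maj_count, tie_count)``.
    """
    if info not in ("previous", "current"):
        raise ValueError("info must be 'previous' or 'current'")
    vis = visible_strategies(trial)
    path = trial.strategies[:, seat]
    end = min(t_star, trial.n_rounds)
    raw = min_count = maj_count = tie_count = 0
    prev_val, prev_t = None, None
    for t in range(end):
        val = path[t]
        if np.isnan(val):
            prev_val, prev_t = None, None
            continue
        if prev_val is not None and val != prev_val:
            raw += 1
            ref_t = prev_t if info == "previous" else t
            others = np.delete(vis[ref_t], seat)
            share = (others == val).mean()
            if share < 0.5:
                min_count += 1
            elif share > 0.5:
                maj_count += 1
            else:
                tie_count += 1
        prev_val, prev_t = val, t
    sw = max(raw - 1, 0) if diffused else raw
    return sw, min_count, maj_count, tie_count


def behavioural_discriminant(sw: int, min_count: int, maj_count: int, t_star: int) -> float:
    """``Δ_v = sw/T* + min_v − maj_v/2`` — positive values point to
    explorer-like behaviour (frequent and minority-joining switches)."""
    if t_star < 1:
        raise ValueError("T* must be >= 1")
    return sw / t_star + min_count - 0.5 * maj_count


def classify(min_count: int, delta: float) -> str:
    """Explorer iff the participant ever joined a minority and Δ > 0."""
    if min_count == 0 or delta <= 0:
        return "non-explorer"
    return "explorer"


@dataclass(frozen=True)
class ParticipantStats:
    trial_id: str
    seat: int
    irregular: str
    sw: int | None = None
    min_count: int | None = None
    maj_count: int | None = None
    tie_count: int | None = None
    t_star: int | None = None
    delta: float | None = None
    label: str | None = None
    y: float | None = None


@dataclass(frozen=True)
class ClassStats:
    """Mean and sample standard deviation of switching rates per class."""

    mu_e: float
    sigma_e: float
    mu_n: float
    sigma_n: float
    n_e: int
    n_n: int

    @property
    def defined(self) -> bool:
        return self.n_e >= 2 and self.n_n >= 2


def class_summary(stats: list[ParticipantStats]) -> ClassStats:
    y_e = [s.y for s in stats if s.label == "explorer"]
    y_n = [s.y for s in stats if s.label == "non-explorer"]

    def _mu_sigma(ys: list[float]) -> tuple[float, float]:
        if not ys:
            return float("nan"), float("nan")
        mu = float(np.mean(ys))
        sigma = float(np.std(ys, ddof=1)) if len(ys) >= 2 else float("nan")
        return mu, sigma

    mu_e, sigma_e = _mu_sigma(y_e)
    mu_n, sigma_n = _mu_sigma(y_n)
    return ClassStats(mu_e, sigma_e, mu_n, sigma_n, len(y_e), len(y_n))


def process_trial(
    trial: TrialRecord,
    labels: dict[int, str] | None = None,
    info: str = "previous",
) -> list[ParticipantStats]:
    """Per-recruit statistics for one trial (regular seats classified)."""
    if labels is None:
        labels = identify_irregulars(trial)
    t_star, diffused = empirical_t_star(trial, labels)
    out = []
    for seat in trial.recruit_seats:
        irr = labels[seat]
        if irr != "none":
            out.append(ParticipantStats(trial.trial_id, seat, irr))
            continue
        sw, mn, mj, tie = count_switch_events(trial, seat, t_star, diffused, info)
        delta = behavioural_discriminant(sw, mn, mj, t_star)
        out.append(
            ParticipantStats(
                trial_id=trial.trial_id,
                seat=seat,
                irregular="none",
                sw=sw,
                min_count=mn,
                maj_count=mj,
                tie_count=tie,
                t_star=t_star,
                delta=delta,
                label=classify(mn, delta),
                y=sw / t_star,
            )
        )
    return out


def process_trials(
    trials: list[TrialRecord],
    apply_filter: bool = True,
    info: str = "previous",
) -> tuple[pd.DataFrame, ClassStats]:
    """Clean, classify and summarise a whole dataset.

    Returns a tidy per-recruit DataFrame (retained trials only when
    ``apply_filter``) and the class-level switching-rate statistics used
    by the calibration cost.
    """
    labels = [identify_irregulars(t) for t in trials]
    if apply_filter:
        kept, mask = filter_trials(trials, labels)
        kept_labels = [l for l, m in zip(labels, mask) if m]
    else:
        kept, kept_labels = trials, labels
    stats: list[ParticipantStats] = []
    for trial, lab in zip(kept, kept_labels):
        stats.extend(process_trial(trial, lab, info))
    frame = pd.DataFrame([s.__dict__ for s in stats])
    return frame, class_summary(stats)
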