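"""Trial-processing tests: irregular-behaviour labelling, the trial
exclusion rule, switch-event counting and the explorer classification."""

import numpy as np
import pytest

from social_diffusion import (
    TrialRecord,
    behavioural_discriminant,
    class_summary,
    classify,
    count_switch_events,
    filter_trials,
    identify_irregulars,
    process_trials,
)
from social_diffusion.trials import (
    ParticipantStats,
    ROLE_COMMITTED,
    ROLE_DROPOUT,
    ROLE_PARTICIPANT,
    empirical_t_star,
    process_trial,
)


def make_trial(strategies, roles, stage2_start=2, consensus_round=None, trial_id="t"):
    return TrialRecord(
        trial_id=trial_id,
        strategies=np.asarray(strategies, dtype=float),
        roles=roles,
        stage2_start=stage2_start,
        consensus_round=consensus_round,
    )


def full_group_trial(participant_paths, n_committed=3, stage2_start=2):
    """Build a 12-seat trial: participant paths + committed bots that play
    0 in round 1 (Stage I) and 1 afterwards."""
    paths = np.asarray(participant_paths, dtype=float)
    rounds = paths.shape[0]
    bots = np.ones((rounds, n_committed))
    bots[: stage2_start - 1] = 0.0
    strategies = np.hstack([paths, bots])
    roles = [ROLE_PARTICIPANT] * paths.shape[1] + [ROLE_COMMITTED] * n_committed
    return make_trial(strategies, roles, stage2_start=stage2_start)


class TestIdentifyIrregulars:
    def test_totally_stubborn_detection(self):
        # 24 rounds, 11 seats on the alternative from round 3, one hold-out
        rounds = 24
        paths = np.ones((rounds, 9))
        paths[0] = 0.0  # Stage I round on status quo
        paths[:, 0] = 0.0  # the stubborn participant never moves
        trial = full_group_trial(paths)
        labels = identify_irregulars(trial)
        assert labels[0] == "totally_stubborn"
        assert all(v == "none" for s, v in labels.items() if s != 0)

    def test_all_zero_without_group_consensus_is_regular(self):
        # playing the status quo throughout is not stubborn unless everyone
        # else was on the alternative for two consecutive rounds
        rounds = 24
        paths = np.zeros((rounds, 9))
        paths[3:, 1] = 1.0  # only one other participant adopts
        trial = full_group_trial(paths)
        assert identify_irregulars(trial)[0] == "none"

    def test_missed_rounds_threshold(self):
        rounds = 24
        base = np.zeros((rounds, 9))
        base[:5, 0] = np.nan  # 5/24 = 20.8% > 20%
        base[:4, 1] = np.nan  # 4/24 = 16.7% <= 20%
        trial = full_group_trial(base)
        labels = identify_irregulars(trial)
        assert labels[0] == "missed_rounds"
        assert labels[1] == "none"

    def test_dropout_by_role_and_by_absence(self):
        rounds = 6
        paths = np.zeros((rounds, 9))
        paths[:, 2] = np.nan
        trial = full_group_trial(paths)
        trial.roles[1] = ROLE_DROPOUT
        labels = identify_irregulars(trial)
        assert labels[1] == "dropout"
        assert labels[2] == "dropout"


class TestFilterTrials:
    def test_clean_trial_retained(self):
        trial = full_group_trial(np.zeros((6, 9)))
        kept, mask = filter_trials([trial])
        assert mask == [True]

    def test_removal_rule_requires_both_conditions(self):
        rounds = 24
        # 10 recruits: 1 missed-rounds + 3 dropouts = 40% irregular -> removed
        paths = np.zeros((rounds, 10))
        paths[:6, 0] = np.nan
        bad = full_group_trial(paths, n_committed=2)
        for seat in (1, 2, 3):
            bad.roles[seat] = ROLE_DROPOUT
        # 3 dropouts but nobody missed rounds -> retained
        paths2 = np.zeros((rounds, 10))
        ok = full_group_trial(paths2, n_committed=2)
        for seat in (1, 2, 3):
            ok.roles[seat] = ROLE_DROPOUT
        kept, mask = filter_trials([bad, ok])
        assert mask == [False, True]
        assert len(kept) == 1 and kept[0] is ok


class TestCountSwitchEvents:
    def test_hand_classified_switches(self):
        """Path [0,1,1,0,0]: the switch to 1 joins a 3/11 minority, the
        switch back to 0 joins a 4/11 minority; no consensus, so both
        switches count undiscounted."""
        rounds = 5
        paths = np.zeros((rounds, 1))
        paths[1:3, 0] = 1.0  # the focal participant: 0,1,1,0,0
        # 11 fellow players: 3 on the alternative when the first switch is
        # decided (round 1 information), 7 when the second is decided
        others = np.zeros((rounds, 8))
        bots = np.ones((rounds, 3))  # committed bots on 1 throughout stage II
        others[1:, 0] = 1.0
        others[2:, 1:4] = 1.0  # round 3 onwards: 4 others + 3 bots = 7 on 1
        strategies = np.hstack([paths, others, bots])
        roles = [ROLE_PARTICIPANT] * 9 + [ROLE_COMMITTED] * 3
        trial = make_trial(strategies, roles, stage2_start=1)
        sw, mn, mj, tie = count_switch_events(trial, 0, t_star=5, diffused=False)
        assert (sw, mn, mj, tie) == (2, 2, 0, 0)

    def test_constant_path(self):
        trial = full_group_trial(np.zeros((6, 9)))
        assert count_switch_events(trial, 0, 6, False) == (0, 0, 0, 0)

    def test_final_consensus_switch_discounted_and_majority(self):
        rounds = 6
        paths = np.ones((rounds, 9))
        paths[0] = 0.0
        paths[:5, 0] = 0.0  # focal switches only in the final round
        trial = full_group_trial(paths)
        sw, mn, mj, tie = count_switch_events(trial, 0, t_star=6, diffused=True)
        assert (sw, mn, mj) == (0, 0, 1)

    def test_info_set_convention_switchable(self):
        rounds = 3
        paths = np.zeros((rounds, 9))
        paths[1:, 0] = 1.0
        paths[1:, 1:5] = 1.0  # four others move in the same round
        trial = full_group_trial(paths)
        _, mn_prev, _, _ = count_switch_events(trial, 0, 3, False, info="previous")
        _, mn_curr, _, _ = count_switch_events(trial, 0, 3, False, info="current")
        # against the previous round the mover joined a 0/11 minority;
        # against the same round it joined 4 participants + 3 bots = 7/11
        assert mn_prev == 1
        assert mn_curr == 0


class TestDiscriminantAndClassification:
    def test_discriminant_arithmetic(self):
        assert behavioural_discriminant(3, 1, 2, 10) == pytest.approx(0.3)
        assert behavioural_discriminant(4, 1, 3, 24) == pytest.approx(4 / 24 - 0.5)
        assert behavioural_discriminant(0, 0, 0, 24) == 0.0

    def test_zero_t_star_rejected(self):
        with pytest.raises(ValueError):
            behavioural_discriminant(1, 0, 0, 0)

    def test_classification_rules(self):
        assert classify(0, 5.0) == "non-explorer"
        assert classify(1, 0.3) == "explorer"
        assert classify(1, -1 / 3) == "non-explorer"
        assert classify(2, 0.0) == "non-explorer"

    def test_majority_only_joiner_is_non_explorer(self):
        """A participant who only ever follows the current majority has
        min_count = 0 and is always a non-explorer."""
        rounds = 8
        paths = np.ones((rounds, 9))
        paths[0] = 0.0
        paths[:5, 0] = 0.0  # focal follows once the majority has moved
        trial = full_group_trial(paths)
        stats = process_trial(trial)
        focal = [s for s in stats if s.seat == 0][0]
        assert focal.min_count == 0
        assert focal.label == "non-explorer"

    def test_seat_relabelling_invariance(self):
        rounds = 10
        rng = np.random.default_rng(5)
        paths = (rng.random((rounds, 9)) < 0.4).astype(float)
        trial = full_group_trial(paths)
        stats = {s.seat: s.label for s in process_trial(trial)}
        perm = [3, 1, 0, 2, 4, 5, 8, 6, 7]
        permuted = make_trial(
            np.hstack([paths[:, perm], trial.strategies[:, 9:]]),
            trial.roles,
            stage2_start=2,
        )
        stats_perm = {s.seat: s.label for s in process_trial(permuted)}
        for new, old in enumerate(perm):
            assert stats_perm[new] == stats[old]


class TestClassSummary:
    def test_equal_rates_zero_sd(self):
        stats = [
            ParticipantStats("t", i, "none", label="explorer", y=0.3) for i in range(3)
        ]
        cs = class_summary(stats)
        assert cs.mu_e == pytest.approx(0.3)
        assert cs.sigma_e == pytest.approx(0.0)

    def test_sample_standard_deviation(self):
        stats = [
            ParticipantStats("t", 0, "none", label="explorer", y=0.2),
            ParticipantStats("t", 1, "none", label="explorer", y=0.4),
        ]
        cs = class_summary(stats)
        assert cs.mu_e == pytest.approx(0.3)
        assert cs.sigma_e == pytest.approx(np.std([0.2, 0.4], ddof=1))

    def test_empty_class_flagged(self):
        stats = [ParticipantStats("t", 0, "none", label="explorer", y=0.2)]
        cs = class_summary(stats)
        assert cs.n_n == 0
        assert not cs.defined
        assert np.isnan(cs.mu_n)


class TestEmpiricalTStar:
    def test_consensus_round_found(self):
        rounds = 6
        paths = np.ones((rounds, 9))
        paths[0] = 0.0
        paths[:4, 0] = 0.0  # slowest regular adopts in round 5
        trial = full_group_trial(paths)
        t_star, diffused = empirical_t_star(trial, identify_irregulars(trial))
        assert (t_star, diffused) == (5, True)

    def test_no_consensus_defaults_to_24(self):
        trial = full_group_trial(np.zeros((24, 9)))
        t_star, diffused = empirical_t_star(trial, identify_irregulars(trial))
        assert (t_star, diffused) == (24, False)


def test_process_trials_pipeline(realistic_dataset):
    frame, stats = process_trials(realistic_dataset)
    regular = frame[frame.irregular == "none"]
    assert set(regular.label) <= {"explorer", "non-explorer"}
    assert ((regular.y >= 0) & (regular.y <= 1)).all()
    assert stats.n_e + stats.n_n == len(regular)
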