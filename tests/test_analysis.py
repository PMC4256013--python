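"""Interval-bias statistics: splits, classifications, rates, JND ratios."""

import math

import numpy as np
import pytest

from helpers import block_from_trials, raw_trial, trial_with_diff
from intervalbias import (
    BiasLabel,
    ModelTag,
    ObserverParams,
    Protocol,
    ProtocolSpec,
    RefPosition,
    RepeatLabel,
    SimulationConfig,
    classify_bias_trials,
    classify_repeat_trials,
    fit_psychometric_jnd,
    jnd_ratio,
    jnd_ratios_by_participant,
    overall_percent_correct,
    paired_test,
    percent_correct_by_higher_tone,
    percent_correct_by_reference,
    response_rate_first_higher,
    simulate_experiment,
)

LN1000 = math.log(1000.0)


class TestPairedTest:
    def test_textbook_worked_example(self):
        """Differences {1,2,3,4}: mean 2.5, SD 1.2910 -> t = 3.873,
        Cohen's d = 1.936."""
        res = paired_test([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0])
        assert res.t == pytest.approx(3.873, abs=5e-4)
        assert res.d == pytest.approx(1.936, abs=5e-4)
        assert not res.degenerate

    def test_identical_vectors(self):
        res = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p, res.d) == (0.0, 1.0, 0.0)
        assert res.degenerate

    def test_constant_nonzero_difference_flagged(self):
        res = paired_test([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert res.degenerate
        assert math.isnan(res.t)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_test([1.0], [0.0])


def _toy_participant_blocks(pid="p1"):
    """4 Ref1 trials with 3 correct, 4 Ref2 trials with 2 correct."""
    trials = []
    for i in range(4):
        trials.append(trial_with_diff(i + 1, 5.0, ref_first=True, correct=i < 3))
    for i in range(4):
        trials.append(trial_with_diff(i + 5, 5.0, ref_first=False, correct=i < 2))
    return [block_from_trials(trials, pid=pid, bid=f"{pid}-1")]


class TestReferenceSplit:
    def test_toy_counting(self):
        rep = percent_correct_by_reference(_toy_participant_blocks())
        assert rep.pc_group1 == pytest.approx(75.0)
        assert rep.pc_group2 == pytest.approx(50.0)
        assert rep.n_participants == 1
        assert rep.degenerate  # no paired test on one participant

    def test_all_correct_degenerate(self):
        blocks = [
            block_from_trials(
                [trial_with_diff(1, 5.0, ref_first=True, correct=True),
                 trial_with_diff(2, 5.0, ref_first=False, correct=True)],
                pid=pid, bid=pid,
            )
            for pid in ("a", "b", "c")
        ]
        rep = percent_correct_by_reference(blocks)
        assert (rep.pc_group1, rep.pc_group2) == (100.0, 100.0)
        assert rep.degenerate

    def test_participant_without_both_groups_is_excluded(self):
        ok = _toy_participant_blocks("p1")
        only_ref1 = [
            block_from_trials(
                [trial_with_diff(1, 5.0, ref_first=True, correct=True)],
                pid="p2", bid="p2-1",
            )
        ]
        rep = percent_correct_by_reference(ok + only_ref1)
        assert rep.n_participants == 1
        assert rep.excluded_participants == ("p2",)

    def test_exclude_first_n_drops_early_trials(self):
        # the toy participant's Ref1 trials are exactly the first four, so
        # excluding them leaves no participant with trials in both groups
        with pytest.raises(ValueError):
            percent_correct_by_reference(_toy_participant_blocks(), exclude_first_n=4)

    def test_missing_reference_labels_rejected(self):
        block = block_from_trials(
            [raw_trial(1, 1050.0, 1000.0, correct=True)],
            protocol=ProtocolSpec(Protocol.NO_REFERENCE, block_length=1),
        )
        with pytest.raises(ValueError):
            percent_correct_by_reference([block])


class TestHigherToneSplit:
    def test_toy_two_trials(self):
        trials = [
            raw_trial(1, 1050.0, 1000.0, RefPosition.SECOND, correct=True),
            raw_trial(2, 1000.0, 1050.0, RefPosition.FIRST, correct=True),
        ]
        rep = percent_correct_by_higher_tone([block_from_trials(trials)])
        assert (rep.pc_group1, rep.pc_group2) == (100.0, 100.0)

    def test_equivalent_to_reference_split_in_reference_lower(
        self, reference_lower_blocks
    ):
        """In the reference-lower design the comparison is always higher,
        so the higher-tone split is the reference split with the groups
        swapped."""
        by_ref = percent_correct_by_reference(reference_lower_blocks)
        by_tone = percent_correct_by_higher_tone(reference_lower_blocks)
        assert by_tone.pc_group1 == pytest.approx(by_ref.pc_group2)
        assert by_tone.pc_group2 == pytest.approx(by_ref.pc_group1)
        assert by_tone.t_stat == pytest.approx(-by_ref.t_stat)

    def test_pooled_groups_recover_overall_percent_correct(
        self, reference_lower_blocks
    ):
        blocks = [b for b in reference_lower_blocks if b.participant_id == "sim001"]
        rep = percent_correct_by_reference(blocks)
        n1 = sum(t.ref_position is RefPosition.FIRST for b in blocks for t in b.trials)
        n2 = sum(t.ref_position is RefPosition.SECOND for b in blocks for t in b.trials)
        pooled = (rep.pc_group1 * n1 + rep.pc_group2 * n2) / (n1 + n2)
        overall = overall_percent_correct(blocks)
        assert pooled == pytest.approx(overall.mean)

    def test_naive_observer_shows_no_tone_bias(self):
        """A history-free observer splits evenly by which tone is higher."""
        spec = ProtocolSpec(Protocol.REFERENCE)
        obs = ObserverParams(ModelTag.NAIVE, sigma=0.04)
        blocks, _ = simulate_experiment(
            SimulationConfig(spec, obs, n_participants=100, master_seed=50)
        )
        rep = percent_correct_by_higher_tone(blocks)
        assert abs(rep.gap) < 2.0
        assert rep.p_value > 0.01


class TestClassifications:
    def test_bias_plus_when_trace_above_descending_pair(self):
        trials = [
            raw_trial(1, 1100.0, 1200.0),  # sets m = ln 1100
            raw_trial(2, 1050.0, 1000.0),  # m > x1 > x2
        ]
        labels = classify_bias_trials(block_from_trials(trials))
        assert labels == [BiasLabel.NEUTRAL, BiasLabel.BIAS_PLUS]

    def test_bias_minus_when_contraction_shrinks_difference(self):
        trials = [
            raw_trial(1, 1100.0, 1200.0),
            raw_trial(2, 1000.0, 1050.0),  # x1 < x2 with m > x1
        ]
        labels = classify_bias_trials(block_from_trials(trials))
        assert labels[1] is BiasLabel.BIAS_MINUS

    def test_neutral_when_trace_equals_first_tone(self):
        trials = [raw_trial(1, 1000.0, 1100.0), raw_trial(2, 1000.0, 1050.0)]
        labels = classify_bias_trials(block_from_trials(trials))
        assert labels[1] is BiasLabel.NEUTRAL

    def test_repeat_labels_constant_and_alternating(self):
        up = [raw_trial(i + 1, 1050.0, 1000.0) for i in range(4)]
        labels = classify_repeat_trials(block_from_trials(up))
        assert labels[0] is None
        assert all(l is RepeatLabel.REPEAT for l in labels[1:])

        alternating = [
            raw_trial(i + 1, *((1050.0, 1000.0) if i % 2 == 0 else (1000.0, 1050.0)))
            for i in range(4)
        ]
        labels = classify_repeat_trials(block_from_trials(alternating))
        assert all(l is RepeatLabel.ALTERNATE for l in labels[1:])

    def test_repeat_needs_two_trials(self):
        with pytest.raises(ValueError):
            classify_repeat_trials(block_from_trials([raw_trial(1, 1050.0, 1000.0)]))


class TestResponseRate:
    def test_toy_rate(self):
        trials = [
            raw_trial(1, 1050.0, 1000.0, correct=True),   # responded first
            raw_trial(2, 1050.0, 1000.0, correct=True),   # responded first
            raw_trial(3, 1000.0, 1050.0, correct=False),  # responded first
            raw_trial(4, 1000.0, 1050.0, correct=True),   # responded second
        ]
        rep = response_rate_first_higher([block_from_trials(trials)])
        assert rep.mean == pytest.approx(75.0)

    def test_reconstruction_matches_recorded_responses(self, reference_blocks):
        recorded = response_rate_first_higher(reference_blocks[:5])
        import dataclasses

        stripped = []
        for b in reference_blocks[:5]:
            trials = [
                dataclasses.replace(t, response_first_higher=None) for t in b.trials
            ]
            stripped.append(dataclasses.replace(b, trials=trials))
        assert response_rate_first_higher(stripped).mean == pytest.approx(
            recorded.mean
        )

    def test_strong_bias_saturates_rate(self):
        spec = ProtocolSpec(Protocol.REFERENCE)
        obs = ObserverParams(ModelTag.RESPONSE_BIAS, sigma=0.04, beta=50.0)
        blocks, _ = simulate_experiment(
            SimulationConfig(spec, obs, n_participants=5, master_seed=51)
        )
        assert response_rate_first_higher(blocks).mean > 95.0


class TestJndRatio:
    def test_symmetric_behavior_gives_unit_ratio(self):
        trials = []
        idx = 1
        for d, correct in [(2.0, True), (4.0, True), (6.0, True), (3.0, False)] * 4:
            trials.append(trial_with_diff(idx, d, ref_first=True, correct=correct))
            idx += 1
            trials.append(trial_with_diff(idx, d, ref_first=False, correct=correct))
            idx += 1
        r = jnd_ratio([block_from_trials(trials)])
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance(self):
        """Doubling every stimulus difference doubles both subset JNDs and
        leaves the ratio unchanged."""
        rng = np.random.default_rng(52)
        slope = {True: 3.0, False: 6.0}  # Ref1 twice as acute as Ref2

        def synth(scale):
            trials, idx = [], 1
            for _ in range(300):
                for ref_first in (True, False):
                    d = float(rng.uniform(0.5, 12.0))
                    p = float(
                        0.5 + 0.5 * math.erf(d / slope[ref_first] / math.sqrt(2))
                    )
                    correct = bool(rng.random() < p)
                    trials.append(
                        trial_with_diff(idx, d * scale, ref_first=ref_first,
                                        correct=correct)
                    )
                    idx += 1
            return [block_from_trials(trials)]

        rng_state = rng.bit_generator.state
        r1 = jnd_ratio(synth(1.0))
        rng.bit_generator.state = rng_state
        r2 = jnd_ratio(synth(2.0))
        assert r2 == pytest.approx(r1, rel=1e-6)
        assert r1 < 1.0  # Ref1 subset is more acute by construction

    def test_insufficient_trials_rejected(self):
        trials = [trial_with_diff(1, 5.0, ref_first=True, correct=True)]
        with pytest.raises(ValueError):
            jnd_ratio([block_from_trials(trials)])

    def test_fit_recovers_known_psychometric_slope(self):
        rng = np.random.default_rng(53)
        s = 4.0
        d = rng.uniform(0.5, 12.0, size=800)
        from scipy.special import ndtr

        correct = rng.random(800) < ndtr(d / s)
        jnd = fit_psychometric_jnd(d, correct)
        expected = s * 0.8207  # inv_Phi(0.5 ** (1/3))
        assert jnd == pytest.approx(expected, rel=0.2)

    def test_protocol_direction_of_median_ratio(
        self, reference_lower_blocks, reference_blocks
    ):
        """The contraction observer yields r > 1 (worse Ref1 acuity) in the
        reference-lower design and r < 1 in the reference design."""
        r_low = jnd_ratios_by_participant(reference_lower_blocks).median()
        r_ref = jnd_ratios_by_participant(reference_blocks).median()
        assert r_low > 1.0
        assert r_ref < 1.0
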