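"""Behavioral statistics for interval bias.

The central quantity is percent correct computed separately over two
complementary groups of trials — by reference interval (Ref1 vs Ref2), by
which tone was higher, by whether contraction toward the stimulus history
helps (Bias+) or hurts (Bias−), and by whether the correct response
repeats the previous trial's.  Trials are pooled within participant
(across that participant's blocks) before computing percentages, and all
population statistics (mean ± SEM, paired t-tests, Cohen's d) are taken
across participants.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .protocols import Block, RefPosition, jnd_from_block, trial_diff_percent

__all__ = [
    "BiasLabel",
    "RepeatLabel",
    "SplitReport",
    "PairedTestResult",
    "RateReport",
    "paired_test",
    "percent_correct_by_reference",
    "percent_correct_by_higher_tone",
    "percent_correct_by_bias",
    "percent_correct_by_repeat",
    "response_rate_first_higher",
    "classify_bias_trials",
    "classify_repeat_trials",
    "fit_psychometric_jnd",
    "jnd_ratio",
    "jnd_ratios_by_participant",
    "overall_percent_correct",
    "population_jnd",
]

logger = logging.getLogger(__name__)

#: Criterion performance level of the 3-down-1-up track, 0.5**(1/3).
CRITERION_P = 0.5 ** (1.0 / 3.0)


class BiasLabel(enum.Enum):
    BIAS_PLUS = "bias+"
    BIAS_MINUS = "bias-"
    NEUTRAL = "neutral"


class RepeatLabel(enum.Enum):
    REPEAT = "repeat"
    ALTERNATE = "alternate"


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    d: float  # Cohen's d = mean(diff) / SD(diff)
    n: int
    degenerate: bool = False


def paired_test(
    values_group1: Sequence[float], values_group2: Sequence[float]
) -> PairedTestResult:
    """Two-sided paired t-test with Cohen's d on the paired differences.

    Zero-variance differences are flagged degenerate: identical vectors
    return (t=0, p=1, d=0), a constant non-zero difference returns NaNs.
    """
    v1 = np.asarray(values_group1, dtype=float)
    v2 = np.asarray(values_group2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if len(v1) < 2:
        raise ValueError("need at least 2 pairs")
    diff = v1 - v2
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if np.all(diff == 0.0):
            return PairedTestResult(t=0.0, p=1.0, d=0.0, n=len(v1), degenerate=True)
        return PairedTestResult(
            t=math.nan, p=math.nan, d=math.nan, n=len(v1), degenerate=True
        )
    t, p = stats.ttest_rel(v1, v2)
    d = float(diff.mean()) / sd
    return PairedTestResult(t=float(t), p=float(p), d=d, n=len(v1))


@dataclass(frozen=True)
class SplitReport:
    """Population summary of percent correct in two groups of trials."""

    split_name: str
    pc_group1: float
    pc_group2: float
    sem1: float
    sem2: float
    n_participants: int
    t_stat: float
    p_value: float
    cohens_d: float
    fraction_group1_better: float
    degenerate: bool
    per_participant: pd.DataFrame  # columns pc1, pc2 indexed by participant
    excluded_participants: tuple = ()

    @property
    def gap(self) -> float:
        """pc_group1 − pc_group2 in percentage points."""
        return self.pc_group1 - self.pc_group2


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return math.nan
    return float(values.std(ddof=1) / math.sqrt(len(values)))


def _trial_records(
    blocks: Sequence[Block],
    group_fn: Callable[[Block], list[Optional[int]]],
    exclude_first_n: int = 0,
) -> pd.DataFrame:
    """One row per grouped trial: participant, group (1/2), correct."""
    rows = []
    for b in blocks:
        groups = group_fn(b)
        for t, g in zip(b.trials, groups):
            if g is None or t.index <= exclude_first_n:
                continue
            if t.correct is None:
                raise ValueError(
                    f"trial {t.index} of block {b.block_id!r} has no outcome"
                )
            rows.append((b.participant_id, g, bool(t.correct)))
    return pd.DataFrame(rows, columns=["participant", "group", "correct"])


def _split_report(records: pd.DataFrame, split_name: str) -> SplitReport:
    per_part = {}
    excluded = []
    for pid, grp in records.groupby("participant", sort=False):
        g1 = grp.loc[grp["group"] == 1, "correct"]
        g2 = grp.loc[grp["group"] == 2, "correct"]
        if len(g1) == 0 or len(g2) == 0:
            excluded.append(pid)
            logger.info(
                "participant %r excluded from %s: empty group", pid, split_name
            )
            continue
        per_part[pid] = (100.0 * g1.mean(), 100.0 * g2.mean())
    if not per_part:
        raise ValueError(f"{split_name}: no participant has trials in both groups")
    frame = pd.DataFrame.from_dict(per_part, orient="index", columns=["pc1", "pc2"])
    pc1 = frame["pc1"].to_numpy()
    pc2 = frame["pc2"].to_numpy()
    if len(frame) < 2:
        test = PairedTestResult(
            t=math.nan, p=math.nan, d=math.nan, n=len(frame), degenerate=True
        )
    else:
        test = paired_test(pc1, pc2)
    better = np.where(pc1 > pc2, 1.0, np.where(pc1 < pc2, 0.0, 0.5))
    return SplitReport(
        split_name=split_name,
        pc_group1=float(pc1.mean()),
        pc_group2=float(pc2.mean()),
        sem1=_sem(pc1),
        sem2=_sem(pc2),
        n_participants=len(frame),
        t_stat=test.t,
        p_value=test.p,
        cohens_d=test.d,
        fraction_group1_better=float(better.mean()),
        degenerate=test.degenerate,
        per_participant=frame,
        excluded_participants=tuple(excluded),
    )


def percent_correct_by_reference(
    blocks: Sequence[Block], exclude_first_n: int = 0
) -> SplitReport:
    """Percent correct in Ref1 (reference first) vs Ref2 trials.

    ``exclude_first_n`` drops that many trials from the start of every
    block before pooling, to check that the bias is not an artifact of
    the staircase's initial descent.
    """

    def groups(b: Block) -> list[Optional[int]]:
        out = []
        for t in b.trials:
            if t.ref_position is RefPosition.FIRST:
                out.append(1)
            elif t.ref_position is RefPosition.SECOND:
                out.append(2)
            else:
                raise ValueError(
                    "reference split needs ref_position FIRST/SECOND on every trial"
                )
        return out

    records = _trial_records(blocks, groups, exclude_first_n)
    return _split_report(records, "ref1_vs_ref2")


def percent_correct_by_higher_tone(
    blocks: Sequence[Block], exclude_first_n: int = 0
) -> SplitReport:
    """Percent correct when the first tone is higher vs the second."""

    def groups(b: Block) -> list[Optional[int]]:
        return [1 if t.x1 > t.x2 else 2 for t in b.trials]

    records = _trial_records(blocks, groups, exclude_first_n)
    return _split_report(records, "f1higher_vs_f2higher")


def classify_bias_trials(block: Block) -> list[BiasLabel]:
    """Label each trial by whether contraction toward the history helps.

    With m(t) the running mean of the previous trials' first-tone logs,
    pulling the remembered x1 toward m enlarges the perceived difference
    in the correct direction iff (m − x1)(x1 − x2) > 0 (Bias+), shrinks
    it iff < 0 (Bias−), and is neutral at exact equality.  Trial 1 has no
    history and is neutral.
    """
    labels = []
    total = 0.0
    for n, t in enumerate(block.trials):
        if n == 0:
            labels.append(BiasLabel.NEUTRAL)
        else:
            m = total / n
            moment = (m - t.x1) * (t.x1 - t.x2)
            if moment > 0:
                labels.append(BiasLabel.BIAS_PLUS)
            elif moment < 0:
                labels.append(BiasLabel.BIAS_MINUS)
            else:
                labels.append(BiasLabel.NEUTRAL)
        total += t.x1
    return labels


def classify_repeat_trials(block: Block) -> list[Optional[RepeatLabel]]:
    """Label each trial by whether the correct response repeats.

    Trial t is REPEAT iff the higher interval (= correct response) is the
    same as on trial t−1; the first trial is unlabeled.
    """
    if len(block.trials) < 2:
        raise ValueError("need at least 2 trials to classify repeats")
    labels: list[Optional[RepeatLabel]] = [None]
    for prev, cur in zip(block.trials, block.trials[1:]):
        same = (cur.x1 > cur.x2) == (prev.x1 > prev.x2)
        labels.append(RepeatLabel.REPEAT if same else RepeatLabel.ALTERNATE)
    return labels


def percent_correct_by_bias(blocks: Sequence[Block]) -> SplitReport:
    """Percent correct in Bias+ vs Bias− trials (neutral trials dropped)."""

    def groups(b: Block) -> list[Optional[int]]:
        mapping = {BiasLabel.BIAS_PLUS: 1, BiasLabel.BIAS_MINUS: 2}
        return [mapping.get(lab) for lab in classify_bias_trials(b)]

    records = _trial_records(blocks, groups)
    return _split_report(records, "biasplus_vs_biasminus")


def percent_correct_by_repeat(blocks: Sequence[Block]) -> SplitReport:
    """Percent correct in Repeat vs Alternate trials (trial 1 dropped)."""

    def groups(b: Block) -> list[Optional[int]]:
        mapping = {RepeatLabel.REPEAT: 1, RepeatLabel.ALTERNATE: 2}
        return [None if lab is None else mapping[lab] for lab in classify_repeat_trials(b)]

    records = _trial_records(blocks, groups)
    return _split_report(records, "repeat_vs_alternate")


@dataclass(frozen=True)
class RateReport:
    mean: float
    sem: float
    n_participants: int
    per_participant: pd.Series


def _response_first_higher(trial) -> bool:
    if trial.response_first_higher is not None:
        return trial.response_first_higher
    if trial.correct is None:
        raise ValueError("trial has neither response nor outcome")
    return trial.correct == (trial.x1 > trial.x2)


def response_rate_first_higher(blocks: Sequence[Block]) -> RateReport:
    """Per-participant rate of "first tone higher" responses, as percent.

    A missing response is reconstructed from correctness and which tone
    was higher.  A rate near 50% rules out a blanket response bias.
    """
    rows = [
        (b.participant_id, _response_first_higher(t))
        for b in blocks
        for t in b.trials
    ]
    frame = pd.DataFrame(rows, columns=["participant", "first_higher"])
    per = 100.0 * frame.groupby("participant", sort=False)["first_higher"].mean()
    return RateReport(
        mean=float(per.mean()),
        sem=_sem(per.to_numpy()),
        n_participants=len(per),
        per_participant=per,
    )


def overall_percent_correct(blocks: Sequence[Block]) -> RateReport:
    """Mean ± SEM across participants of per-participant percent correct."""
    rows = []
    for b in blocks:
        for t in b.trials:
            if t.correct is None:
                raise ValueError(f"block {b.block_id!r} has trials without outcomes")
            rows.append((b.participant_id, t.correct))
    frame = pd.DataFrame(rows, columns=["participant", "correct"])
    per = 100.0 * frame.groupby("participant", sort=False)["correct"].mean()
    return RateReport(
        mean=float(per.mean()),
        sem=_sem(per.to_numpy()),
        n_participants=len(per),
        per_participant=per,
    )


def population_jnd(blocks: Sequence[Block], n_last: int = 20) -> RateReport:
    """Mean ± SEM across participants of the staircase JND (% difference).

    Each participant's JND is the mean over their blocks of the last-20-
    trials mean frequency difference.
    """
    rows = [(b.participant_id, jnd_from_block(b, n_last)) for b in blocks]
    frame = pd.DataFrame(rows, columns=["participant", "jnd"])
    per = frame.groupby("participant", sort=False)["jnd"].mean()
    return RateReport(
        mean=float(per.mean()),
        sem=_sem(per.to_numpy()),
        n_participants=len(per),
        per_participant=per,
    )


def fit_psychometric_jnd(
    diff_percents: Sequence[float],
    corrects: Sequence[bool],
    criterion: float = CRITERION_P,
) -> float:
    """JND from a one-parameter probit psychometric fit.

    Fits P(correct | d) = Phi(d / s) by maximum likelihood over the slope
    s > 0 (d is the unsigned % frequency difference, so chance is pinned
    at d = 0) and returns the difference achieving the criterion level,
    s * Phi^{-1}(criterion).  Raises if the fit does not converge.
    """
    d = np.asarray(diff_percents, dtype=float)
    y = np.asarray(corrects, dtype=bool)
    if d.shape != y.shape or d.ndim != 1 or len(d) == 0:
        raise ValueError("diff_percents and corrects must be equal-length 1-D")
    if np.any(d <= 0):
        raise ValueError("differences must be positive")

    def negll(log_s: float) -> float:
        p = ndtr(d / math.exp(log_s))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -float(np.sum(np.where(y, np.log(p), np.log(1.0 - p))))

    res = optimize.minimize_scalar(
        negll, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"psychometric fit did not converge: {res.message}")
    return math.exp(float(res.x)) * float(ndtri(criterion))


def jnd_ratio(
    participant_blocks: Sequence[Block],
    exclude_first_n: int = 0,
    min_trials: int = 10,
) -> float:
    """Ratio r = JND(Ref1 trials) / JND(Ref2 trials) for one participant.

    Subset JNDs come from separate psychometric fits because interleaved
    staircase subsets share the same tracked differences, so the last-20
    rule cannot distinguish them.  r > 1 means worse acuity on Ref1
    trials.
    """
    subsets: dict[int, tuple[list[float], list[bool]]] = {1: ([], []), 2: ([], [])}
    for b in participant_blocks:
        for t in b.trials:
            if t.index <= exclude_first_n:
                continue
            if t.ref_position is RefPosition.FIRST:
                g = 1
            elif t.ref_position is RefPosition.SECOND:
                g = 2
            else:
                raise ValueError("jnd_ratio needs reference-position labels")
            if t.correct is None:
                raise ValueError("jnd_ratio needs trial outcomes")
            subsets[g][0].append(trial_diff_percent(t, b.protocol))
            subsets[g][1].append(t.correct)
    for g in (1, 2):
        if len(subsets[g][0]) < min_trials:
            raise ValueError(
                f"fewer than {min_trials} trials in subset Ref{g}"
            )
    jnd1 = fit_psychometric_jnd(*subsets[1])
    jnd2 = fit_psychometric_jnd(*subsets[2])
    if jnd2 == 0.0:
        raise ValueError("degenerate Ref2 psychometric fit (zero JND)")
    return jnd1 / jnd2


def jnd_ratios_by_participant(
    blocks: Sequence[Block], exclude_first_n: int = 0, min_trials: int = 10
) -> pd.Series:
    """r per participant (see :func:`jnd_ratio`); failures are excluded.

    The population summary used downstream is the median of the returned
    series.
    """
    by_pid: dict[object, list[Block]] = {}
    for b in blocks:
        by_pid.setdefault(b.participant_id, []).append(b)
    ratios = {}
    for pid, pblocks in by_pid.items():
        try:
            ratios[pid] = jnd_ratio(pblocks, exclude_first_n, min_trials)
        except (ValueError, RuntimeError) as exc:
            logger.info("participant %r excluded from JND ratio: %s", pid, exc)
    if not ratios:
        raise ValueError("no participant yielded a JND ratio")
    return pd.Series(ratios, name="jnd_ratio")
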