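"""Shared constructors for hand-built trials and blocks."""

import math

from intervalbias import Block, Protocol, ProtocolSpec, RefPosition, Trial


def trial_with_diff(index, diff_percent, ref_hz=1000.0, ref_first=True, correct=True):
    """Reference-lower style trial: comparison above the reference by d%."""
    non = ref_hz * (1.0 + diff_percent / 100.0)
    f1, f2 = (ref_hz, non) if ref_first else (non, ref_hz)
    trial = Trial(
        index=index,
        x1=math.log(f1),
        x2=math.log(f2),
        ref_position=RefPosition.FIRST if ref_first else RefPosition.SECOND,
        diff_percent=float(diff_percent),
    )
    response = (f1 > f2) if correct else (f1 < f2)
    return trial.with_response(response)


def raw_trial(index, f1, f2, ref_position=RefPosition.NONE, correct=None):
    trial = Trial(
        index=index, x1=math.log(f1), x2=math.log(f2), ref_position=ref_position
    )
    if correct is not None:
        response = (f1 > f2) if correct else (f1 < f2)
        trial = trial.with_response(response)
    return trial


def block_from_trials(trials, protocol=None, pid="p1", bid="b1"):
    spec = protocol or ProtocolSpec(
        Protocol.REFERENCE_LOWER, block_length=len(trials)
    )
    return Block(protocol=spec, trials=list(trials), participant_id=pid, block_id=bid)
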