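"""Trial-table serialization, deposited-data decoding, and configuration.

The interchange schema is a flat table with one row per trial:

    participant, block, trial_index, f1_hz, f2_hz, ref_position,
    response_first_higher, correct

Simulated blocks serialize to it, CSV files round-trip through it, and
deposited MAT 5.0 experiment files (matrices ``s1``/``s2``/``c`` of shape
n_blocks x 80, plus an optional participant-ID vector) decode into it.
"""

from __future__ import annotations

import logging
import math
import tomllib
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.io import loadmat

from .protocols import Block, Protocol, ProtocolSpec, RefPosition, Trial

__all__ = [
    "TABLE_COLUMNS",
    "blocks_to_table",
    "table_to_blocks",
    "write_table",
    "read_table",
    "read_dataset_s1",
    "load_config",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = (
    "participant",
    "block",
    "trial_index",
    "f1_hz",
    "f2_hz",
    "ref_position",
    "response_first_higher",
    "correct",
)

#: Relative tolerance when deciding which interval holds the constant
#: reference tone (stimuli should be exactly 1000.0 Hz but float
#: round-trips are tolerated).
REFERENCE_MATCH_RTOL = 1e-6


def blocks_to_table(blocks: list[Block]) -> pd.DataFrame:
    """Flatten blocks into the interchange table (one row per trial)."""
    rows = []
    for b in blocks:
        for t in b.trials:
            rows.append(
                (
                    b.participant_id,
                    b.block_id,
                    t.index,
                    t.f1_hz,
                    t.f2_hz,
                    t.ref_position.value,
                    t.response_first_higher,
                    t.correct,
                )
            )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def table_to_blocks(table: pd.DataFrame, protocol: ProtocolSpec) -> list[Block]:
    """Rebuild Block objects from an interchange table.

    Rows are grouped by (participant, block) preserving order; trial
    indices must run 1..block_length within each group.
    """
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    blocks = []
    for (pid, bid), grp in table.groupby(["participant", "block"], sort=False):
        grp = grp.sort_values("trial_index")
        trials = []
        for row in grp.itertuples(index=False):
            resp = row.response_first_higher
            resp = None if pd.isna(resp) else bool(resp)
            corr = row.correct
            corr = None if pd.isna(corr) else bool(corr)
            trials.append(
                Trial(
                    index=int(row.trial_index),
                    x1=math.log(float(row.f1_hz)),
                    x2=math.log(float(row.f2_hz)),
                    ref_position=RefPosition(row.ref_position),
                    response_first_higher=resp,
                    correct=corr,
                )
            )
        block = Block(protocol=protocol, trials=trials, participant_id=pid, block_id=bid)
        block.validate()
        blocks.append(block)
    return blocks


def write_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the interchange table as CSV (full float precision)."""
    path = Path(path)
    try:
        table.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:  # surface the offending path
        raise OSError(f"failed to write trial table to {path}: {exc}") from exc


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CSV trial table written by :func:`write_table`."""
    path = Path(path)
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:
        raise OSError(f"failed to read trial table from {path}: {exc}") from exc
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("response_first_higher", "correct"):
        if table[col].notna().any():
            table[col] = table[col].astype(bool)
    return table


def _derive_ref_position(
    f1: float, f2: float, reference_hz: float, row_context: str
) -> RefPosition:
    tol = REFERENCE_MATCH_RTOL * reference_hz
    first = abs(f1 - reference_hz) <= tol
    second = abs(f2 - reference_hz) <= tol
    if first and second:
        raise ValueError(
            f"{row_context}: both tones equal the {reference_hz} Hz reference"
        )
    if first:
        return RefPosition.FIRST
    if second:
        return RefPosition.SECOND
    raise ValueError(
        f"{row_context}: neither tone ({f1}, {f2}) matches the "
        f"{reference_hz} Hz reference"
    )


def read_dataset_s1(
    path: Union[str, Path], protocol: ProtocolSpec
) -> pd.DataFrame:
    """Decode a deposited MAT 5.0 experiment file into the trial table.

    The file carries matrices ``s1`` and ``s2`` (stimuli in Hz) and ``c``
    (1 = correct) of shape n_blocks x 80.  A 1-D integer-like vector of
    length n_blocks, whatever its variable name, is taken as the
    participant ID of each block (its name is logged); without one, each
    block is its own participant.  The reference interval is derived as
    the interval whose tone equals the protocol's reference frequency,
    and the response is reconstructed from correctness and which tone was
    higher.
    """
    path = Path(path)
    mat = loadmat(path)
    for var in ("s1", "s2", "c"):
        if var not in mat:
            raise ValueError(f"{path}: missing MAT variable {var!r}")
    s1 = np.asarray(mat["s1"], dtype=float)
    s2 = np.asarray(mat["s2"], dtype=float)
    c = np.asarray(mat["c"], dtype=float)
    if not (s1.shape == s2.shape == c.shape) or s1.ndim != 2:
        raise ValueError(
            f"{path}: s1/s2/c must share one n_blocks x n_trials shape; got "
            f"{s1.shape}, {s2.shape}, {c.shape}"
        )
    n_blocks, n_trials = s1.shape

    participants = None
    for name, value in mat.items():
        if name.startswith("__") or name in ("s1", "s2", "c"):
            continue
        arr = np.asarray(value).squeeze()
        if arr.ndim == 1 and arr.size == n_blocks:
            participants = arr
            logger.info("using MAT variable %r as the participant vector", name)
            break
    if participants is None:
        participants = np.arange(1, n_blocks + 1)
        logger.info("no participant vector found; one participant per block")

    # block counter within participant, in file order
    block_no: dict[object, int] = {}
    rows = []
    for i in range(n_blocks):
        pid = participants[i].item() if hasattr(participants[i], "item") else participants[i]
        block_no[pid] = block_no.get(pid, 0) + 1
        bid = f"{pid}-{block_no[pid]}"
        for j in range(n_trials):
            f1, f2 = float(s1[i, j]), float(s2[i, j])
            if f1 <= 0 or f2 <= 0:
                raise ValueError(f"{path}: non-positive stimulus at block {i}, trial {j}")
            if protocol.name is Protocol.NO_REFERENCE:
                pos = RefPosition.NONE
            else:
                pos = _derive_ref_position(
                    f1, f2, protocol.reference_hz, f"{path} block {i} trial {j}"
                )
            correct = bool(c[i, j])
            response = correct == (f1 > f2)
            rows.append((pid, bid, j + 1, f1, f2, pos.value, response, correct))
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def load_config(path: Union[str, Path]) -> dict:
    """Load a TOML run configuration.

    Recognised sections: [protocol] (name, reference_hz, block_length,
    no_reference_range_hz), [observer], [fitting], [simulate].  The
    [protocol] section is materialised into a ProtocolSpec under the key
    "protocol_spec"; everything else is returned as plain dictionaries so
    callers keep their own defaults (precedence: caller args > config >
    package defaults).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    if "protocol" in cfg:
        p = cfg["protocol"]
        kwargs = {}
        if "reference_hz" in p:
            kwargs["reference_hz"] = float(p["reference_hz"])
        if "block_length" in p:
            kwargs["block_length"] = int(p["block_length"])
        if "no_reference_range_hz" in p:
            kwargs["no_reference_range_hz"] = tuple(p["no_reference_range_hz"])
        cfg["protocol_spec"] = ProtocolSpec(Protocol(p["name"]), **kwargs)
    return cfg
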