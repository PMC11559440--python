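"""Posture-code consolidation into the five groups, and majority-vote smoothing.

The device emits 15-second recordings built from a small code alphabet
(walking, upright, reclined, four lying variants, unknown, fall), plus
"S-"-prefixed self-reported variants and multi-code permutations when
the posture changed inside a slot.  Every recording collapses to one of
five groups; an isolated single-timestamp group flip between two equal
neighbours is treated as noise and removed by a one-pass majority vote.
"""

from __future__ import annotations

import logging
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GRID_SECONDS, tokenize_recording

logger = logging.getLogger(__name__)


class PostureGroup(str, Enum):
    LYING = "Lying"
    RECLINED = "Reclined"
    UPRIGHT = "Upright"
    UNKNOWN = "Unknown"
    USER_DEFINED = "UserDefined"


GROUPS: list[str] = [g.value for g in PostureGroup]

# Base code alphabet (configurable; the self-reported variants add an
# "S-" prefix to the first seven).
LYING_CODES = frozenset({"LSP", "LPR", "LRS", "LLS"})
UPRIGHT_CODES = frozenset({"U90", "WLK"})
RECLINED_CODES = frozenset({"U45"})
UNKNOWN_CODE = "UNK"
FALL_CODE = "FALL"
BASE_ALPHABET = sorted(LYING_CODES | UPRIGHT_CODES | RECLINED_CODES | {UNKNOWN_CODE, FALL_CODE})
SELF_REPORT_PREFIX = "S-"

GROUP_SERIES_COLUMNS = ["mrn", "timestamp", "group"]


def classify_recording(tokens: Sequence[str]) -> PostureGroup:
    """Map a tokenized recording to its posture group.

    Precedence: any self-reported token wins (UserDefined); then any UNK
    token or a blank recording (Unknown); then all-lying recordings
    (Lying); then any U90/WLK (Upright); then any U45 (Reclined).
    Anything left (e.g. a lone FALL or an unrecognized token) falls back
    to Unknown — the function is total.
    """
    if any(t.startswith(SELF_REPORT_PREFIX) for t in tokens):
        return PostureGroup.USER_DEFINED
    if not tokens or UNKNOWN_CODE in tokens:
        return PostureGroup.UNKNOWN
    token_set = set(tokens)
    if token_set <= LYING_CODES:
        return PostureGroup.LYING
    if token_set & UPRIGHT_CODES:
        return PostureGroup.UPRIGHT
    if token_set & RECLINED_CODES:
        return PostureGroup.RECLINED
    logger.debug("unrecognized recording %r classified as Unknown", list(tokens))
    return PostureGroup.UNKNOWN


def classify_string(posture_string: str) -> PostureGroup:
    """Tokenize then classify a raw posture string."""
    return classify_recording(tokenize_recording(posture_string))


def consolidate(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw recordings to a per-patient group series.

    Returns a frame with columns ``mrn, timestamp, group`` sorted by
    patient then timestamp.  Distinct posture strings are classified
    once and mapped, so cost scales with the number of unique strings.
    """
    out = records[["mrn", "timestamp"]].copy()
    raw = records["posture"].fillna("") if len(records) else pd.Series(dtype=str)
    uniques = raw.unique() if len(records) else np.array([], dtype=object)
    mapping = {s: classify_string(s).value for s in uniques}
    n_fallback = sum(
        1
        for s, g in mapping.items()
        if g == PostureGroup.UNKNOWN.value
        and tokenize_recording(s)
        and UNKNOWN_CODE not in tokenize_recording(s)
    )
    if n_fallback:
        logger.warning("%d unique posture strings fell through to Unknown", n_fallback)
    out["group"] = raw.map(mapping) if len(records) else pd.Series(dtype=str)
    return out.sort_values(["mrn", "timestamp"], kind="stable").reset_index(drop=True)


def smooth_majority_vote(series: pd.DataFrame) -> pd.DataFrame:
    """One-pass 3-window majority vote over each patient's group series.

    All votes are taken on the *input* values simultaneously.  An
    interior timestamp with grid-adjacent neighbours on both sides
    (15 s away, same patient) is replaced by the modal group of the
    3-window; with three distinct values there is no winner and the
    value is kept.  Timestamps adjacent to a data gap or at the edges
    of a patient's series are never changed, and the output has exactly
    the input's timestamps and gap structure.
    """
    df = series.sort_values(["mrn", "timestamp"], kind="stable").reset_index(drop=True)
    n = len(df)
    if n < 3:
        return df
    g = df["group"].to_numpy()
    ts = df["timestamp"].to_numpy()
    mrn = df["mrn"].to_numpy()
    step = np.timedelta64(GRID_SECONDS, "s")
    prev_ok = (mrn[1:-1] == mrn[:-2]) & ((ts[1:-1] - ts[:-2]) == step)
    next_ok = (mrn[1:-1] == mrn[2:]) & ((ts[2:] - ts[1:-1]) == step)
    # In a 3-window a majority exists iff the two neighbours agree; any
    # other agreeing pair already includes the centre value.
    change = prev_ok & next_ok & (g[:-2] == g[2:]) & (g[:-2] != g[1:-1])
    out = g.copy()
    idx = np.flatnonzero(change) + 1
    out[idx] = g[idx - 1]
    df = df.copy()
    df["group"] = out
    return df


def timeline_table(series: pd.DataFrame, mrn: str) -> pd.DataFrame:
    """Per-patient (timestamp, group) table for timeline plotting."""
    sub = series.loc[series["mrn"] == mrn, ["timestamp", "group"]]
    return sub.sort_values("timestamp", kind="stable").reset_index(drop=True)
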