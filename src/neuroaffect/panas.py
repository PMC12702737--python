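"""PANAS scoring and affect-change variable construction.

The 20-item PANAS is scored on a 1-5 Likert scale into a positive-affect
(PA) and a negative-affect (NA) subscale, each the sum of 10 items and hence
in [10, 50].  The derived variables are the pre-to-post subscale deltas and
the affective shift, the net PANAS change used as the subjective-reappraisal
predictor.  Because "net change" is ambiguous, the shift mode is explicit in
every output: ``net`` (default) is dPA - dNA, improvement-signed; ``sum`` is
dPA + dNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .exceptions import ConfigError, InputError

__all__ = [
    "POSITIVE_ITEMS",
    "NEGATIVE_ITEMS",
    "PanasScores",
    "AffectDeltas",
    "score_panas",
    "affect_deltas",
    "derive_affect_columns",
]

# Canonical 20-item ordering (0-based indices): interested, distressed,
# excited, upset, strong, guilty, scared, hostile, enthusiastic, proud,
# irritable, alert, ashamed, inspired, nervous, determined, attentive,
# jittery, active, afraid.
POSITIVE_ITEMS = (0, 2, 4, 8, 9, 11, 13, 15, 16, 18)
NEGATIVE_ITEMS = (1, 3, 5, 6, 7, 10, 12, 14, 17, 19)


@dataclass(frozen=True)
class PanasScores:
    pa: int
    na: int

    def __post_init__(self):
        for name, v in (("pa", self.pa), ("na", self.na)):
            if not 10 <= v <= 50:
                raise InputError(f"{name} score {v} outside [10, 50]")


@dataclass(frozen=True)
class AffectDeltas:
    delta_positive: float
    delta_negative: float
    affective_shift: float
    shift_mode: str


def score_panas(items: Sequence[int],
                positive_items: Sequence[int] = POSITIVE_ITEMS,
                negative_items: Sequence[int] = NEGATIVE_ITEMS) -> PanasScores:
    """Sum the positive and negative subscales of a 20-item response."""
    if len(items) != 20:
        raise InputError(f"expected 20 items, got {len(items)}")
    for idx, v in enumerate(items):
        if v is None or not float(v).is_integer() or not 1 <= int(v) <= 5:
            raise InputError(f"item {idx} value {v!r} outside Likert range [1, 5]")
    return PanasScores(pa=sum(int(items[i]) for i in positive_items),
                       na=sum(int(items[i]) for i in negative_items))


def affect_deltas(pre: PanasScores, post: PanasScores,
                  shift_mode: str = "net") -> AffectDeltas:
    """Pre-to-post deltas and the mode-tagged affective shift."""
    dp = float(post.pa - pre.pa)
    dn = float(post.na - pre.na)
    if shift_mode == "net":
        shift = dp - dn
    elif shift_mode == "sum":
        shift = dp + dn
    else:
        raise ConfigError(f"unknown shift_mode {shift_mode!r}; use 'net' or 'sum'")
    return AffectDeltas(delta_positive=dp, delta_negative=dn,
                        affective_shift=shift, shift_mode=shift_mode)


def derive_affect_columns(frame, shift_mode: str = "net"):
    """Recompute delta_positive / delta_negative / affective_shift columns.

    Works on a cohort table holding pa_pre / na_pre / pa_post / na_post
    (score-level) columns; returns a copy with the three derived columns
    overwritten and the shift mode recorded in ``frame.attrs``.
    """
    needed = ["pa_pre", "na_pre", "pa_post", "na_post"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise InputError(f"cohort is missing score columns: {missing}")
    if shift_mode not in ("net", "sum"):
        raise ConfigError(f"unknown shift_mode {shift_mode!r}; use 'net' or 'sum'")
    out = frame.copy()
    dp = out["pa_post"] - out["pa_pre"]
    dn = out["na_post"] - out["na_pre"]
    out["delta_positive"] = dp
    out["delta_negative"] = dn
    out["affective_shift"] = dp - dn if shift_mode == "net" else dp + dn
    out.attrs["shift_mode"] = shift_mode
    return out
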