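"""Per-participant episode definitions for weekly pain-diary series.

A week is a *zero-week* when the participant reported 0 days with bothersome
low-back pain; any response 1-7 is a pain week.  A *non-episode* is a run of
at least ``window`` (default 4) consecutive zero-weeks -- the proposed
pain-free demarcation between episodes of low-back pain.

Two missing-data policies are implemented:

STRICT
    A week counts as ZERO only when a response exists and equals 0; missing
    weeks count as pain so that zero-weeks are never overestimated.

LENIENT
    Starts from STRICT, then reclassifies an unanswered week as ZERO when it
    lies within ``window`` weeks (absolute distance, either direction) of a
    *responded* zero-week.  Imputed weeks never anchor further imputation,
    so the rule is applied in a single pass and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import ParticipantSeries

__all__ = [
    "PolicyMode",
    "PainStatePolicy",
    "PainStateSequence",
    "EpisodeProfile",
    "classify",
    "max_zero_run",
    "has_non_episode",
    "non_episode_at_end",
    "profile",
]


class PolicyMode(str, Enum):
    STRICT = "strict"
    LENIENT = "lenient"


@dataclass(frozen=True)
class PainStatePolicy:
    """Missing-data policy plus the non-episode window length in weeks."""

    mode: PolicyMode = PolicyMode.STRICT
    window: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", PolicyMode(self.mode))
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")


STRICT = PainStatePolicy(PolicyMode.STRICT)
LENIENT = PainStatePolicy(PolicyMode.LENIENT)


@dataclass(frozen=True)
class PainStateSequence:
    """Derived weekly states: ``zero[i]`` True where week i+1 is a zero-week.

    ``responded`` is carried alongside so downstream consumers can tell a
    reported zero-week from an imputed one.
    """

    zero: np.ndarray
    responded: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "zero", np.asarray(self.zero, dtype=bool))
        object.__setattr__(self, "responded", np.asarray(self.responded, dtype=bool))
        if self.zero.shape != self.responded.shape:
            raise ValueError("zero and responded must have the same length")

    def __len__(self) -> int:
        return self.zero.size


@dataclass(frozen=True)
class EpisodeProfile:
    """Summary of one participant under one policy."""

    max_zero_run: int
    has_non_episode: bool
    non_episode_at_end: bool


def classify(series: ParticipantSeries, policy: PainStatePolicy = STRICT) -> PainStateSequence:
    """Classify each week as zero-week or pain week under the given policy.

    STRICT: ZERO iff responded and value == 0.  LENIENT additionally imputes
    ZERO for unanswered weeks within ``policy.window`` weeks of a responded
    zero-week; responded weeks are never reclassified.
    """
    responded = series.responded
    zero = responded & (series.responses == 0)
    if policy.mode is PolicyMode.LENIENT:
        anchor_weeks = np.flatnonzero(zero)  # responded zero-weeks only
        if anchor_weeks.size:
            missing_weeks = np.flatnonzero(~responded)
            if missing_weeks.size:
                dist = np.abs(missing_weeks[:, None] - anchor_weeks[None, :]).min(axis=1)
                zero = zero.copy()
                zero[missing_weeks[dist <= policy.window]] = True
    return PainStateSequence(zero=zero, responded=responded)


def max_zero_run(states: PainStateSequence | np.ndarray) -> int:
    """Length of the longest run of consecutive zero-weeks (0 if none)."""
    zero = states.zero if isinstance(states, PainStateSequence) else np.asarray(states, dtype=bool)
    if zero.size == 0 or not zero.any():
        return 0
    # run lengths from boundaries of the boolean mask
    padded = np.concatenate(([False], zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def has_non_episode(states: PainStateSequence | np.ndarray, window: int = 4) -> bool:
    """True iff the series contains a pain-free run of at least ``window`` weeks."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    return max_zero_run(states) >= window


def non_episode_at_end(series: ParticipantSeries, policy: PainStatePolicy = STRICT) -> bool:
    """True iff the participant ends the study inside a non-episode.

    Counting starts from the last study week if it was answered, otherwise
    from the second-last week (no further fallback: if both are unanswered
    the start stays at the second-last week, which under STRICT is a pain
    week and the result is False; under LENIENT imputation may still apply).
    The result is True iff the ``window`` weeks ending at the start week are
    all zero-weeks under the policy.
    """
    n = series.study_weeks
    if n < policy.window + 1:
        raise ValueError(
            f"study horizon {n} too short for window {policy.window} plus fallback"
        )
    states = classify(series, policy)
    start = n - 1 if series.responded[n - 1] else n - 2
    return bool(states.zero[start - policy.window + 1 : start + 1].all())


def profile(series: ParticipantSeries, policy: PainStatePolicy = STRICT) -> EpisodeProfile:
    """Bundle the three per-participant statistics under a single policy."""
    states = classify(series, policy)
    run = max_zero_run(states)
    return EpisodeProfile(
        max_zero_run=run,
        has_non_episode=run >= policy.window,
        non_episode_at_end=non_episode_at_end(series, policy),
    )
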