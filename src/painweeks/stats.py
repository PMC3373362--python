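"""Cohort-level filtering, prevalence estimation, and summary tables.

Prevalences are reported as integer-rounded percentages with 95% confidence
intervals from the normal-approximation (Wald) interval

    p_hat +/- 1.96 * sqrt(p_hat * (1 - p_hat) / n),

clipped to [0, 100] and rounded to integer percent.  Two rounding variants
are provided: ``"nearest"`` (half away from zero; the canonical one) and
``"outward"`` (floor the lower bound, ceil the upper), since published
tables are found with either convention.  Non-overlap of two intervals is
the significance heuristic used at this reporting granularity.

The cohort summary mirrors the field's standard reporting shape: a
missingness table (weeks with no response, binned), the distribution of
each participant's maximum run of zero-weeks (binned 0..8, "9+"), and the
prevalences of any non-episode and of a non-episode at the end of the study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .episodes import PainStatePolicy, classify, profile
from .io import ResponseMatrix

__all__ = [
    "ProportionEstimate",
    "CohortSummary",
    "wald_ci_percent",
    "wald_ci_from_proportion",
    "ci_nonoverlap",
    "compliance_filter",
    "summarize",
    "missing_context_stat",
    "MAX_RUN_CATEGORIES",
    "MISSINGNESS_CATEGORIES",
]

Z_95 = 1.96

#: Bins for the per-participant maximum zero-run table.
MAX_RUN_CATEGORIES = [str(k) for k in range(9)] + ["9+"]

#: Bins (label, lo, hi inclusive) for the weeks-with-no-response table.
MISSINGNESS_CATEGORIES = [
    ("0", 0, 0),
    ("1-5", 1, 5),
    ("6-10", 6, 10),
    ("11-26", 11, 26),
    ("27+", 27, math.inf),
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion as percent with integer 95% CI bounds.

    ``defined`` is False for the degenerate zero-denominator case; all other
    fields are then meaningless and consumers must check the flag.
    """

    numerator: int
    denominator: int
    percent: float
    ci_low_pct: int
    ci_high_pct: int
    defined: bool = True

    @classmethod
    def undefined(cls) -> "ProportionEstimate":
        return cls(0, 0, float("nan"), 0, 0, defined=False)

    def to_dict(self) -> dict:
        if not self.defined:
            return {"defined": False}
        return {
            "defined": True,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "percent": self.percent,
            "ci_low_pct": self.ci_low_pct,
            "ci_high_pct": self.ci_high_pct,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProportionEstimate":
        if not d.get("defined", True):
            return cls.undefined()
        return cls(
            numerator=d["numerator"],
            denominator=d["denominator"],
            percent=d["percent"],
            ci_low_pct=d["ci_low_pct"],
            ci_high_pct=d["ci_high_pct"],
        )

    def __str__(self) -> str:
        if not self.defined:
            return "undefined (n=0)"
        return f"{_round_half_away(self.percent)}% ({self.ci_low_pct}-{self.ci_high_pct})"


def wald_ci_from_proportion(
    p_hat: float, n: int, rounding: str = "nearest"
) -> ProportionEstimate:
    """Wald 95% CI from a proportion ``p_hat`` and sample size ``n``.

    Bounds are ``100 * (p_hat -/+ 1.96*sqrt(p_hat*(1-p_hat)/n))`` clipped to
    [0, 100] and rounded to integer percent.  ``rounding="nearest"`` rounds
    half away from zero; ``"outward"`` widens (floor lower, ceil upper).
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat must be in [0, 1], got {p_hat}")
    if n <= 0:
        return ProportionEstimate.undefined()
    half_width = Z_95 * math.sqrt(p_hat * (1.0 - p_hat) / n)
    low = max(0.0, 100.0 * (p_hat - half_width))
    high = min(100.0, 100.0 * (p_hat + half_width))
    if rounding == "nearest":
        lo, hi = _round_half_away(low), _round_half_away(high)
    elif rounding == "outward":
        lo, hi = int(math.floor(low)), int(math.ceil(high))
    else:
        raise ValueError(f"unknown rounding variant {rounding!r}")
    # integer counts round-trip exactly when p_hat came from counts
    return ProportionEstimate(
        numerator=_round_half_away(p_hat * n),
        denominator=n,
        percent=100.0 * p_hat,
        ci_low_pct=lo,
        ci_high_pct=hi,
    )


def wald_ci_percent(
    numerator: int, denominator: int, rounding: str = "nearest"
) -> ProportionEstimate:
    """Wald 95% CI for a count out of a denominator (see module docstring)."""
    if denominator == 0:
        return ProportionEstimate.undefined()
    if not 0 <= numerator <= denominator:
        raise ValueError(f"need 0 <= numerator <= denominator, got {numerator}/{denominator}")
    est = wald_ci_from_proportion(numerator / denominator, denominator, rounding)
    return ProportionEstimate(
        numerator=numerator,
        denominator=denominator,
        percent=est.percent,
        ci_low_pct=est.ci_low_pct,
        ci_high_pct=est.ci_high_pct,
    )


def ci_nonoverlap(a: ProportionEstimate, b: ProportionEstimate) -> bool:
    """True iff the two 95% CIs are disjoint (the significance heuristic)."""
    if not (a.defined and b.defined):
        raise ValueError("cannot compare undefined estimates")
    return a.ci_high_pct < b.ci_low_pct or b.ci_high_pct < a.ci_low_pct


def compliance_filter(
    matrix: ResponseMatrix, min_response_fraction: float = 0.5
) -> tuple[ResponseMatrix, list[str]]:
    """Drop participants who answered fewer than ``min_response_fraction`` of weeks.

    The boundary is inclusive ("at least 50% of the time"): with 52 study
    weeks, 26 responses are retained and 25 excluded.  Returns the retained
    matrix and the excluded ids, in input order.
    """
    if not 0.0 < min_response_fraction <= 1.0:
        raise ValueError(f"min_response_fraction must be in (0, 1], got {min_response_fraction}")
    if matrix.n_participants == 0:
        return matrix, []
    responded = (~matrix.data.isna()).sum(axis=1) / matrix.study_weeks
    keep = responded >= min_response_fraction
    excluded = [str(i) for i in matrix.data.index[~keep]]
    return ResponseMatrix(matrix.data.loc[keep]), excluded


@dataclass
class CohortSummary:
    """All cohort-level outputs for one matrix under one policy."""

    n_entered: int
    n_analyzed: int
    policy_mode: str
    window: int
    excluded_ids: list[str]
    missingness_table: dict[str, int]
    max_run_table: dict[str, ProportionEstimate]
    prev_any_non_episode: ProportionEstimate
    prev_non_episode_at_end: ProportionEstimate

    def to_dict(self) -> dict:
        return {
            "n_entered": self.n_entered,
            "n_analyzed": self.n_analyzed,
            "policy_mode": self.policy_mode,
            "window": self.window,
            "excluded_ids": list(self.excluded_ids),
            "missingness_table": dict(self.missingness_table),
            "max_run_table": {k: v.to_dict() for k, v in self.max_run_table.items()},
            "prev_any_non_episode": self.prev_any_non_episode.to_dict(),
            "prev_non_episode_at_end": self.prev_non_episode_at_end.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSummary":
        return cls(
            n_entered=d["n_entered"],
            n_analyzed=d["n_analyzed"],
            policy_mode=d["policy_mode"],
            window=d["window"],
            excluded_ids=list(d["excluded_ids"]),
            missingness_table={k: int(v) for k, v in d["missingness_table"].items()},
            max_run_table={
                k: ProportionEstimate.from_dict(v) for k, v in d["max_run_table"].items()
            },
            prev_any_non_episode=ProportionEstimate.from_dict(d["prev_any_non_episode"]),
            prev_non_episode_at_end=ProportionEstimate.from_dict(d["prev_non_episode_at_end"]),
        )


def _max_run_category(run: int) -> str:
    return str(run) if run < 9 else "9+"


def _missingness_category(n_missing: int) -> str:
    for label, lo, hi in MISSINGNESS_CATEGORIES:
        if lo <= n_missing <= hi:
            return label
    raise AssertionError("unreachable")


def summarize(
    matrix: ResponseMatrix,
    policy: PainStatePolicy,
    min_response_fraction: float = 0.5,
    rounding: str = "nearest",
) -> CohortSummary:
    """Run the whole cohort analysis: filter, profile, bin, estimate.

    Applies the compliance filter, computes each retained participant's
    episode profile under ``policy``, bins maximum zero-runs into categories
    0..8 and "9+", bins missing-week counts, and attaches Wald estimates to
    every category and to both non-episode prevalences.  When every
    participant is filtered out, all estimates are undefined markers.
    """
    analyzed, excluded = compliance_filter(matrix, min_response_fraction)
    n_analyzed = analyzed.n_participants

    run_counts = {label: 0 for label in MAX_RUN_CATEGORIES}
    missing_counts = {label: 0 for label, _, _ in MISSINGNESS_CATEGORIES}
    n_any = 0
    n_end = 0
    for series in analyzed:
        prof = profile(series, policy)
        run_counts[_max_run_category(prof.max_zero_run)] += 1
        missing_counts[_missingness_category(series.n_missing)] += 1
        n_any += prof.has_non_episode
        n_end += prof.non_episode_at_end

    if n_analyzed == 0:
        run_table = {label: ProportionEstimate.undefined() for label in MAX_RUN_CATEGORIES}
        prev_any = prev_end = ProportionEstimate.undefined()
    else:
        run_table = {
            label: wald_ci_percent(count, n_analyzed, rounding)
            for label, count in run_counts.items()
        }
        prev_any = wald_ci_percent(n_any, n_analyzed, rounding)
        prev_end = wald_ci_percent(n_end, n_analyzed, rounding)

    return CohortSummary(
        n_entered=matrix.n_participants,
        n_analyzed=n_analyzed,
        policy_mode=policy.mode.value,
        window=policy.window,
        excluded_ids=excluded,
        missingness_table=missing_counts,
        max_run_table=run_table,
        prev_any_non_episode=prev_any,
        prev_non_episode_at_end=prev_end,
    )


def missing_context_stat(matrix: ResponseMatrix) -> float | None:
    """Fraction of missing cells whose nearest responded neighbours are all pain weeks.

    For each missing cell, the nearest responded week on each side (where one
    exists) is inspected; the cell counts as "pain-surrounded" when every
    such neighbour reported 1-7 days of pain.  Cells with no responded
    neighbour at all are excluded from the denominator.  Returns None when
    the matrix has no eligible missing cell.

    This quantifies the informal observation that non-response clusters
    around pain weeks, i.e. that missing data are more likely to hide pain
    than pain-free weeks.
    """
    eligible = 0
    pain_surrounded = 0
    for series in matrix:
        resp = series.responses
        responded_idx = np.flatnonzero(series.responded)
        if responded_idx.size == 0:
            continue
        for i in np.flatnonzero(~series.responded):
            left = responded_idx[responded_idx < i]
            right = responded_idx[responded_idx > i]
            neighbours = []
            if left.size:
                neighbours.append(resp[left[-1]])
            if right.size:
                neighbours.append(resp[right[0]])
            if not neighbours:
                continue
            eligible += 1
            if all(v > 0 for v in neighbours):
                pain_surrounded += 1
    if eligible == 0:
        return None
    return pain_surrounded / eligible
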