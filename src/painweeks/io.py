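"""Reading, validating and writing the participants x weeks response matrix.

The canonical on-disk form is a wide CSV with header
``participant_id,week_1,...,week_N``.  Each cell holds the number of days
(0-7) with bothersome low-back pain in the preceding week, or is empty when
the participant did not respond that week.  Week indexing is 1-based in every
public contract ("week 1" is the first study week).

Out-of-range or non-numeric cells are coerced to missing -- the diary
protocol only admits integers 0-7, so anything else is an entry error, not a
pain report.  Every coercion is recorded in a :class:`ValidationReport` so
data-quality problems stay visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantSeries",
    "ResponseMatrix",
    "ValidationReport",
    "ValidationWarning",
    "read_response_csv",
    "write_response_csv",
    "write_report",
    "read_report",
]

#: Inclusive bounds of a valid weekly response (days with LBP in the week).
RESPONSE_MIN, RESPONSE_MAX = 0, 7


@dataclass(frozen=True)
class ParticipantSeries:
    """One participant's ordered weekly responses over the study horizon.

    ``responses`` is a float array of length ``study_weeks``; valid entries
    are integers 0-7 stored as floats, missing weeks are ``nan``.
    """

    participant_id: str
    responses: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "responses", arr)
        present = arr[~np.isnan(arr)]
        if present.size and (
            (present < RESPONSE_MIN).any()
            or (present > RESPONSE_MAX).any()
            or (present != np.round(present)).any()
        ):
            raise ValueError(
                f"participant {self.participant_id!r}: responses must be "
                f"integers in [{RESPONSE_MIN}, {RESPONSE_MAX}] or missing"
            )

    @property
    def study_weeks(self) -> int:
        return self.responses.size

    @property
    def responded(self) -> np.ndarray:
        """Boolean mask, True where an actual response exists."""
        return ~np.isnan(self.responses)

    @property
    def n_responded(self) -> int:
        return int(self.responded.sum())

    @property
    def n_missing(self) -> int:
        return self.study_weeks - self.n_responded


@dataclass(frozen=True)
class ResponseMatrix:
    """A cohort of :class:`ParticipantSeries`, all on the same study horizon.

    Backed by a pandas DataFrame (index = participant id, columns =
    ``week_1..week_N``, float with NaN for missing) so it slots directly into
    pandas-based workflows via :attr:`data`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate participant ids: {dupes}")

    @classmethod
    def from_series(cls, series: list[ParticipantSeries], study_weeks: int | None = None) -> "ResponseMatrix":
        if series:
            weeks = {s.study_weeks for s in series}
            if len(weeks) != 1:
                raise ValueError(f"series have mixed lengths: {sorted(weeks)}")
            n = weeks.pop()
            if study_weeks is not None and study_weeks != n:
                raise ValueError(f"series length {n} != study_weeks {study_weeks}")
        else:
            n = study_weeks if study_weeks is not None else 0
        df = pd.DataFrame(
            [s.responses for s in series],
            index=pd.Index([s.participant_id for s in series], name="participant_id"),
            columns=week_columns(n),
            dtype=float,
        )
        return cls(df)

    @property
    def study_weeks(self) -> int:
        return self.data.shape[1]

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def participant_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def series(self, participant_id: str) -> ParticipantSeries:
        return ParticipantSeries(participant_id, self.data.loc[participant_id].to_numpy(dtype=float))

    def __iter__(self) -> Iterator[ParticipantSeries]:
        for pid, row in zip(self.data.index, self.data.to_numpy(dtype=float)):
            yield ParticipantSeries(str(pid), row)

    def __len__(self) -> int:
        return self.n_participants

    def subset(self, participant_ids: list[str]) -> "ResponseMatrix":
        return ResponseMatrix(self.data.loc[participant_ids])

    def n_missing_per_participant(self) -> pd.Series:
        return self.data.isna().sum(axis=1)


def week_columns(study_weeks: int) -> list[str]:
    return [f"week_{w}" for w in range(1, study_weeks + 1)]


@dataclass(frozen=True)
class ValidationWarning:
    participant_id: str
    week: int  # 1-based
    raw_value: str


@dataclass
class ValidationReport:
    """Record of cells coerced to missing during CSV parsing."""

    warnings: list[ValidationWarning] = field(default_factory=list)

    @property
    def n_coerced(self) -> int:
        return len(self.warnings)


def _parse_cell(raw: object) -> tuple[float, bool]:
    """Return (value, ok).  value is nan for empty/invalid cells."""
    if raw is None:
        return np.nan, True
    text = str(raw).strip()
    if text == "" or text.lower() == "nan":
        return np.nan, True
    try:
        value = float(text)
    except ValueError:
        return np.nan, False
    if value != int(value) or not (RESPONSE_MIN <= value <= RESPONSE_MAX):
        return np.nan, False
    return value, True


def read_response_csv(
    path: str | Path, study_weeks: int | None = None
) -> tuple[ResponseMatrix, ValidationReport]:
    """Read a wide response CSV into a :class:`ResponseMatrix`.

    The first column is the participant id; the remaining columns are the
    weekly responses in week order.  ``study_weeks`` is inferred from the
    header when not given; when given, the file must match it exactly.

    Empty cells become missing.  Cells that are neither empty nor an integer
    in 0-7 are coerced to missing and recorded in the returned
    :class:`ValidationReport`.  Duplicate participant ids and rows of the
    wrong length are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skip_blank_lines=True)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no columns found")
    n_weeks = df.shape[1] - 1
    if study_weeks is not None and n_weeks != study_weeks:
        raise ValueError(
            f"{path}: header has {n_weeks} week columns, expected {study_weeks}"
        )

    report = ValidationReport()
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for _, rec in df.iterrows():
        pid = str(rec.iloc[0]).strip()
        values = np.empty(n_weeks, dtype=float)
        for week, raw in enumerate(rec.iloc[1:], start=1):
            value, ok = _parse_cell(raw)
            values[week - 1] = value
            if not ok:
                report.warnings.append(ValidationWarning(pid, week, str(raw)))
        ids.append(pid)
        rows.append(values)

    seen = set()
    for pid in ids:
        if pid in seen:
            raise ValueError(f"{path}: duplicate participant id {pid!r}")
        seen.add(pid)

    matrix = ResponseMatrix.from_series(
        [ParticipantSeries(pid, row) for pid, row in zip(ids, rows)],
        study_weeks=n_weeks,
    )
    return matrix, report


def write_response_csv(matrix: ResponseMatrix, path: str | Path) -> None:
    """Write a :class:`ResponseMatrix` in the canonical wide-CSV dialect.

    Round-trips losslessly through :func:`read_response_csv` (missing cells
    are written as empty strings, values as bare integers).
    """
    out = matrix.data.copy()
    # integers-as-floats would render "3.0"; format as plain integers
    formatted = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    formatted.index.name = "participant_id"
    formatted.to_csv(path)


def write_report(report: dict, path: str | Path) -> None:
    """Serialize an analysis report (or a single summary dict) as JSON.

    The report is whatever :meth:`painweeks.stats.CohortSummary.to_dict`
    or :func:`painweeks.cli.build_report` produced; JSON keeps it both
    machine-readable and diffable, and :func:`read_report` round-trips it.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with Path(path).open("r", encoding="utf-8") as fh:
        return json.load(fh)
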