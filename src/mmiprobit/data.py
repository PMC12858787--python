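"""Domain types and I/O for long-format MMI score tables.

An MMI (multiple mini-interview) cohort is a long table with one row per
candidate x station encounter.  Each encounter carries four factor labels
(candidate, interviewer, station, day) and one integer ordinal score.  The
default score range is 3..15: three rubric domains each marked on a 5-point
scale and summed.

All labels are opaque strings; anonymisation is the caller's concern.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical factor names, in model order.
FACTORS: tuple[str, ...] = ("candidate", "interviewer", "station", "day")

#: Default CSV header names for :func:`read_scores`.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "candidate": "candidate_id",
    "interviewer": "interviewer_id",
    "station": "station_id",
    "day": "day",
    "score": "score",
}

_RECORD_COLUMNS = ["candidate", "interviewer", "station", "day", "score"]


class MMIDataError(ValueError):
    """Raised when a score table violates a hard invariant.

    Carries the :class:`ValidationReport` describing every violation found,
    so callers can surface row-level diagnostics.
    """

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = [f"row {r}: [{rule}] {msg}" for r, rule, msg in report.errors]
        super().__init__(
            "invalid MMI score table (%d error%s):\n%s"
            % (len(report.errors), "s" if len(report.errors) != 1 else "", "\n".join(lines))
        )


@dataclass(frozen=True)
class CategoryRange:
    """Attainable integer score range ``lo..hi`` (inclusive)."""

    lo: int = 3
    hi: int = 15

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"need lo < hi, got ({self.lo}, {self.hi})")

    @property
    def n_categories(self) -> int:
        return self.hi - self.lo + 1

    @property
    def categories(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    def __contains__(self, score: int) -> bool:
        return self.lo <= score <= self.hi


@dataclass(frozen=True)
class ScoreRecord:
    """One observed encounter: candidate i scored by interviewer j at station k on day t."""

    candidate_id: str
    interviewer_id: str
    station_id: str
    day_id: str
    score: int


@dataclass
class ValidationReport:
    """Outcome of validating a score table.

    ``errors`` are hard invariant violations (the table is unusable);
    ``warnings`` flag structural oddities the model tolerates.  Row numbers
    refer to 1-based data rows (header excluded) where applicable, or 0 for
    table-level findings.
    """

    errors: list[tuple[int, str, str]] = field(default_factory=list)
    warnings: list[tuple[int, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def error(self, row: int, rule: str, message: str) -> None:
        self.errors.append((row, rule, message))

    def warn(self, row: int, message: str) -> None:
        self.warnings.append((row, message))


class MMIDataset:
    """A validated MMI score table with per-factor level registries.

    The registries index the distinct labels of each factor in
    first-appearance order; codes are dense 0-based integers used by the
    model machinery.  Construction enforces the hard invariants (scores in
    range, one score per candidate x station pair).
    """

    def __init__(self, records: pd.DataFrame, score_range: CategoryRange):
        records = records.reset_index(drop=True)[_RECORD_COLUMNS].copy()
        for col in _RECORD_COLUMNS[:-1]:
            records[col] = records[col].astype(str)
        records["score"] = records["score"].astype(np.int64)
        report = _check_hard_invariants(records, score_range)
        if not report.is_valid:
            raise MMIDataError(report)
        self.records = records
        self.range = score_range
        self.levels: dict[str, pd.Index] = {
            f: pd.Index(pd.unique(records[f])) for f in FACTORS
        }
        self.codes: dict[str, np.ndarray] = {
            f: self.levels[f].get_indexer(records[f]).astype(np.int64) for f in FACTORS
        }

    # -- basic protocol ----------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.records)

    def n_levels(self, factor: str) -> int:
        return len(self.levels[factor])

    @property
    def scores(self) -> np.ndarray:
        return self.records["score"].to_numpy()

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MMIDataset):
            return NotImplemented
        return self.range == other.range and self.records.equals(other.records)

    def __repr__(self) -> str:
        return (
            f"MMIDataset({self.n_records} records, "
            + ", ".join(f"{self.n_levels(f)} {f}s" for f in FACTORS)
            + f", scores {self.range.lo}-{self.range.hi})"
        )

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[ScoreRecord], score_range: CategoryRange
    ) -> "MMIDataset":
        rows = [
            (r.candidate_id, r.interviewer_id, r.station_id, r.day_id, r.score)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
        return cls(df, score_range)

    def to_records(self) -> list[ScoreRecord]:
        return [
            ScoreRecord(r.candidate, r.interviewer, r.station, r.day, int(r.score))
            for r in self.records.itertuples(index=False)
        ]


def _check_hard_invariants(df: pd.DataFrame, rng: CategoryRange) -> ValidationReport:
    report = ValidationReport()
    out = (df["score"] < rng.lo) | (df["score"] > rng.hi)
    for i in np.flatnonzero(out.to_numpy()):
        report.error(
            int(i) + 1,
            "score_range",
            f"score {df['score'].iloc[i]} outside [{rng.lo}, {rng.hi}]",
        )
    dup = df.duplicated(subset=["candidate", "station"], keep="first")
    for i in np.flatnonzero(dup.to_numpy()):
        report.error(
            int(i) + 1,
            "duplicate_encounter",
            f"duplicate (candidate, station) pair "
            f"({df['candidate'].iloc[i]!r}, {df['station'].iloc[i]!r})",
        )
    return report


def read_scores(
    path: str | Path,
    score_range: CategoryRange = CategoryRange(),
    column_map: Mapping[str, str] | None = None,
) -> MMIDataset:
    """Read a long-format CSV of MMI scores into a validated dataset.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8, RFC-4180 quoting).
    score_range
        Attainable score range; out-of-range scores abort the load.
    column_map
        Maps the keys ``candidate``, ``interviewer``, ``station``, ``day``,
        ``score`` to header names in the file.  Defaults to
        ``candidate_id, interviewer_id, station_id, day, score``.

    Raises
    ------
    MMIDataError
        With a row-level :class:`ValidationReport` if any score fails to
        parse as an integer, lies outside the range, or a (candidate,
        station) pair is duplicated.
    FileNotFoundError, KeyError
        For a missing file or missing mapped column.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [v for v in cols.values() if v not in raw.columns]
    if missing:
        raise KeyError(f"missing column(s) {missing} in {path}; found {list(raw.columns)}")
    report = ValidationReport()
    score_raw = raw[cols["score"]]
    scores = pd.to_numeric(score_raw, errors="coerce")
    bad = scores.isna() | (scores != scores.round())
    for i in np.flatnonzero(bad.to_numpy()):
        report.error(int(i) + 1, "score_parse", f"non-integer score {score_raw.iloc[i]!r}")
    if not report.is_valid:
        raise MMIDataError(report)
    df = pd.DataFrame(
        {
            "candidate": raw[cols["candidate"]],
            "interviewer": raw[cols["interviewer"]],
            "station": raw[cols["station"]],
            "day": raw[cols["day"]],
            "score": scores.astype(np.int64),
        }
    )
    return MMIDataset(df, score_range)


def write_scores(
    dataset: MMIDataset,
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write a dataset back to CSV; round-trips exactly through :func:`read_scores`."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    header = [cols[k] for k in ("candidate", "interviewer", "station", "day", "score")]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(header)
        for r in dataset.records.itertuples(index=False):
            writer.writerow([r.candidate, r.interviewer, r.station, r.day, int(r.score)])


def validate(dataset: MMIDataset) -> ValidationReport:
    """Validate a dataset and report structural warnings.

    Errors repeat the hard invariants (range, duplicate encounters) for
    datasets built through other routes; warnings flag:

    * candidates seen at fewer stations than the modal station count,
    * interviewers covering multiple stations on the same day,
    * score categories in the range that were never awarded.
    """
    report = _check_hard_invariants(dataset.records, dataset.range)
    df = dataset.records

    per_cand = df.groupby("candidate", sort=False)["station"].nunique()
    modal = int(per_cand.mode().max())  # ties resolve to the larger count
    for cand, k in per_cand.items():
        if k < modal:
            report.warn(0, f"candidate {cand!r} has {k} of {modal} stations")

    multi = df.groupby(["interviewer", "day"], sort=False)["station"].nunique()
    for (ivr, day), k in multi.items():
        if k > 1:
            report.warn(0, f"interviewer {ivr!r} covered {k} stations on day {day!r}")

    seen = set(df["score"].unique())
    for cat in dataset.range.categories:
        if int(cat) not in seen:
            report.warn(0, f"category {cat} unobserved")
    return report
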