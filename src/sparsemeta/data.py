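"""Trial-level 2x2 tables for meta-analysis of binary outcomes.

A meta-analysis dataset is an ordered collection of two-arm trials, each
summarised by the number of events and the number of randomised patients
per arm.  Zero-event arms and double-zero trials are first-class citizens:
they are retained in datasets and enter the binomial likelihood unchanged.
Continuity corrections appear in this module only through
:func:`within_study_variances`, which exists to build empirical
heterogeneity priors, never to patch the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "MetaAnalysisDataset",
    "read_dataset",
    "write_dataset",
    "observed_event_probability",
    "within_study_variances",
    "load_mmn",
    "load_gbs",
]

#: Column names for the (events, non-events) file convention.
_NONEVENT_COLUMNS = [
    "label",
    "events_treatment",
    "nonevents_treatment",
    "events_control",
    "nonevents_control",
]
#: Column names for the (events, arm total) file convention.
_TOTAL_COLUMNS = [
    "label",
    "events_treatment",
    "n_treatment",
    "events_control",
    "n_control",
]


class DatasetValidationError(ValueError):
    """Raised when a trial table violates the 2x2 count constraints."""


@dataclass(frozen=True)
class TrialRecord:
    """One two-arm trial: events ``r`` out of ``n`` patients per arm.

    Parameters
    ----------
    label
        Trial identifier, unique within a dataset.
    r_t, n_t
        Event count and sample size in the treatment arm.
    r_c, n_c
        Event count and sample size in the control arm.
    """

    label: str
    r_t: int
    n_t: int
    r_c: int
    n_c: int

    def __post_init__(self) -> None:
        for name in ("r_t", "n_t", "r_c", "n_c"):
            value = getattr(self, name)
            if not float(value).is_integer():
                raise DatasetValidationError(
                    f"trial {self.label!r}: {name}={value} is not an integer"
                )
            object.__setattr__(self, name, int(value))
        if self.n_t <= 0 or self.n_c <= 0:
            raise DatasetValidationError(
                f"trial {self.label!r}: arm sizes must be positive "
                f"(n_t={self.n_t}, n_c={self.n_c})"
            )
        if not (0 <= self.r_t <= self.n_t) or not (0 <= self.r_c <= self.n_c):
            raise DatasetValidationError(
                f"trial {self.label!r}: event counts must satisfy 0 <= r <= n "
                f"(got {self.r_t}/{self.n_t} and {self.r_c}/{self.n_c})"
            )

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """The four 2x2 cells (a, b, c, d) = (r_t, n_t - r_t, r_c, n_c - r_c)."""
        return (self.r_t, self.n_t - self.r_t, self.r_c, self.n_c - self.r_c)

    @property
    def has_zero_cell(self) -> bool:
        return any(cell == 0 for cell in self.cells)

    def swap_arms(self) -> "TrialRecord":
        """Return the trial with treatment and control labels exchanged."""
        return TrialRecord(self.label, self.r_c, self.n_c, self.r_t, self.n_t)


@dataclass(frozen=True)
class MetaAnalysisDataset:
    """An ordered collection of :class:`TrialRecord` with unique labels."""

    trials: tuple[TrialRecord, ...]
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        trials = tuple(self.trials)
        object.__setattr__(self, "trials", trials)
        if len(trials) < 1:
            raise DatasetValidationError("a dataset needs at least one trial")
        labels = [t.label for t in trials]
        if len(set(labels)) != len(labels):
            raise DatasetValidationError(f"duplicate trial labels in {labels}")

    @property
    def k(self) -> int:
        """Number of trials."""
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    def __len__(self) -> int:
        return self.k

    def swap_arms(self) -> "MetaAnalysisDataset":
        return MetaAnalysisDataset(
            tuple(t.swap_arms() for t in self.trials), name=self.name
        )

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (r_t, n_t, r_c, n_c), one entry per trial."""
        r_t = np.array([t.r_t for t in self.trials], dtype=np.int64)
        n_t = np.array([t.n_t for t in self.trials], dtype=np.int64)
        r_c = np.array([t.r_c for t in self.trials], dtype=np.int64)
        n_c = np.array([t.n_c for t in self.trials], dtype=np.int64)
        return r_t, n_t, r_c, n_c

    def to_frame(self, convention: str = "nonevents") -> pd.DataFrame:
        """Tabular view in either file convention (see :func:`read_dataset`)."""
        if convention == "nonevents":
            rows = [
                (t.label, t.r_t, t.n_t - t.r_t, t.r_c, t.n_c - t.r_c)
                for t in self.trials
            ]
            return pd.DataFrame(rows, columns=_NONEVENT_COLUMNS)
        if convention == "totals":
            rows = [(t.label, t.r_t, t.n_t, t.r_c, t.n_c) for t in self.trials]
            return pd.DataFrame(rows, columns=_TOTAL_COLUMNS)
        raise ValueError(f"unknown convention {convention!r}")


def _dataset_from_frame(frame: pd.DataFrame, name: str, path: str) -> MetaAnalysisDataset:
    columns = [c.strip().lower() for c in frame.columns]
    frame = frame.set_axis(columns, axis=1)
    if set(_NONEVENT_COLUMNS) <= set(columns):
        convention = "nonevents"
    elif set(_TOTAL_COLUMNS) <= set(columns):
        convention = "totals"
    else:
        raise DatasetValidationError(
            f"{path}: header must contain either {_NONEVENT_COLUMNS} or "
            f"{_TOTAL_COLUMNS}; got {columns}"
        )
    trials = []
    for idx, row in frame.iterrows():
        try:
            if convention == "nonevents":
                trial = TrialRecord(
                    label=str(row["label"]),
                    r_t=row["events_treatment"],
                    n_t=row["events_treatment"] + row["nonevents_treatment"],
                    r_c=row["events_control"],
                    n_c=row["events_control"] + row["nonevents_control"],
                )
            else:
                trial = TrialRecord(
                    label=str(row["label"]),
                    r_t=row["events_treatment"],
                    n_t=row["n_treatment"],
                    r_c=row["events_control"],
                    n_c=row["n_control"],
                )
        except (DatasetValidationError, TypeError) as exc:
            raise DatasetValidationError(f"{path}: row {idx}: {exc}") from exc
        trials.append(trial)
    return MetaAnalysisDataset(tuple(trials), name=name)


def read_dataset(path: str | Path, name: str | None = None) -> MetaAnalysisDataset:
    """Read a comma-separated trial table.

    Two header conventions are accepted and auto-detected:

    * ``label, events_treatment, nonevents_treatment, events_control,
      nonevents_control`` — events and non-events per arm (the layout used
      by published forest-plot tables);
    * ``label, events_treatment, n_treatment, events_control, n_control`` —
      events and arm totals.

    Raises
    ------
    DatasetValidationError
        On a malformed header, non-integer or negative counts, or ``r > n``,
        naming the offending row.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    return _dataset_from_frame(frame, name=name or path.stem, path=str(path))


def write_dataset(
    dataset: MetaAnalysisDataset, path: str | Path, convention: str = "nonevents"
) -> None:
    """Write a dataset as CSV; inverse of :func:`read_dataset`."""
    dataset.to_frame(convention).to_csv(path, index=False)


def observed_event_probability(trial: TrialRecord) -> float:
    """Pooled observed event probability (r_t + r_c) / (n_t + n_c)."""
    return (trial.r_t + trial.r_c) / (trial.n_t + trial.n_c)


def within_study_variances(
    dataset: MetaAnalysisDataset | Iterable[TrialRecord],
    correction: float = 0.5,
) -> np.ndarray:
    """Per-trial log odds ratio variances ``1/a + 1/b + 1/c + 1/d``.

    The constant ``correction`` is added to all four cells of any trial
    with at least one zero cell; trials without zero cells are left
    uncorrected.  These variances serve only to set the scale of empirical
    heterogeneity priors — the hierarchical model itself never uses them.
    """
    if correction < 0:
        raise ValueError("correction must be non-negative")
    trials: Sequence[TrialRecord] = (
        dataset.trials if isinstance(dataset, MetaAnalysisDataset) else tuple(dataset)
    )
    out = np.empty(len(trials), dtype=float)
    for i, trial in enumerate(trials):
        cells = np.asarray(trial.cells, dtype=float)
        if trial.has_zero_cell:
            if correction == 0:
                raise ValueError(
                    f"trial {trial.label!r} has a zero cell; a positive "
                    "continuity correction is required for its variance"
                )
            cells = cells + correction
        out[i] = np.sum(1.0 / cells)
    return out


def _load_fixture(filename: str, name: str) -> MetaAnalysisDataset:
    with resources.as_file(
        resources.files("sparsemeta.datasets").joinpath(filename)
    ) as path:
        return read_dataset(path, name=name)


def load_mmn() -> MetaAnalysisDataset:
    """Multifocal motor neuropathy: 3 trials of intravenous immunoglobulin
    vs placebo, outcome improvement in disability (MRC scale)."""
    return _load_fixture("mmn.csv", "mmn")


def load_gbs() -> MetaAnalysisDataset:
    """Guillain-Barre syndrome: 4 trials of intravenous immunoglobulin vs
    plasma exchange, outcome treatment discontinuation."""
    return _load_fixture("gbs.csv", "gbs")
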