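"""Trial data model for longitudinal HRQoL scores with monotone dropout.

A trial dataset holds one 0-100 dimension score per subject and scheduled
visit, an arm indicator (0 = control, 1 = experimental), and the derived
dropout index ``D`` = index (1-based) of the last visit with an available
score.  Completers have ``D = J``.  Files are long-format CSV with columns
``subject_id, arm, time_months, score``; an empty field or the literal
``NA`` encodes a missing score.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np
import pandas as pd

_LOG = logging.getLogger(__name__)

#: Planned visit times (months) of the emulated trial design: baseline,
#: during treatment (1.25, 3), month 4, then follow-up.
DEFAULT_VISIT_TIMES = (0.0, 1.25, 3.0, 4.0, 6.0, 12.0, 24.0, 36.0)

#: Observed times must match a schedule entry within this tolerance (months);
#: all model design matrices use the planned time, never the observed one.
VISIT_MATCH_TOL = 0.01

LONG_COLUMNS = ("subject_id", "arm", "time_months", "score")


def _round_half_up(x):
    """Round to the nearest integer with halves going up (summary style)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclasses.dataclass(frozen=True)
class VisitSchedule:
    """Planned assessment times in months, strictly increasing, J >= 2."""

    times: tuple
    labels: tuple = None

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        if len(times) < 2:
            raise ValueError("a visit schedule needs at least two visits")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("visit times must be strictly increasing")
        labels = self.labels
        if labels is None:
            labels = tuple(f"V{j}" for j in range(len(times)))
        else:
            labels = tuple(str(x) for x in labels)
            if len(labels) != len(times):
                raise ValueError("labels and times must have equal length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "labels", labels)

    @property
    def J(self) -> int:
        return len(self.times)

    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def match(self, t: float) -> int:
        """Return the 0-based visit index matching time ``t``, or -1."""
        diffs = np.abs(self.times_array() - float(t))
        j = int(np.argmin(diffs))
        return j if diffs[j] <= VISIT_MATCH_TOL else -1


def default_schedule() -> VisitSchedule:
    return VisitSchedule(DEFAULT_VISIT_TIMES)


@dataclasses.dataclass
class TrialDataset:
    """Wide view of a trial: ``scores[i, j]`` is subject i's score at visit j.

    Missing scores are NaN.  Every retained subject must have at least one
    available score (the evaluable intent-to-treat rule); subjects failing it
    are excluded upstream with a logged count.
    """

    ids: np.ndarray
    arm: np.ndarray
    scores: np.ndarray
    schedule: VisitSchedule
    n_excluded: int = 0

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.arm = np.asarray(self.arm, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.ids)
        if self.arm.shape != (n,):
            raise ValueError("arm must be one value per subject")
        if self.scores.shape != (n, self.schedule.J):
            raise ValueError(
                f"scores must be (n_subjects, J) = ({n}, {self.schedule.J})"
            )
        if not np.isin(self.arm, (0, 1)).all():
            raise ValueError("arm indicator must be 0 (control) or 1 (experimental)")
        if n and not np.isfinite(self.scores).any(axis=1).all():
            raise ValueError(
                "every retained subject needs at least one available score"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def observed(self) -> np.ndarray:
        """Boolean availability mask, shape (n, J)."""
        return np.isfinite(self.scores)

    @property
    def dropout_index(self) -> np.ndarray:
        """1-based index D of the last visit with an available score."""
        obs = self.observed
        return self.schedule.J - np.argmax(obs[:, ::-1], axis=1)

    def is_monotone(self) -> bool:
        """True if missing-once-missing-always holds for every subject."""
        obs = self.observed
        counts = obs.sum(axis=1)
        return bool((counts == self.dropout_index).all())

    def subset(self, mask) -> "TrialDataset":
        mask = np.asarray(mask)
        return TrialDataset(
            self.ids[mask], self.arm[mask], self.scores[mask], self.schedule
        )


@dataclasses.dataclass
class MissingnessSummary:
    """Availability per visit x arm and dropout distribution per last visit.

    ``availability`` columns: visit, label, arm, n_available, n_expected,
    compliance_frac, compliance_pct (half-up integer).  ``dropout`` columns:
    dropout_visit (D, 1-based), label, arm, n_dropped, cum_dropout_frac,
    cum_dropout_pct; the D = J row counts completers and repeats the final
    cumulative dropout value.
    """

    availability: pd.DataFrame
    dropout: pd.DataFrame
    arm_totals: dict


def read_long_table(path, schedule: VisitSchedule | None = None) -> TrialDataset:
    """Read a long-format CSV into a :class:`TrialDataset`.

    Empty score fields and the literal ``NA`` parse as missing; any other
    non-numeric score is an error naming the offending row.  Subjects with
    no available score at all are excluded with a logged count.
    """
    schedule = schedule or default_schedule()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")

    n_rows = len(df)
    ids_order: list = []
    seen: dict = {}
    arm_of: dict = {}
    for row_no, (sid, arm_s, t_s, sc_s) in enumerate(
        zip(df["subject_id"], df["arm"], df["time_months"], df["score"]), start=2
    ):
        try:
            arm = int(arm_s)
        except ValueError:
            arm = -1
        if arm not in (0, 1):
            raise ValueError(f"row {row_no}: arm must be 0 or 1, got {arm_s!r}")
        try:
            t = float(t_s)
        except ValueError:
            raise ValueError(f"row {row_no}: unreadable visit time {t_s!r}")
        j = schedule.match(t)
        if j < 0:
            raise ValueError(
                f"row {row_no}: visit time {t} does not match the schedule "
                f"{schedule.times} within +/-{VISIT_MATCH_TOL}"
            )
        sc_s = sc_s.strip()
        if sc_s in ("", "NA"):
            score = np.nan
        else:
            try:
                score = float(sc_s)
            except ValueError:
                raise ValueError(f"row {row_no}: unreadable score {sc_s!r}")
        if sid not in seen:
            seen[sid] = np.full(schedule.J, np.nan)
            seen[sid + "\x00filled"] = np.zeros(schedule.J, dtype=bool)
            ids_order.append(sid)
            arm_of[sid] = arm
        else:
            if arm_of[sid] != arm:
                raise ValueError(f"row {row_no}: subject {sid!r} has conflicting arms")
        filled = seen[sid + "\x00filled"]
        if filled[j]:
            raise ValueError(
                f"row {row_no}: duplicate entry for subject {sid!r} at visit "
                f"{schedule.labels[j]}"
            )
        filled[j] = True
        seen[sid][j] = score

    scores = np.array([seen[s] for s in ids_order], dtype=float)
    arms = np.array([arm_of[s] for s in ids_order], dtype=int)
    ids = np.array(ids_order, dtype=object)
    if n_rows == 0:
        raise ValueError("empty input file")

    evaluable = np.isfinite(scores).any(axis=1)
    n_excluded = int((~evaluable).sum())
    if n_excluded:
        _LOG.warning(
            "excluded %d subject(s) with no available score (not evaluable)",
            n_excluded,
        )
    return TrialDataset(
        ids[evaluable], arms[evaluable], scores[evaluable], schedule, n_excluded
    )


def write_long_table(dataset: TrialDataset, path) -> None:
    """Write a dataset in long format; missing scores are written as ``NA``.

    A write-then-read round trip reproduces scores, arms, and D exactly.
    """
    rows = []
    times = dataset.schedule.times
    for i in range(dataset.n_subjects):
        for j, t in enumerate(times):
            s = dataset.scores[i, j]
            rows.append(
                (
                    dataset.ids[i],
                    dataset.arm[i],
                    repr(float(t)),
                    "NA" if not np.isfinite(s) else repr(float(s)),
                )
            )
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, index=False)


def monotonize(dataset: TrialDataset, policy: str = "truncate_at_first_gap") -> TrialDataset:
    """Force a strictly monotone missingness pattern.

    ``truncate_at_first_gap`` blanks every score after a subject's first
    internal gap and recomputes D; ``keep`` returns the dataset unchanged.
    The selection-model likelihood is defined for monotone dropout only, so
    intermittent gaps must be resolved (this policy is the package's explicit
    stand-in for a step the dropout models do not define).
    """
    if policy == "keep":
        return dataset
    if policy != "truncate_at_first_gap":
        raise ValueError(f"unknown policy {policy!r}")
    obs = dataset.observed
    scores = dataset.scores.copy()
    for i in range(dataset.n_subjects):
        row = obs[i]
        gap = np.flatnonzero(~row)
        if gap.size:
            scores[i, gap[0]:] = np.nan
    return TrialDataset(dataset.ids, dataset.arm, scores, dataset.schedule,
                        dataset.n_excluded)


def summarize_missingness(dataset: TrialDataset) -> MissingnessSummary:
    """Per-arm availability by visit and dropout distribution by last visit."""
    if dataset.n_subjects == 0:
        raise ValueError("cannot summarize an empty dataset")
    J = dataset.schedule.J
    obs = dataset.observed
    D = dataset.dropout_index
    avail_rows = []
    drop_rows = []
    arm_totals = {}
    for arm in (0, 1):
        mask = dataset.arm == arm
        n_arm = int(mask.sum())
        arm_totals[arm] = n_arm
        if n_arm == 0:
            continue
        for j in range(J):
            n_av = int(obs[mask, j].sum())
            frac = n_av / n_arm
            avail_rows.append(
                (j, dataset.schedule.labels[j], arm, n_av, n_arm, frac,
                 int(_round_half_up(100 * frac)))
            )
        cum = 0
        for d in range(1, J + 1):
            n_d = int((D[mask] == d).sum())
            if d < J:
                cum += n_d
            frac = cum / n_arm
            drop_rows.append(
                (d, dataset.schedule.labels[d - 1], arm, n_d, frac,
                 int(_round_half_up(100 * frac)))
            )
    availability = pd.DataFrame(
        avail_rows,
        columns=["visit", "label", "arm", "n_available", "n_expected",
                 "compliance_frac", "compliance_pct"],
    )
    dropout = pd.DataFrame(
        drop_rows,
        columns=["dropout_visit", "label", "arm", "n_dropped",
                 "cum_dropout_frac", "cum_dropout_pct"],
    )
    return MissingnessSummary(availability, dropout, arm_totals)


def dataset_from_records(records: Iterable[tuple], schedule: VisitSchedule | None = None,
                         ) -> TrialDataset:
    """Build a dataset from ``(id, arm, scores)`` tuples (scores length J, NaN
    for missing).  Convenience constructor used by tests and scripts."""
    schedule = schedule or default_schedule()
    ids, arms, scores = [], [], []
    for sid, arm, sc in records:
        ids.append(sid)
        arms.append(arm)
        scores.append(sc)
    return TrialDataset(np.array(ids, dtype=object), np.array(arms, dtype=int),
                        np.array(scores, dtype=float), schedule)
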