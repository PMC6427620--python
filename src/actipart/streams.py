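"""Label streams, runs, bouts, wear-time validation and partitioning indices.

A :class:`BehaviorStream` is a per-subject sequence of fixed-length epochs,
each labeled with one of five behaviors — lying, sitting, standing, light
physical activity (LPA), moderate-to-vigorous physical activity (MVPA) —
or NONWEAR.  Partitioning indices are computed for three behavior
class-sets: sedentary (SB = lying + sitting), non-sedentary
(NSB = standing + LPA + MVPA) and MVPA alone.

Conventions: epochs are 0-based with half-open extents [start, start+n);
runs and bouts never cross a day boundary (each day is a separate
observation window); NONWEAR breaks runs and counts as off-target time
inside a candidate bout window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import close

BEHAVIORS = ("LIE", "SIT", "STAND", "LPA", "MVPA")
NONWEAR = "NONWEAR"
ALPHABET = BEHAVIORS + (NONWEAR,)

CLASS_SETS = {
    "SB": frozenset({"LIE", "SIT"}),
    "NSB": frozenset({"STAND", "LPA", "MVPA"}),
    "MVPA": frozenset({"MVPA"}),
}

__all__ = [
    "BEHAVIORS",
    "NONWEAR",
    "ALPHABET",
    "CLASS_SETS",
    "BehaviorStream",
    "Run",
    "Bout",
    "PartitioningIndices",
    "WearReport",
    "run_length_encode",
    "validate_wear",
    "behavior_composition",
    "detect_bouts",
    "gini_index",
    "partitioning_indices",
    "read_epoch_csv",
    "read_events_csv",
    "write_epoch_csv",
    "write_events_csv",
]


@dataclass
class BehaviorStream:
    """Per-epoch labeled time series for one subject."""

    subject_id: str
    epoch_length_s: float
    labels: np.ndarray  # array of str, one per epoch
    day_index: np.ndarray  # int day number per epoch, nondecreasing

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        self.day_index = np.asarray(self.day_index, dtype=int)
        if self.labels.size == 0:
            raise ValueError("stream must contain at least one epoch")
        if self.labels.size != self.day_index.size:
            raise ValueError("labels and day_index must have equal length")
        bad = set(self.labels) - set(ALPHABET)
        if bad:
            raise ValueError(f"unknown label(s): {sorted(bad)}")
        if np.any(np.diff(self.day_index) < 0):
            raise ValueError("day_index must be nondecreasing")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def days(self) -> np.ndarray:
        return np.unique(self.day_index)


@dataclass(frozen=True)
class Run:
    """A maximal same-label sequence within one day."""

    label: str
    start_epoch: int
    n_epochs: int
    duration_s: float
    day_index: int


@dataclass(frozen=True)
class Bout:
    """A window dominated by a target class-set.

    The window starts and ends on in-target epochs, the target class-set
    occupies at least the purity threshold of the window, and the window
    is at least the minimum bout length.
    """

    class_set: frozenset
    start_epoch: int
    n_epochs: int
    duration_s: float
    target_fraction: float
    day_index: int


@dataclass(frozen=True)
class PartitioningIndices:
    """Per-subject partitioning indices for one behavior class-set.

    median_bout_min is NaN when the subject has no bout of that class-set.
    """

    median_bout_min: float
    gini: float
    ratio_bout_total: float


@dataclass
class WearReport:
    subject_id: str
    day_wear_hours: dict
    valid_days: list
    invalid_days: list
    subject_valid: bool


def run_length_encode(stream: BehaviorStream, class_set=None) -> list[Run]:
    """Maximal runs of equal label (or of class-set membership), split at
    day boundaries.

    With ``class_set`` given, labels are first collapsed to in/out of the
    set and only in-set runs are returned; the run's ``label`` is then the
    sorted, '+'-joined set name.  Concatenating the plain runs reproduces
    the stream exactly.
    """
    labels = stream.labels
    days = stream.day_index
    n = labels.size
    if class_set is not None:
        member = np.fromiter((l in class_set for l in labels), bool, count=n)
        keys = member.astype(int)
        run_label = "+".join(sorted(class_set))
    else:
        keys = labels

    runs: list[Run] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or not (np.all(keys[i] == keys[start]) and days[i] == days[start]):
            if class_set is None or member[start]:
                runs.append(
                    Run(
                        label=labels[start] if class_set is None else run_label,
                        start_epoch=start,
                        n_epochs=i - start,
                        duration_s=(i - start) * stream.epoch_length_s,
                        day_index=int(days[start]),
                    )
                )
            start = i
    return runs


def validate_wear(
    stream: BehaviorStream,
    min_day_hours: float = 10.0,
    min_valid_days: int = 4,
) -> tuple[BehaviorStream | None, WearReport]:
    """Drop days with insufficient wear; flag subjects with too few valid days.

    A day is invalid when its wear time (non-NONWEAR epochs) is strictly
    less than ``min_day_hours``; a subject is invalid when strictly fewer
    than ``min_valid_days`` days remain.  Returns the filtered stream
    (None when no valid day survives) and a per-day report.
    """
    wear = stream.labels != NONWEAR
    day_hours = {}
    valid_days, invalid_days = [], []
    for d in stream.days:
        mask = stream.day_index == d
        hours = wear[mask].sum() * stream.epoch_length_s / 3600.0
        day_hours[int(d)] = hours
        (valid_days if hours >= min_day_hours else invalid_days).append(int(d))

    report = WearReport(
        subject_id=stream.subject_id,
        day_wear_hours=day_hours,
        valid_days=valid_days,
        invalid_days=invalid_days,
        subject_valid=len(valid_days) >= min_valid_days,
    )
    if not valid_days:
        return None, report
    keep = np.isin(stream.day_index, valid_days)
    filtered = BehaviorStream(
        subject_id=stream.subject_id,
        epoch_length_s=stream.epoch_length_s,
        labels=stream.labels[keep],
        day_index=stream.day_index[keep],
    )
    return filtered, report


def behavior_composition(stream: BehaviorStream) -> np.ndarray:
    """Five-part wear-time composition (LIE, SIT, STAND, LPA, MVPA).

    Proportions of wear epochs; parts may be zero (apply the zero policy
    before log-ratio modelling).
    """
    wear = stream.labels[stream.labels != NONWEAR]
    if wear.size == 0:
        raise ValueError("stream has no wear epochs")
    counts = np.array([(wear == b).sum() for b in BEHAVIORS], dtype=float)
    return close(counts)


def detect_bouts(
    stream: BehaviorStream,
    class_set,
    min_bout_s: float = 60.0,
    purity: float = 0.8,
) -> list[Bout]:
    """Greedy left-to-right bout detection.

    A candidate opens at an in-target epoch and extends epoch by epoch
    while the cumulative target fraction of the window stays at or above
    ``purity`` (stopping at a day boundary); the window is then trimmed
    back to its last in-target epoch and emitted if the trimmed duration
    is at least ``min_bout_s``.  The scan resumes after an emitted bout,
    or at the epoch after a failed candidate's start.  Bouts of one
    class-set never overlap.
    """
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must be in (0.5, 1]")
    if min_bout_s < stream.epoch_length_s:
        raise ValueError("min_bout_s must be at least one epoch length")
    class_set = frozenset(class_set)

    labels = stream.labels
    days = stream.day_index
    n = labels.size
    member = np.fromiter((l in class_set for l in labels), bool, count=n)

    bouts: list[Bout] = []
    i = 0
    while i < n:
        if not member[i]:
            i += 1
            continue
        day = days[i]
        n_target = 0
        j = i
        last_target = i
        while j < n and days[j] == day:
            n_target_next = n_target + int(member[j])
            if n_target_next / (j - i + 1) < purity:
                break
            n_target = n_target_next
            if member[j]:
                last_target = j
            j += 1
        # trim back to last in-target epoch
        end = last_target + 1
        n_epochs = end - i
        n_target_trimmed = int(member[i:end].sum())
        duration = n_epochs * stream.epoch_length_s
        if duration >= min_bout_s:
            bouts.append(
                Bout(
                    class_set=class_set,
                    start_epoch=i,
                    n_epochs=n_epochs,
                    duration_s=duration,
                    target_fraction=n_target_trimmed / n_epochs,
                    day_index=int(day),
                )
            )
            i = end
        else:
            i += 1
    return bouts


def gini_index(durations) -> float:
    """Gini index of a duration distribution.

    G = sum_ij |d_i - d_j| / (2 n^2 mean(d)); equals twice the area
    between the diagonal and the Lorenz curve of cumulative time share
    versus cumulative sequence share (sequences sorted ascending).
    Bounded by (n-1)/n; 0 for a single or all-equal durations.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one duration")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    d = np.sort(d)
    n = d.size
    # O(n log n) equivalent of the pairwise formula
    cum = np.cumsum(d)
    return float((2.0 * np.arange(1, n + 1) - n - 1) @ d / (n * cum[-1]))


def partitioning_indices(
    stream: BehaviorStream,
    class_set,
    min_bout_s: float = 60.0,
    purity: float = 0.8,
) -> PartitioningIndices:
    """Median bout length (minutes), Gini of class-set run durations, and
    the ratio of class-set time inside bouts to total class-set time.

    The Gini is taken over ALL class-set runs — bouts and sporadic
    sequences alike.  With zero bouts the median is NaN and the ratio 0.
    """
    class_set = frozenset(class_set)
    runs = run_length_encode(stream, class_set=class_set)
    if not runs:
        raise ValueError("stream contains no epochs of the class set")
    total_s = sum(r.duration_s for r in runs)

    bouts = detect_bouts(stream, class_set, min_bout_s=min_bout_s, purity=purity)
    member = np.fromiter((l in class_set for l in stream.labels), bool, count=len(stream))
    in_bout_s = sum(
        member[b.start_epoch : b.start_epoch + b.n_epochs].sum() * stream.epoch_length_s
        for b in bouts
    )

    median_min = (
        float(np.median([b.duration_s for b in bouts]) / 60.0) if bouts else float("nan")
    )
    return PartitioningIndices(
        median_bout_min=median_min,
        gini=gini_index([r.duration_s for r in runs]),
        ratio_bout_total=in_bout_s / total_s,
    )


# ---------------------------------------------------------------------------
# CSV I/O


def read_epoch_csv(path, epoch_length_s: float) -> list[BehaviorStream]:
    """Read an epoch CSV (subject_id, day_index, epoch_index, label) into
    one stream per subject, ordered by (day_index, epoch_index)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "day_index", "epoch_index", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"epoch CSV must have columns {sorted(required)}")
    streams = []
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values(["day_index", "epoch_index"])
        streams.append(
            BehaviorStream(
                subject_id=str(sid),
                epoch_length_s=epoch_length_s,
                labels=g["label"].to_numpy(dtype=object),
                day_index=g["day_index"].to_numpy(dtype=int),
            )
        )
    return streams


def read_events_csv(path, epoch_length_s: float) -> list[BehaviorStream]:
    """Read an events CSV (subject_id, day_index, start_s, duration_s, label)
    and expand each event into whole epochs (durations rounded to the
    nearest epoch, minimum one)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "day_index", "start_s", "duration_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"events CSV must have columns {sorted(required)}")
    streams = []
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values(["day_index", "start_s"])
        labels, days = [], []
        for _, row in g.iterrows():
            n = max(1, int(round(row["duration_s"] / epoch_length_s)))
            labels.extend([row["label"]] * n)
            days.extend([int(row["day_index"])] * n)
        streams.append(
            BehaviorStream(
                subject_id=str(sid),
                epoch_length_s=epoch_length_s,
                labels=np.array(labels, dtype=object),
                day_index=np.array(days, dtype=int),
            )
        )
    return streams


def write_events_csv(path, streams) -> None:
    """Write streams as events (subject_id, day_index, start_s, duration_s,
    label), one row per run; start_s is seconds from the start of the day."""
    rows = []
    for s in streams:
        day_start = {int(d): int(np.argmax(s.day_index == d)) for d in s.days}
        for r in run_length_encode(s):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "day_index": r.day_index,
                    "start_s": (r.start_epoch - day_start[r.day_index]) * s.epoch_length_s,
                    "duration_s": r.duration_s,
                    "label": r.label,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_epoch_csv(path, streams) -> None:
    frames = []
    for s in streams:
        epoch_in_day = np.zeros(len(s), dtype=int)
        for d in s.days:
            mask = s.day_index == d
            epoch_in_day[mask] = np.arange(mask.sum())
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "day_index": s.day_index,
                    "epoch_index": epoch_in_day,
                    "label": s.labels,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
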