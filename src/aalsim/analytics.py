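"""Evaluation and data-analysis layer.

Mirrors the deployment's evaluation methodology: classify context events
into *atomic* (tap use, shower use, location changes) and *complex*
(detected deviances and service provisions), compare system context with
the caregivers' hourly log-sheets on a weekly patient-hour grid, summarise
crash records into uptime statistics, build chronological activity
heatmaps, flag deterioration in daily reminder counts, and train the
next-hour activity predictor (bagged decision trees with vote-entropy
active learning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .simulate import LogSheetRow

__all__ = [
    "EventClassification",
    "MatchReport",
    "HeatmapMatrix",
    "DeteriorationReport",
    "PredictionModel",
    "classify_events",
    "matching_rate",
    "uptime_stats",
    "build_heatmap",
    "detect_deterioration",
    "hourly_labels_from_sheets",
    "train_predictor",
    "predict",
    "active_learn",
    "NoOverlapError",
    "SeriesTooShortError",
    "EmptyPeriodError",
    "DegenerateLabelsError",
]

LABELS = ("bathroom", "common area", "room")

_SHEET_CLASS = {
    "Bathroom": "bathroom",
    "Common area": "common area",
    "Dining area": "common area",
    "Bedroom": "room",
    "Other": "away",
}


class NoOverlapError(ValueError):
    pass


class SeriesTooShortError(ValueError):
    pass


class EmptyPeriodError(ValueError):
    pass


class DegenerateLabelsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# event classification

@dataclass
class EventClassification:
    per_day: pd.DataFrame     # columns: day, tap_uses, shower_uses, location_changes, detections, provisions, atomic, complex

    @property
    def mean_atomic_per_day(self) -> float:
        return float(self.per_day["atomic"].mean())

    @property
    def mean_complex_per_day(self) -> float:
        return float(self.per_day["complex"].mean())


def classify_events(run_logs: Iterable) -> EventClassification:
    """Per-day atomic/complex tallies from reasoning-run logs.

    Atomic events are low-level context occurrences the platform extracted:
    tap-use and shower-use episodes plus believed-location changes.
    Complex events are detected deviances plus service provisions (episodes
    for which at least one action was emitted).
    """
    rows = []
    for log in run_logs:
        rows.append(
            {
                "day": log.day,
                "tap_uses": log.tap_uses,
                "shower_uses": log.shower_uses,
                "location_changes": log.location_changes,
                "detections": len(log.detections),
                "provisions": log.provisions,
            }
        )
    df = pd.DataFrame(rows, columns=["day", "tap_uses", "shower_uses", "location_changes", "detections", "provisions"])
    df["atomic"] = df[["tap_uses", "shower_uses", "location_changes"]].sum(axis=1)
    df["complex"] = df[["detections", "provisions"]].sum(axis=1)
    return EventClassification(df)


# ---------------------------------------------------------------------------
# matching rate

_DEVIANCE_FIELDS = ("shower_too_long", "tap_left_on", "forgot_flush", "wandered")


@dataclass
class MatchReport:
    week: int
    comparisons: int
    matches: int
    per_category: dict[str, tuple[int, int]]   # category -> (matches, comparisons)

    @property
    def rate(self) -> float:
        return 100.0 * self.matches / self.comparisons


def matching_rate(system_rows: Sequence[LogSheetRow], sheet_rows: Sequence[LogSheetRow], week: int = 0) -> MatchReport:
    """Agreement between system-inferred context and caregiver sheets.

    Both sides are hourly patient grids (the only granularity the two data
    sources share).  Each (patient, day, hour) cell contributes one
    location comparison and one comparison per deviance flag; the rate is
    100 x matches / comparisons over the week.
    """
    sysidx = {(r.date, r.patient, r.hour): r for r in system_rows}
    cats: dict[str, list[int]] = {c: [0, 0] for c in ("location",) + _DEVIANCE_FIELDS}
    matches = comparisons = 0
    for sheet in sheet_rows:
        sys_row = sysidx.get((sheet.date, sheet.patient, sheet.hour))
        if sys_row is None:
            continue
        pairs = [("location", sys_row.location == sheet.location)]
        pairs += [(f, getattr(sys_row, f) == getattr(sheet, f)) for f in _DEVIANCE_FIELDS]
        for cat, ok in pairs:
            cats[cat][1] += 1
            cats[cat][0] += int(ok)
            comparisons += 1
            matches += int(ok)
    if comparisons == 0:
        raise NoOverlapError("no overlapping patient-hours between system log and sheets")
    return MatchReport(week, comparisons, matches, {c: (m, n) for c, (m, n) in cats.items()})


# ---------------------------------------------------------------------------
# uptime

def uptime_stats(crash_times_days: Sequence[float], period_days: float) -> dict:
    """Mean days between failures over a period (and the crash count).

    With no crashes the mean interval is the whole period.  Crash times are
    in days from the period start, time-sorted.
    """
    ts = list(crash_times_days)
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("crash records must be time-sorted")
    if not ts:
        return {"mean_uptime_days": float(period_days), "crashes": 0}
    intervals = np.diff([0.0] + ts)
    return {"mean_uptime_days": float(np.mean(intervals)), "crashes": len(ts)}


# ---------------------------------------------------------------------------
# chronological heatmaps

@dataclass
class HeatmapMatrix:
    """days x 24 x class densities; densities in [0, 1], summing to <= 1."""

    days: list[int]
    classes: tuple[str, ...]
    cells: np.ndarray          # shape (len(days), 24, len(classes))

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, d in enumerate(self.days):
            for h in range(24):
                rec = {"day": d, "hour": h}
                rec.update({c: self.cells[i, h, j] for j, c in enumerate(self.classes)})
                recs.append(rec)
        return pd.DataFrame(recs)


def build_heatmap(
    source: str,
    *,
    patient: str,
    sheet_rows: Optional[Sequence[LogSheetRow]] = None,
    events_by_day: Optional[dict[int, Sequence]] = None,
    context_by_day: Optional[dict[int, Sequence[tuple]]] = None,
    bed_sensor: Optional[str] = None,
) -> HeatmapMatrix:
    """Chronological activity heatmap for one patient.

    ``source="logsheets"`` uses the caregiver sheets (ground truth): each
    hour cell carries density 1 for its recorded class, with days the
    patient was away (location "Other" all day) rendered as the distinct
    ``away`` class.  ``source="sensors"`` maps sensor firings per the
    system-log convention — washroom vibration+motion time to ``bathroom``,
    bed-pressure time to ``room`` — with the patient's attributed washroom
    intervals taken from the reasoning context log.
    """
    classes = ("bathroom", "common area", "room", "away")
    if source == "logsheets":
        if not sheet_rows:
            raise EmptyPeriodError("no sheet rows in period")
        rows = [r for r in sheet_rows if r.patient == patient]
        if not rows:
            raise EmptyPeriodError(f"no rows for {patient}")
        days = sorted({r.date for r in rows})
        cells = np.zeros((len(days), 24, len(classes)))
        for r in rows:
            cls = _SHEET_CLASS.get(r.location, "away")
            cells[days.index(r.date), r.hour, classes.index(cls)] = 1.0
        return HeatmapMatrix(days, classes, cells)

    if source == "sensors":
        if context_by_day is None:
            raise EmptyPeriodError("sensor heatmap needs context intervals")
        days = sorted(context_by_day)
        if not days:
            raise EmptyPeriodError("no days in period")
        cells = np.zeros((len(days), 24, len(classes)))
        for i, d in enumerate(days):
            spans = [(loc, a, b) for (p, loc, a, b) in context_by_day[d] if p == patient]
            if not spans:
                cells[i, :, classes.index("away")] = 1.0
                continue
            for loc, a, b in spans:
                cls = {"washroom": "bathroom", "bedroom": "room", "commonArea": "common area"}.get(loc)
                if cls is None:
                    continue
                h0, h1 = int(a // 3600), min(24, int(math.ceil(b / 3600)))
                for h in range(h0, h1):
                    lo, hi = h * 3600.0, (h + 1) * 3600.0
                    cells[i, h, classes.index(cls)] += max(0.0, min(b, hi) - max(a, lo)) / 3600.0
        np.clip(cells, 0.0, 1.0, out=cells)
        return HeatmapMatrix(days, classes, cells)

    raise ValueError(f"unknown source {source!r}")


# ---------------------------------------------------------------------------
# deterioration detection

@dataclass
class DeteriorationReport:
    daily_counts: list[float]
    baseline_window: int
    baseline_max: float
    threshold: float
    flagged_days: list[int]

    @property
    def flagged(self) -> Optional[int]:
        return self.flagged_days[0] if self.flagged_days else None


def detect_deterioration(
    daily_counts: Sequence[float],
    baseline_window: int = 14,
    factor: float = 2.0,
    consecutive: int = 2,
) -> DeteriorationReport:
    """Flag a sustained jump in a patient's daily reminder counts.

    A day is flagged when the count exceeds ``factor`` x the maximum of the
    baseline window for at least ``consecutive`` consecutive days; the
    first such day marks the suspected change (e.g. a habitual <6
    reminders/day stepping up to ~12 when the patient's condition worsens).
    """
    counts = list(daily_counts)
    if len(counts) <= baseline_window:
        raise SeriesTooShortError(
            f"series length {len(counts)} must exceed baseline window {baseline_window}"
        )
    baseline_max = max(counts[:baseline_window])
    threshold = factor * baseline_max
    flagged = []
    run = 0
    for i in range(baseline_window, len(counts)):
        if counts[i] > threshold:
            run += 1
            if run >= consecutive:
                flagged.append(i - run + 1)
                run = -10**9  # only the episode's first day is reported
        else:
            run = 0
    return DeteriorationReport(counts, baseline_window, baseline_max, threshold, flagged)


# ---------------------------------------------------------------------------
# next-hour activity prediction

@dataclass
class PredictionModel:
    trees: list[DecisionTreeClassifier]
    classes: tuple[str, ...]
    history: int                       # previous hourly activities used
    n_features: int = 0

#: Features drawn per split and bootstrap-bag fraction.  Random-subspace
#: splits and half-size bags keep the committee diverse, which the
#: vote-entropy query strategy depends on; majority voting over 25 trees
#: restores the accuracy individual trees give up.
MAX_FEATURES = 2
BAG_FRACTION = 0.5


def hourly_labels_from_sheets(sheet_rows: Sequence[LogSheetRow], patient: str) -> pd.Series:
    """Chronological hourly activity labels for one patient."""
    rows = sorted((r for r in sheet_rows if r.patient == patient), key=lambda r: (r.date, r.hour))
    idx = [(r.date, r.hour) for r in rows]
    vals = [_SHEET_CLASS.get(r.location, "away") for r in rows]
    vals = [v if v in LABELS else "room" for v in vals]
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["day", "hour"]))


def featurize(labels: Sequence[str], history: int = 3, start: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """(hour-of-day, day-of-week, previous ``history`` activities) -> next activity.

    ``start`` is the absolute hour index of ``labels[0]`` (so slices taken
    mid-stream keep their hour-of-day and day-of-week alignment).
    """
    codes = np.array([LABELS.index(v) for v in labels])
    n = len(codes)
    if n <= history:
        raise DegenerateLabelsError("not enough hours for the feature recipe")
    X, y = [], []
    for i in range(history, n):
        absolute = start + i
        hour = absolute % 24
        dow = (absolute // 24) % 7
        X.append([hour, dow] + list(codes[i - history:i]))
        y.append(codes[i])
    return np.array(X), np.array(y)


def train_predictor(
    labels: Sequence[str],
    *,
    n_trees: int = 25,
    max_depth: int = 6,
    history: int = 3,
    seed: int = 0,
) -> PredictionModel:
    """Bagged random-subspace decision trees over the hourly sequence."""
    X, y = featurize(labels, history)
    return _fit(X, y, n_trees=n_trees, max_depth=max_depth, history=history, seed=seed)


def _fit(X, y, *, n_trees, max_depth, history, seed) -> PredictionModel:
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("need at least two activity classes")
    rng = np.random.default_rng(seed)
    trees = []
    n = len(y)
    bag = max(4, int(n * BAG_FRACTION))
    max_features = min(MAX_FEATURES, X.shape[1])
    for k in range(n_trees):
        idx = rng.integers(0, n, size=bag)
        tree = DecisionTreeClassifier(max_depth=max_depth, max_features=max_features,
                                      random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(X[idx], y[idx])
        trees.append(tree)
    return PredictionModel(trees, LABELS, history, X.shape[1])


def _votes(model: PredictionModel, X: np.ndarray) -> np.ndarray:
    counts = np.zeros((len(X), len(model.classes)))
    for tree in model.trees:
        pred = tree.predict(X)
        for j in range(len(model.classes)):
            counts[:, j] += pred == j
    return counts


def predict(model: PredictionModel, X: np.ndarray) -> np.ndarray:
    """Majority vote over the ensemble; returns label strings."""
    X = np.atleast_2d(np.asarray(X))
    counts = _votes(model, X)
    return np.array([model.classes[j] for j in np.argmax(counts, axis=1)])


def _accuracy(model: PredictionModel, X, y) -> float:
    counts = _votes(model, X)
    return float(np.mean(np.argmax(counts, axis=1) == y))


def active_learn(
    pool_X: np.ndarray,
    pool_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    budget: int,
    *,
    seed: int = 0,
    n_trees: int = 25,
    max_depth: int = 6,
    init: int = 4,
    strategy: str = "entropy",
) -> list[tuple[int, float]]:
    """Pool-based label acquisition; returns the accuracy curve.

    ``strategy="entropy"`` queries the pool item with maximal vote entropy
    (ensemble disagreement); ``strategy="random"`` is the paired baseline.
    The curve holds ``(labelled size, held-out accuracy)`` pairs from the
    seed set (``init``, expanded if needed until two classes are present)
    up to ``budget``.
    """
    if budget > len(pool_y):
        raise ValueError("budget exceeds pool size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool_y))
    init = min(init, len(order))
    labelled = list(order[:init])
    unlabelled = list(order[init:])
    # the seed set must expose at least two classes for a tree to be fitted
    while len(np.unique(pool_y[labelled])) < 2 and unlabelled:
        labelled.append(unlabelled.pop(0))
    curve = []
    while True:
        model = _fit(pool_X[labelled], pool_y[labelled],
                     n_trees=n_trees, max_depth=max_depth, history=0, seed=seed + len(labelled))
        curve.append((len(labelled), _accuracy(model, test_X, test_y)))
        if len(labelled) >= budget or not unlabelled:
            break
        if strategy == "random":
            pick_pos = 0
        else:
            counts = _votes(model, pool_X[unlabelled])
            p = counts / counts.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ent = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
            # maximal vote entropy; ties (e.g. a unanimous ensemble) are
            # broken toward feature vectors not yet in the labelled set,
            # then uniformly at random, so the query never stalls on pool
            # order or re-buys known patterns
            best = np.flatnonzero(ent >= ent.max() - 1e-12)
            if len(best) > 1:
                seen = {tuple(row) for row in pool_X[labelled]}
                novel = [b for b in best if tuple(pool_X[unlabelled[b]]) not in seen]
                if novel:
                    best = np.asarray(novel)
            pick_pos = int(best[rng.integers(len(best))])
        labelled.append(unlabelled.pop(pick_pos))
    return curve
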