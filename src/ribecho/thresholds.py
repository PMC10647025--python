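"""Amplitude-threshold classifiers in the time and frequency domains.

The decision statistic is the maximum of the rectified signal inside a
time window (time domain) or the maximum spectral magnitude inside the
fixed 493.8-931.3 kHz band (frequency domain). A single threshold theta1
separates No Rib from Rib; the ternary task adds a second, higher
threshold theta2 separating Partial Rib from Whole Rib, while theta1 is
frozen from the binary Rib/No-Rib fit on the same cohort.

Thresholds are fitted exactly: the balanced error of the rule
``s >= theta -> positive`` is piecewise constant in theta, so evaluating
midpoints between consecutive distinct statistics (plus one candidate
below the minimum and one above the maximum) covers every achievable
classification. The time window itself is fitted by a coarse-to-fine grid
search with the step halved each round.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError, FittingError
from .preprocess import (ARTIFACT_SPAN, DEFAULT_BAND, FREQ_WINDOW, AlignedTrace,
                         rectified_aligned, align, spectrum, window_bounds)
from .sim import Dataset, RawTrace

NO_RIB, RIB, PARTIAL_RIB, WHOLE_RIB = "no_rib", "rib", "partial_rib", "whole_rib"

#: location -> class label for each task; task 1 drops locations B and D.
TASK_LABELS: dict[int, dict[str, str]] = {
    1: {"A": NO_RIB, "C": WHOLE_RIB, "E": WHOLE_RIB},
    2: {"A": NO_RIB, "B": RIB, "C": RIB, "D": RIB, "E": RIB},
    3: {"A": NO_RIB, "B": PARTIAL_RIB, "D": PARTIAL_RIB,
        "C": WHOLE_RIB, "E": WHOLE_RIB},
}

#: the "positive" class of each binary task (for F1 and threshold fitting).
POSITIVE_CLASS = {1: WHOLE_RIB, 2: RIB}

COHORTS = ("all", "low_bmi", "high_bmi")


def task_classes(task: int) -> tuple[str, ...]:
    """Ordered class list of a task (negative class first)."""
    if task == 1:
        return (NO_RIB, WHOLE_RIB)
    if task == 2:
        return (NO_RIB, RIB)
    if task == 3:
        return (NO_RIB, PARTIAL_RIB, WHOLE_RIB)
    raise ConfigurationError(f"task must be 1, 2 or 3, got {task}")


def trace_label(location: str, task: int) -> str | None:
    """Class label of a location under a task; None if the task drops it."""
    if task not in TASK_LABELS:
        raise ConfigurationError(f"task must be 1, 2 or 3, got {task}")
    return TASK_LABELS[task].get(location)


def select_cohort(dataset: Dataset, cohort: str) -> list[RawTrace]:
    """Traces of one BMI cohort ('all' keeps everything)."""
    if cohort not in COHORTS:
        raise ConfigurationError(f"cohort must be one of {COHORTS}")
    if cohort == "all":
        return list(dataset.traces)
    return [t for t in dataset.traces
            if dataset.participant(t.participant_id).cohort == cohort]


@dataclass
class TimeThresholdModel:
    """Fitted time window plus one or two amplitude thresholds (volts)."""

    task: int
    cohort: str
    window_start_s: float
    window_end_s: float
    theta1: float
    theta2: float | None = None

    def __post_init__(self) -> None:
        if not self.window_end_s > self.window_start_s:
            raise ConfigurationError("window_end must exceed window_start")
        if self.theta2 is not None and not self.theta2 > self.theta1:
            raise ConfigurationError("theta2 must exceed theta1")


@dataclass
class FreqThresholdModel:
    """Fixed spectral band plus one or two magnitude thresholds."""

    task: int
    cohort: str
    band_lo_hz: float = DEFAULT_BAND[0]
    band_hi_hz: float = DEFAULT_BAND[1]
    theta1: float = 0.0
    theta2: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.band_lo_hz < self.band_hi_hz:
            raise ConfigurationError("band must satisfy 0 < lo < hi")
        if self.theta2 is not None and not self.theta2 > self.theta1:
            raise ConfigurationError("theta2 must exceed theta1")


def decision_statistic_time(rectified: AlignedTrace,
                            window: tuple[float, float]) -> float:
    """Maximum of the rectified signal inside the time window (volts)."""
    i0, i1 = window_bounds(window[0], window[1], rectified.sampling_rate,
                           len(rectified.voltage))
    if i1 <= i0:
        raise ConfigurationError("empty decision window")
    return float(np.max(rectified.voltage[i0:i1]))


def decision_statistic_freq(trace_aligned: AlignedTrace,
                            band: tuple[float, float] = DEFAULT_BAND,
                            window: tuple[float, float] = FREQ_WINDOW) -> float:
    """Maximum spectral magnitude within the retained band."""
    spec = spectrum(trace_aligned, window[0], window[1], band[0], band[1])
    return float(np.max(spec.magnitude))


def threshold_candidates(statistics: np.ndarray) -> np.ndarray:
    """Candidate thresholds: midpoints of distinct sorted statistics plus
    one candidate below the minimum and one above the maximum."""
    s = np.unique(np.asarray(statistics, dtype=float))
    mids = (s[:-1] + s[1:]) / 2.0
    return np.concatenate([[s[0] - 1.0], mids, [s[-1] + 1.0]])


def _balanced_errors(statistics: np.ndarray, positive: np.ndarray,
                     thetas: np.ndarray) -> np.ndarray:
    """Balanced error of ``s >= theta -> positive`` for each candidate."""
    pos = np.sort(statistics[positive])
    neg = np.sort(statistics[~positive])
    # fraction of positives below theta (missed) / negatives at/above theta.
    miss = np.searchsorted(pos, thetas, side="left") / pos.size
    false_alarm = 1.0 - np.searchsorted(neg, thetas, side="left") / neg.size
    return 0.5 * (miss + false_alarm)


def fit_threshold(statistics, positive, min_theta: float | None = None,
                  ) -> tuple[float, float]:
    """Exact balanced-error-minimizing threshold.

    Returns ``(theta, balanced_error)``; ties resolve to the smallest
    candidate. ``min_theta`` restricts the search to candidates strictly
    above it (used for the ternary second threshold).
    """
    statistics = np.asarray(statistics, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if statistics.size != positive.size or statistics.size == 0:
        raise DataError("statistics and labels must be equal-length, nonempty")
    if positive.all() or (~positive).all():
        raise FittingError("both classes must be present to fit a threshold")
    thetas = threshold_candidates(statistics)
    if min_theta is not None:
        thetas = thetas[thetas > min_theta]
        if thetas.size == 0:
            raise FittingError(
                f"no feasible threshold above {min_theta}: classes overlap "
                "entirely below the first threshold")
    errors = _balanced_errors(statistics, positive, thetas)
    # ties (equal up to float rounding) resolve to the smallest candidate
    best = int(np.nonzero(errors <= errors.min() + 1e-12)[0][0])
    return float(thetas[best]), float(errors[best])


def _stat_matrix(rectified_traces: list[AlignedTrace]) -> tuple[np.ndarray, float]:
    length = min(len(t.voltage) for t in rectified_traces)
    fs = rectified_traces[0].sampling_rate
    return np.stack([t.voltage[:length] for t in rectified_traces]), length / fs


def fit_time_window(
    rectified_traces: list[AlignedTrace],
    positive,
    init_window: tuple[float, float] | None = None,
    rounds: int = 3,
    init_step: float = 8e-6,
    min_start: float = ARTIFACT_SPAN,
) -> tuple[float, float]:
    """Iterative range reduction of the decision window.

    Round 1 scans every (start, end) pair on an ``init_step`` grid spanning
    [min_start, trace end]; each later round halves the step and explores a
    local neighborhood of the incumbent. The objective is the best
    achievable balanced threshold error for that window; ties prefer the
    shorter, earlier window.
    """
    positive = np.asarray(positive, dtype=bool)
    if init_window is None:
        init_window = (min_start, min(t.duration for t in rectified_traces))
    if rounds == 0:
        return init_window
    matrix, t_max = _stat_matrix(rectified_traces)
    fs = rectified_traces[0].sampling_rate

    def objective(start: float, end: float) -> float:
        i0 = int(round(start * fs))
        i1 = min(int(round(end * fs)), matrix.shape[1])
        if i1 <= i0:
            return np.inf
        stats_ = matrix[:, i0:i1].max(axis=1)
        return fit_threshold(stats_, positive)[1]

    def key(start: float, end: float, err: float):
        return (round(err, 12), round(end - start, 12), start)

    best = None
    step = init_step
    starts = np.arange(min_start, t_max - step / 2, step)
    for s in starts:
        for e in np.arange(s + step, t_max + step / 2, step):
            e = min(e, t_max)
            err = objective(s, e)
            cand = (key(s, e, err), (float(s), float(e)))
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        raise FittingError("no feasible window")

    for _ in range(rounds - 1):
        step /= 2.0
        (s0, e0) = best[1]
        for ds in (-2, -1, 0, 1, 2):
            for de in (-2, -1, 0, 1, 2):
                s = max(min_start, s0 + ds * step)
                e = min(t_max, e0 + de * step)
                if e <= s:
                    continue
                err = objective(s, e)
                cand = (key(s, e, err), (float(s), float(e)))
                if cand[0] < best[0]:
                    best = cand
    return best[1]


def _task_traces(dataset: Dataset, task: int, cohort: str,
                 use_known_t0: bool = False):
    traces = select_cohort(dataset, cohort)
    kept, labels = [], []
    for tr in traces:
        label = trace_label(tr.location, task)
        if label is None:
            continue
        kept.append(rectified_aligned(tr, use_known_t0=use_known_t0))
        labels.append(label)
    if not kept:
        raise DataError(f"no traces for task {task} cohort {cohort}")
    return kept, np.array(labels)


def fit_time_model(dataset: Dataset, task: int, cohort: str = "all",
                   rounds: int = 3, use_known_t0: bool = False,
                   ) -> TimeThresholdModel:
    """Fit window + threshold(s) for one task and cohort.

    Tasks 1-2 fit the window and a single threshold against the task's
    binary labels. Task 3 reuses the Task 2 window and theta1 fitted on the
    same cohort, then fits theta2 > theta1 on the Rib-class traces only
    (Partial vs Whole).
    """
    if task in (1, 2):
        rect, labels = _task_traces(dataset, task, cohort, use_known_t0)
        positive = labels == POSITIVE_CLASS[task]
        window = fit_time_window(rect, positive, rounds=rounds)
        matrix, _ = _stat_matrix(rect)
        i0, i1 = int(round(window[0] * rect[0].sampling_rate)), \
            int(round(window[1] * rect[0].sampling_rate))
        stats_ = matrix[:, i0:min(i1, matrix.shape[1])].max(axis=1)
        theta1, _ = fit_threshold(stats_, positive)
        return TimeThresholdModel(task, cohort, window[0], window[1], theta1)

    if task != 3:
        raise ConfigurationError(f"task must be 1, 2 or 3, got {task}")
    base = fit_time_model(dataset, 2, cohort, rounds, use_known_t0)
    rect, labels = _task_traces(dataset, 3, cohort, use_known_t0)
    window = (base.window_start_s, base.window_end_s)
    rib = labels != NO_RIB
    stats_ = np.array([decision_statistic_time(t, window)
                       for t, keep in zip(rect, rib) if keep])
    whole = labels[rib] == WHOLE_RIB
    theta2, _ = fit_threshold(stats_, whole, min_theta=base.theta1)
    return TimeThresholdModel(3, cohort, window[0], window[1],
                              base.theta1, theta2)


def classify_statistic(model: TimeThresholdModel | FreqThresholdModel,
                       s: float) -> str:
    """Apply the threshold rule to a precomputed decision statistic."""
    if model.task == 3:
        if s < model.theta1:
            return NO_RIB
        return PARTIAL_RIB if s < model.theta2 else WHOLE_RIB
    return POSITIVE_CLASS[model.task] if s >= model.theta1 else NO_RIB


def predict_time(model: TimeThresholdModel, trace: RawTrace,
                 use_known_t0: bool = False) -> str:
    rect = rectified_aligned(trace, use_known_t0=use_known_t0)
    s = decision_statistic_time(rect, (model.window_start_s, model.window_end_s))
    return classify_statistic(model, s)


def fit_freq_model(dataset: Dataset, task: int, cohort: str = "all",
                   band: tuple[float, float] = DEFAULT_BAND,
                   use_known_t0: bool = False) -> FreqThresholdModel:
    """Fit spectral-magnitude threshold(s); the band is fixed, not fitted."""
    if task not in (1, 2, 3):
        raise ConfigurationError(f"task must be 1, 2 or 3, got {task}")
    traces = select_cohort(dataset, cohort)
    stats_, labels = [], []
    for tr in traces:
        label = trace_label(tr.location, task)
        if label is None:
            continue
        stats_.append(decision_statistic_freq(
            align(tr, use_known_t0=use_known_t0), band))
        labels.append(label)
    stats_ = np.array(stats_)
    labels = np.array(labels)
    if labels.size == 0:
        raise DataError(f"no traces for task {task} cohort {cohort}")

    if task in (1, 2):
        theta1, _ = fit_threshold(stats_, labels == POSITIVE_CLASS[task])
        return FreqThresholdModel(task, cohort, band[0], band[1], theta1)
    # Task 3: theta1 from the binary Rib/No-Rib split, frozen; theta2 fitted
    # on the Rib-class traces only (Partial vs Whole), above theta1.
    rib = labels != NO_RIB
    theta1, _ = fit_threshold(stats_, rib)
    theta2, _ = fit_threshold(stats_[rib], labels[rib] == WHOLE_RIB,
                              min_theta=theta1)
    return FreqThresholdModel(3, cohort, band[0], band[1], theta1, theta2)


def predict_freq(model: FreqThresholdModel, trace: RawTrace,
                 use_known_t0: bool = False) -> str:
    s = decision_statistic_freq(align(trace, use_known_t0=use_known_t0),
                                (model.band_lo_hz, model.band_hi_hz))
    return classify_statistic(model, s)


#: Published Task 1 presets (reference documentation, not defaults): the
#: pooled fit used a 73.84 µs window at 2.8 V; the low-BMI cohort a shorter
#: 38.72 µs window at 5.3 V; the high-BMI cohort a 60.80 µs window starting
#: 13.04 µs later at 1.4 V. Window starts assume the 15 µs artifact bound.
REFERENCE_TASK1_MODELS = {
    "all": TimeThresholdModel(1, "all", 1.5e-5, 8.884e-5, 2.8),
    "low_bmi": TimeThresholdModel(1, "low_bmi", 1.5e-5, 5.372e-5, 5.3),
    "high_bmi": TimeThresholdModel(1, "high_bmi", 2.804e-5, 8.884e-5, 1.4),
}
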