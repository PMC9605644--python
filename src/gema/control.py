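"""Online scheduling of the adaptive-threshold parameter.

Each frame contributes one point (frame index, coefficient of variation of
the preprocessed image). A running ordinary-least-squares line CV = m·x + b
models the series; whenever the line's mean absolute relative prediction
error over the most recent points exceeds a tolerance (default 5%), the
line is refit on the points observed since the last refit, yielding the
piecewise-linear tracking behavior a drifting culture requires.

The predicted CV is mapped linearly between the calibration extremes seen
so far onto the integer threshold range [5, 11]. Near confluence the
culture binarizes best with a threshold near 5 and during apoptosis near
11, so the map's direction depends on the experiment mode: in ``growth``
mode low CV → 5 (confluence) and high CV → 11; in ``apoptosis`` mode low
CV → 11 and high CV → 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .errors import DegenerateFitError, OrderingError, UndefinedCVError, ValidationError

THRESHOLD_MIN = 5
THRESHOLD_MAX = 11

MODE_GROWTH = "growth"
MODE_APOPTOSIS = "apoptosis"


class CVPoint(NamedTuple):
    x: int  # frame index
    y: float  # CV value (dimensionless)


@dataclass(frozen=True)
class RegressionModel:
    """A fitted line CV = m·x + b with its fit window and relative error."""

    m: float
    b: float
    fit_window: tuple[CVPoint, ...]
    fit_error: float

    def predict(self, x: float) -> float:
        return self.m * x + self.b


@dataclass(frozen=True)
class ControllerState:
    """Immutable controller snapshot; updates return a new state."""

    mode: str = MODE_GROWTH
    history: tuple[CVPoint, ...] = ()
    model: RegressionModel | None = None
    current_threshold: int = field(default=-1)
    cv_min: float = math.inf
    cv_max: float = -math.inf
    refit_tolerance: float = 0.05
    min_refit_window: int = 5
    # the CV→threshold map is trusted only once the observed CV range spans
    # at least this fraction of cv_max; until then the endpoint is used
    min_calibration_span: float = 0.1
    threshold_min: int = THRESHOLD_MIN
    threshold_max: int = THRESHOLD_MAX
    last_refit_at: int = 0  # length of history when the model was last (re)fit

    def __post_init__(self) -> None:
        if self.mode not in (MODE_GROWTH, MODE_APOPTOSIS):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.current_threshold == -1:
            object.__setattr__(self, "current_threshold", self.cold_start_threshold)

    @property
    def cold_start_threshold(self) -> int:
        # A growth experiment starts sparse (high-dispersion end → 11);
        # an apoptosis experiment starts confluent (→ 5).
        return self.threshold_max if self.mode == MODE_GROWTH else self.threshold_min


def coefficient_of_variation(gray: np.ndarray) -> float:
    """Population standard deviation over mean of all pixel intensities."""
    gray = np.asarray(gray, dtype=np.float64)
    mu = gray.mean()
    if mu == 0.0:
        raise UndefinedCVError("CV undefined: image mean is zero")
    return float(gray.std(ddof=0) / mu)


def fit_regression(points: Sequence[CVPoint]) -> RegressionModel:
    """Ordinary least squares on (frame index, CV) points.

    The fit error is the mean absolute relative error |ŷ − y| / y over the
    points with y > 0 (zero-CV points cannot contribute a relative error).
    """
    points = tuple(points)
    xs = np.array([p.x for p in points], dtype=np.float64)
    if len(points) < 2 or np.unique(xs).size < 2:
        raise DegenerateFitError("regression needs >= 2 points with distinct frame indices")
    ys = np.array([p.y for p in points], dtype=np.float64)
    m, b = np.polyfit(xs, ys, 1)
    model = RegressionModel(m=float(m), b=float(b), fit_window=points, fit_error=0.0)
    return replace(model, fit_error=_relative_error(model, points))


def _relative_error(model: RegressionModel, points: Sequence[CVPoint]) -> float:
    errs = [abs(model.predict(p.x) - p.y) / p.y for p in points if p.y > 0]
    return float(np.mean(errs)) if errs else 0.0


def schedule_threshold(state: ControllerState, predicted_cv: float) -> int:
    """Map a predicted CV onto the integer threshold range.

    The CV is clamped to the calibration extremes observed so far and
    interpolated linearly onto [threshold_min, threshold_max], rounded
    half-up; direction depends on the mode (see module docstring). Before
    any CV spread has been observed the mode's cold-start endpoint is used.
    """
    lo, hi = state.threshold_min, state.threshold_max
    span = state.cv_max - state.cv_min
    if span <= 0 or span < state.min_calibration_span * state.cv_max:
        # no meaningful dynamic range observed yet: interpolation is undefined
        return state.cold_start_threshold
    cv = min(max(predicted_cv, state.cv_min), state.cv_max)
    frac = (cv - state.cv_min) / (state.cv_max - state.cv_min)
    if state.mode == MODE_APOPTOSIS:
        frac = 1.0 - frac
    t = math.floor(lo + frac * (hi - lo) + 0.5)
    return min(max(t, lo), hi)


def update_controller(state: ControllerState, new_point: CVPoint) -> ControllerState:
    """Ingest one (frame index, CV) observation and reschedule the threshold.

    Maintains calibration extremes, fits the first model once two distinct
    frames are seen, and refits on the window since the last refit (at least
    ``min_refit_window`` recent points) whenever the current model's mean
    absolute relative error over the recent points exceeds
    ``refit_tolerance``.
    """
    if state.history and new_point.x <= state.history[-1].x:
        raise OrderingError(
            f"frame index {new_point.x} not greater than last seen {state.history[-1].x}"
        )
    history = state.history + (new_point,)
    cv_min = min(state.cv_min, new_point.y)
    cv_max = max(state.cv_max, new_point.y)
    model = state.model
    refit_at = state.last_refit_at

    if model is None:
        if len(history) >= 2:
            model = fit_regression(history)
            refit_at = len(history)
    else:
        recent = history[-min(len(history), state.min_refit_window) :]
        if _relative_error(model, recent) > state.refit_tolerance:
            window = history[refit_at:]
            if len(window) < state.min_refit_window:
                window = history[-min(len(history), state.min_refit_window) :]
            model = fit_regression(window)
            refit_at = len(history)

    new_state = replace(
        state,
        history=history,
        model=model,
        cv_min=cv_min,
        cv_max=cv_max,
        last_refit_at=refit_at,
    )
    if model is None:
        threshold = state.cold_start_threshold
    else:
        threshold = schedule_threshold(new_state, model.predict(new_point.x))
    return replace(new_state, current_threshold=threshold)
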