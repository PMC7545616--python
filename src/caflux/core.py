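"""Shared domain types for the Ca2+-imaging and variant-filtering pipelines.

The two assays analysed here share a small vocabulary: a :class:`PhaseSchedule`
describes the perfusion/stimulation timeline of an experiment, a
:class:`Trace` is one uniformly sampled fluorescence (or ratio) time series,
and :class:`PeakMetrics` holds the three kinetic read-outs (AUC, peak
amplitude, time to peak) computed for one cell or well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CafluxError",
    "ScheduleError",
    "LayoutError",
    "ShapeError",
    "MaskError",
    "WindowError",
    "BaselineError",
    "ParameterError",
    "ChannelError",
    "GroupingError",
    "ExclusionError",
    "DesignError",
    "InputError",
    "Phase",
    "PhaseSchedule",
    "Trace",
    "WellTrace",
    "PeakMetrics",
    "BaselineResult",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class CafluxError(ValueError):
    """Base class for all domain errors raised by this package."""


class ScheduleError(CafluxError):
    """Phase schedule violates its invariants (gaps, overlaps, bad bounds)."""


class LayoutError(CafluxError):
    """ROI layout invalid: overlapping ROIs or ROI outside the frame."""


class ShapeError(CafluxError):
    """Image/mask dimensions are incompatible."""


class MaskError(CafluxError):
    """ROI mask invalid (e.g. a declared label has no pixels)."""


class WindowError(CafluxError):
    """A requested time window is empty or does not fit the trace/phase."""


class BaselineError(CafluxError):
    """Baseline value unusable (non-positive F0)."""


class ParameterError(CafluxError):
    """A numeric parameter violates its constraint."""


class ChannelError(CafluxError):
    """A fluorescence channel violates its constraint (e.g. F380 <= 0)."""


class GroupingError(CafluxError):
    """A cell/well is not mapped to an experimental unit."""


class ExclusionError(CafluxError):
    """An exclusion id does not exist in the table."""


class DesignError(CafluxError):
    """Statistical design is degenerate or the wrong experimental unit."""


class InputError(CafluxError):
    """Required input column/sample missing, or malformed input record."""


# ---------------------------------------------------------------------------
# Phase schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Phase:
    """One perfusion/stimulation phase: ``label`` over ``[start_s, end_s)``."""

    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered, contiguous, non-overlapping perfusion phases.

    Parameters
    ----------
    phases:
        Ordered phases; each must start where the previous one ended and the
        first must start at 0.
    frame_interval_s:
        Sampling interval of the acquisition, seconds per frame.
    """

    phases: tuple[Phase, ...]
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ScheduleError("schedule needs at least one phase")
        if self.frame_interval_s <= 0:
            raise ScheduleError("frame_interval_s must be positive")
        prev_end = 0.0
        for ph in self.phases:
            if ph.start_s >= ph.end_s:
                raise ScheduleError(
                    f"phase {ph.label!r}: start_s must be < end_s"
                )
            if not np.isclose(ph.start_s, prev_end):
                raise ScheduleError(
                    f"phase {ph.label!r} starts at {ph.start_s}, expected "
                    f"{prev_end} (phases must be contiguous)"
                )
            prev_end = ph.end_s

    @property
    def total_duration_s(self) -> float:
        return self.phases[-1].end_s

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration_s / self.frame_interval_s))

    def times(self) -> np.ndarray:
        """Frame times ``0, dt, 2dt, ...`` spanning the schedule."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def phase(self, label: str) -> Phase:
        for ph in self.phases:
            if ph.label == label:
                return ph
        raise ScheduleError(f"no phase labelled {label!r}")

    def phase_after(self, label: str) -> Phase:
        """The phase immediately following ``label``."""
        for i, ph in enumerate(self.phases):
            if ph.label == label:
                if i + 1 >= len(self.phases):
                    raise ScheduleError(f"{label!r} is the last phase")
                return self.phases[i + 1]
        raise ScheduleError(f"no phase labelled {label!r}")

    def labels_at(self, times: np.ndarray) -> np.ndarray:
        """Phase label for each time point (half-open phase intervals)."""
        times = np.asarray(times, dtype=float)
        out = np.empty(times.shape, dtype=object)
        out[:] = self.phases[-1].label  # t == total_duration maps to last
        for ph in self.phases:
            out[(times >= ph.start_s) & (times < ph.end_s)] = ph.label
        return out.astype(str)


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def _as_1d(x: Iterable[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ShapeError("expected a 1-D array")
    return arr


@dataclass
class Trace:
    """A uniformly sampled fluorescence (or ratio) time series.

    ``values`` are in arbitrary fluorescence units for raw traces,
    dimensionless for dF/F0 or baseline-normalized ratio traces.
    """

    id: str
    time_s: np.ndarray
    values: np.ndarray
    group: str | None = None
    stimulus: str | None = None
    phase_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = _as_1d(self.time_s)
        self.values = _as_1d(self.values)
        if self.time_s.shape != self.values.shape:
            raise ShapeError("time_s and values must have equal length")
        if self.time_s.size < 2:
            raise ShapeError("a trace needs at least two frames")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ShapeError("time_s must be strictly increasing")
        if not np.allclose(dt, dt[0]):
            raise ShapeError("time_s must be uniformly spaced")
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("trace values must be finite")

    @property
    def frame_interval_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def window_mask(self, start_s: float, end_s: float) -> np.ndarray:
        """Boolean mask of frames with ``start_s <= t <= end_s``."""
        if end_s < start_s:
            raise WindowError("window end before start")
        mask = (self.time_s >= start_s) & (self.time_s <= end_s)
        if not mask.any():
            raise WindowError(
                f"window [{start_s}, {end_s}] s contains no frames"
            )
        return mask

    def with_values(self, values: np.ndarray, **changes) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float), **changes)


@dataclass
class WellTrace:
    """One plate-reader well: alternating 340/380 nm excitation channels."""

    well_id: str
    time_s: np.ndarray
    f340: np.ndarray
    f380: np.ndarray
    group: str | None = None
    stimulus: str = "other"

    def __post_init__(self) -> None:
        self.time_s = _as_1d(self.time_s)
        self.f340 = _as_1d(self.f340)
        self.f380 = _as_1d(self.f380)
        if not (self.time_s.shape == self.f340.shape == self.f380.shape):
            raise ShapeError("time_s, f340, f380 must have equal length")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
            raise ShapeError("time_s must be uniform and increasing")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakMetrics:
    """Kinetic read-outs of one cell or well within a response window.

    ``auc`` integrates the signed normalized signal (dF/F0, or ratio minus
    baseline) over the window, units: signal x seconds. ``amplitude`` is the
    window maximum of the normalized signal. ``time_to_peak_s`` is measured
    from the window start (agonist onset), first maximum on ties.
    """

    cell_id: str
    auc: float
    amplitude: float
    time_to_peak_s: float
    group: str | None = None


@dataclass(frozen=True)
class BaselineResult:
    """Baseline F0 chosen from the most stable window of the rest phase."""

    f0: float
    window_start_s: float
    window_end_s: float
    stability_score: float

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise BaselineError(f"baseline F0 must be positive, got {self.f0}")
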