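"""Evoked single-cell assay pipeline: baseline selection, dF/F0, peak
kinetics, per-coverslip aggregation.

The assay records Fluo-4 fluorescence under a five-phase perfusion protocol.
The pipeline (a) picks the baseline F0 as the most stable window of the
first extracellular-Ca2+-free phase, (b) normalizes each frame to
``(F_t - F0)/F0``, (c) extracts AUC, peak amplitude and time to peak from
the agonist response window, and (d) averages cells per coverslip — the
coverslip, not the cell, is the experimental unit carried into statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BaselineError,
    BaselineResult,
    GroupingError,
    PeakMetrics,
    PhaseSchedule,
    Trace,
    WindowError,
)
from .synthetic import AGONIST_PHASE, BASELINE_PHASE

__all__ = [
    "select_baseline",
    "compute_dff",
    "peak_metrics",
    "default_response_window",
    "aggregate_coverslip",
    "analyze_evoked",
]

DEFAULT_BASELINE_WINDOW_S = 30.0
NONRESPONDER_SD_FACTOR = 3.0


def select_baseline(
    trace: Trace,
    schedule: PhaseSchedule,
    window_len_s: float = DEFAULT_BASELINE_WINDOW_S,
    phase_label: str = BASELINE_PHASE,
) -> BaselineResult:
    """Choose F0 from the stablest window of the first 0-Ca2+ phase.

    "Stable" is made objective as the contiguous window of length
    ``window_len_s`` (inside the phase) minimizing the standard deviation of
    the raw trace; F0 is the mean over that window. Earliest window wins on
    ties.
    """
    phase = schedule.phase(phase_label)
    dt = trace.frame_interval_s
    w = int(round(window_len_s / dt))
    if w < 1:
        raise WindowError("window_len_s shorter than one frame")
    idx = np.flatnonzero(
        (trace.time_s >= phase.start_s) & (trace.time_s < phase.end_s)
    )
    if idx.size < w:
        raise WindowError(
            f"phase {phase_label!r} ({idx.size} frames) shorter than the "
            f"requested {w}-frame baseline window"
        )
    seg = trace.values[idx]
    windows = np.lib.stride_tricks.sliding_window_view(seg, w)
    sds = windows.std(axis=1)
    best = int(np.argmin(sds))
    f0 = float(windows[best].mean())
    start = float(trace.time_s[idx[best]])
    return BaselineResult(
        f0=f0,
        window_start_s=start,
        window_end_s=start + (w - 1) * dt,
        stability_score=float(sds[best]),
    )


def compute_dff(trace: Trace, f0: float) -> Trace:
    """Relative intensity ``(F_t - F0)/F0`` with the time axis unchanged."""
    if f0 <= 0:
        raise BaselineError(f"F0 must be positive, got {f0}")
    return trace.with_values((trace.values - f0) / f0)


def default_response_window(schedule: PhaseSchedule) -> tuple[float, float]:
    """Agonist onset to the end of the following 0-Ca2+ phase.

    Covers the ATP-evoked peak; the store-operated-entry phase is a positive
    control and stays out of the metrics.
    """
    agonist = schedule.phase(AGONIST_PHASE)
    following = schedule.phase_after(AGONIST_PHASE)
    return (agonist.start_s, following.end_s)


def peak_metrics(
    dff: Trace, response_window: tuple[float, float]
) -> PeakMetrics:
    """AUC, peak amplitude and time to peak of a dF/F0 trace.

    Amplitude is the window maximum; time to peak the time of the first
    maximum minus the window start; AUC the trapezoidal integral of the
    signed dF/F0 over the window (negative excursions subtract).
    """
    start_s, end_s = response_window
    mask = dff.window_mask(start_s, end_s)
    t = dff.time_s[mask]
    v = dff.values[mask]
    i_peak = int(np.argmax(v))  # argmax takes the first maximum: latency tie-break
    return PeakMetrics(
        cell_id=dff.id,
        auc=float(np.trapezoid(v, t)),
        amplitude=float(v[i_peak]),
        time_to_peak_s=float(t[i_peak] - start_s),
        group=dff.group,
    )


def aggregate_coverslip(
    metrics: list[PeakMetrics] | pd.DataFrame,
    grouping: dict[str, str],
    unit_type: str = "coverslip",
) -> pd.DataFrame:
    """Per-coverslip arithmetic means of the per-cell metrics.

    ``grouping`` maps every cell id to its coverslip id; an unmapped cell is
    an error, never silently dropped. The result carries ``unit_type`` so
    the statistics layer can refuse cell-level input.
    """
    if isinstance(metrics, pd.DataFrame):
        cells = metrics.copy()
    else:
        cells = pd.DataFrame(
            {
                "cell_id": [m.cell_id for m in metrics],
                "group": [m.group for m in metrics],
                "auc": [m.auc for m in metrics],
                "amplitude": [m.amplitude for m in metrics],
                "time_to_peak_s": [m.time_to_peak_s for m in metrics],
            }
        )
    unmapped = [c for c in cells["cell_id"] if c not in grouping]
    if unmapped:
        raise GroupingError(f"cells not mapped to any coverslip: {unmapped[:5]}")
    cells["unit_id"] = cells["cell_id"].map(grouping)
    agg = (
        cells.groupby("unit_id", sort=True)
        .agg(
            group=("group", "first"),
            n_cells=("cell_id", "size"),
            auc=("auc", "mean"),
            amplitude=("amplitude", "mean"),
            time_to_peak_s=("time_to_peak_s", "mean"),
        )
        .reset_index()
    )
    agg["unit_type"] = unit_type
    return agg


def analyze_evoked(
    traces: list[Trace],
    schedule: PhaseSchedule,
    grouping: dict[str, str],
    window_len_s: float = DEFAULT_BASELINE_WINDOW_S,
    response_window: tuple[float, float] | None = None,
    drop_nonresponders: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full evoked pipeline: baseline -> dF/F0 -> metrics -> coverslips.

    A cell whose amplitude falls below three times its baseline noise
    (stability score expressed on the dF/F0 scale) is flagged a
    non-responder; it is retained unless ``drop_nonresponders`` is set.

    Returns ``(cell_metrics, coverslip_summaries)``; the pipeline is a pure
    composition of :func:`select_baseline`, :func:`compute_dff`,
    :func:`peak_metrics` and :func:`aggregate_coverslip`.
    """
    if response_window is None:
        response_window = default_response_window(schedule)
    rows = []
    for tr in traces:
        base = select_baseline(tr, schedule, window_len_s)
        m = peak_metrics(compute_dff(tr, base.f0), response_window)
        noise_dff = base.stability_score / base.f0
        rows.append(
            {
                "cell_id": m.cell_id,
                "group": m.group,
                "f0": base.f0,
                "auc": m.auc,
                "amplitude": m.amplitude,
                "time_to_peak_s": m.time_to_peak_s,
                "responder": m.amplitude >= NONRESPONDER_SD_FACTOR * noise_dff,
            }
        )
    cells = pd.DataFrame(rows)
    used = cells[cells["responder"]] if drop_nonresponders else cells
    coverslips = aggregate_coverslip(
        used.drop(columns=["f0", "responder"]), grouping
    )
    return cells, coverslips
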