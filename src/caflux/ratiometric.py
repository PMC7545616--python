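"""Ratiometric plate-reader pipeline: F340/F380 ratio, running-average
smoothing, baseline normalization, windowed peak metrics.

Fura-2 shifts excitation with Ca2+ binding, so the 340/380 emission ratio
rises with cytosolic Ca2+ and cancels per-well dye load and gain. The
pipeline smooths the ratio with a centered running average of 5, normalizes
to the 30–90 s baseline (the EGTA window before the stimulus) and measures
AUC, peak amplitude and time to peak between 90 and 450 s relative to the
normalized baseline of 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    BaselineError,
    ChannelError,
    ParameterError,
    PeakMetrics,
    Trace,
    WellTrace,
)
from .evoked import aggregate_coverslip

__all__ = [
    "compute_ratio",
    "smooth_running_average",
    "normalize_to_baseline",
    "plate_peak_metrics",
    "analyze_plate",
    "DEFAULT_BASELINE_WINDOW",
    "DEFAULT_ANALYSIS_WINDOW",
]

DEFAULT_SMOOTH_K = 5
DEFAULT_BASELINE_WINDOW = (30.0, 90.0)
DEFAULT_ANALYSIS_WINDOW = (90.0, 450.0)


def compute_ratio(well: WellTrace) -> Trace:
    """Pointwise F340/F380 ratio with well metadata carried through."""
    if np.any(well.f380 <= 0):
        raise ChannelError(
            f"well {well.well_id}: F380 must be strictly positive"
        )
    return Trace(
        id=well.well_id,
        time_s=well.time_s,
        values=well.f340 / well.f380,
        group=well.group,
        stimulus=well.stimulus,
    )


def smooth_running_average(trace: Trace, k: int = DEFAULT_SMOOTH_K) -> Trace:
    """Centered moving mean of odd window ``k``; length preserved.

    Near the edges the window shrinks symmetrically (half-width
    ``min(i, n-1-i, k//2)``), so the mean stays centered and a linear ramp
    passes through unchanged everywhere.
    """
    if k % 2 == 0 or k < 1:
        raise ParameterError(f"running-average window must be odd >= 1, got {k}")
    n = trace.values.size
    if k > n:
        raise ParameterError(f"window {k} longer than trace ({n} frames)")
    v = trace.values
    h = k // 2
    out = np.empty(n)
    for i in range(n):
        hw = min(i, n - 1 - i, h)
        out[i] = v[i - hw : i + hw + 1].mean()
    return trace.with_values(out)


def normalize_to_baseline(
    trace: Trace, baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW
) -> Trace:
    """Divide by the mean over ``baseline_window``; that window then averages
    to exactly 1."""
    mask = trace.window_mask(*baseline_window)
    baseline = float(trace.values[mask].mean())
    if baseline <= 0:
        raise BaselineError(
            f"baseline mean over {baseline_window} s must be positive, "
            f"got {baseline}"
        )
    return trace.with_values(trace.values / baseline)


def plate_peak_metrics(
    norm: Trace, analysis_window: tuple[float, float] = DEFAULT_ANALYSIS_WINDOW
) -> PeakMetrics:
    """Metrics of a baseline-normalized ratio trace, relative to baseline 1.

    ``amplitude = max(norm) - 1``, ``auc = trapezoid of (norm - 1)``, time
    to peak from the window start (earliest maximum on ties), so a flat
    no-response trace scores 0 on all three.
    """
    start_s, end_s = analysis_window
    mask = norm.window_mask(start_s, end_s)
    t = norm.time_s[mask]
    v = norm.values[mask] - 1.0
    i_peak = int(np.argmax(v))
    return PeakMetrics(
        cell_id=norm.id,
        auc=float(np.trapezoid(v, t)),
        amplitude=float(v[i_peak]),
        time_to_peak_s=float(t[i_peak] - start_s),
        group=norm.group,
    )


def analyze_plate(
    wells: list[WellTrace],
    smooth_k: int = DEFAULT_SMOOTH_K,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    analysis_window: tuple[float, float] = DEFAULT_ANALYSIS_WINDOW,
    smooth_before_normalize: bool = True,
    experiment_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full plate pipeline over a set of wells.

    By default the ratio is smoothed, then normalized (trace preparation
    order); set ``smooth_before_normalize=False`` to normalize first — the
    two differ only at baseline-window edges. If ``experiment_of`` maps well
    ids to independent-experiment ids, wells are averaged per experiment and
    the result carries ``unit_type='experiment'``; otherwise per-well
    metrics are returned with ``unit_type='well'`` (not yet a valid
    statistical unit).
    """
    rows = []
    for well in wells:
        tr = compute_ratio(well)
        if smooth_before_normalize:
            tr = normalize_to_baseline(
                smooth_running_average(tr, smooth_k), baseline_window
            )
        else:
            tr = smooth_running_average(
                normalize_to_baseline(tr, baseline_window), smooth_k
            )
        m = plate_peak_metrics(tr, analysis_window)
        rows.append(
            {
                "cell_id": m.cell_id,
                "group": m.group,
                "stimulus": well.stimulus,
                "auc": m.auc,
                "amplitude": m.amplitude,
                "time_to_peak_s": m.time_to_peak_s,
            }
        )
    per_well = pd.DataFrame(rows)
    if experiment_of is None:
        out = per_well.rename(columns={"cell_id": "unit_id"})
        out["unit_type"] = "well"
        return out
    return aggregate_coverslip(
        per_well.drop(columns=["stimulus"]), experiment_of, unit_type="experiment"
    )
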