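"""ROI trace extraction: image stack + label mask -> per-cell mean-intensity
time series.

Masks are static across frames (adherent fibroblasts, no registration); the
value of a cell at frame *f* is the arithmetic mean of its pixels in that
frame. ROIs are returned in ascending label order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MaskError, ShapeError, Trace

__all__ = ["RoiMaskSet", "MaskReport", "extract_roi_traces", "validate_masks"]

DEFAULT_MIN_ROI_AREA = 5  # below this, a mean is noise-dominated -> warning


@dataclass
class RoiMaskSet:
    """Integer label image (0 = background) plus the ROI labels it declares.

    If ``roi_ids`` is omitted it is derived from the positive labels present
    in the image. Declaring a label that has no pixels is a mask error.
    """

    label_image: np.ndarray
    roi_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ShapeError("label_image must be 2-D")
        if not np.issubdtype(self.label_image.dtype, np.integer):
            raise MaskError("label_image must be an integer image")
        if np.any(self.label_image < 0):
            raise MaskError("labels must be non-negative")
        present = np.unique(self.label_image)
        present = tuple(int(v) for v in present if v > 0)
        if self.roi_ids is None:
            self.roi_ids = present
        else:
            self.roi_ids = tuple(sorted(int(v) for v in self.roi_ids))
        if not self.roi_ids:
            raise MaskError("mask contains no ROI labels")


@dataclass
class MaskReport:
    """Outcome of mask validation: per-ROI pixel counts plus any problems."""

    n_rois: int
    pixel_counts: dict[int, int]
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_masks(
    masks: RoiMaskSet,
    frame_shape: tuple[int, int],
    min_area: int = DEFAULT_MIN_ROI_AREA,
) -> MaskReport:
    """Check a mask set against the frame geometry.

    Empty or geometry-incompatible ROIs are errors; ROIs smaller than
    ``min_area`` pixels draw a warning. Failures are carried in the report
    rather than raised.
    """
    counts: dict[int, int] = {}
    errors: list[str] = []
    warnings: list[str] = []
    if tuple(masks.label_image.shape) != tuple(frame_shape):
        errors.append(
            f"mask shape {masks.label_image.shape} != frame shape {tuple(frame_shape)}"
        )
    for roi in masks.roi_ids:
        n = int(np.count_nonzero(masks.label_image == roi))
        counts[roi] = n
        if n == 0:
            errors.append(f"ROI {roi} has no pixels")
        elif n < min_area:
            warnings.append(f"ROI {roi} has only {n} px (< {min_area})")
    return MaskReport(
        n_rois=len(masks.roi_ids),
        pixel_counts=counts,
        errors=errors,
        warnings=warnings,
    )


def extract_roi_traces(
    stack: np.ndarray,
    masks: RoiMaskSet,
    frame_interval_s: float = 1.0,
    group: str | None = None,
) -> list[Trace]:
    """Mean pixel intensity per ROI per frame.

    Parameters
    ----------
    stack:
        ``(n_frames, height, width)`` image stack.
    masks:
        Static label mask matching the frame geometry.
    frame_interval_s:
        Acquisition interval used to build the time axis.

    Returns one :class:`~caflux.core.Trace` per ROI, ascending label order.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ShapeError("stack must be (frames, height, width)")
    if tuple(stack.shape[1:]) != tuple(masks.label_image.shape):
        raise ShapeError(
            f"frame shape {stack.shape[1:]} does not match mask shape "
            f"{masks.label_image.shape}"
        )
    traces: list[Trace] = []
    time_s = np.arange(stack.shape[0]) * frame_interval_s
    for roi in sorted(masks.roi_ids):
        sel = masks.label_image == roi
        if not sel.any():
            raise MaskError(f"ROI {roi} has no pixels")
        traces.append(
            Trace(
                id=f"roi{roi}",
                time_s=time_s,
                values=stack[:, sel].mean(axis=1),
                group=group,
            )
        )
    return traces
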