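"""Frame qualification: which grabbed frames become references or tracked images.

The frame grabber delivers a raw stream of detector frames.  Reference
CBCT projections only need blank frames rejected (mean ROI intensity
above a small floor).  Intrafraction kV frames (IMR — intrafraction
motion review) are gated harder: the beam must be on, the mean ROI
intensity must sit inside a configurable window, and it must exceed
twice the previous grabbed frame's mean — together this picks exactly
one frame per kV pulse out of the stream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .geometry import ROITemplate, normalize_angle


class FrameKind(enum.Enum):
    CBCT = "cbct"   # reference projection from the pre-treatment scan
    IMR = "imr"     # intrafraction motion-review kV image


@dataclass
class ProjectionImage:
    """A 2D detector frame with acquisition metadata."""

    pixels: np.ndarray
    gantry_deg: float
    kind: FrameKind = FrameKind.CBCT
    beam_on: bool = False
    index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be finite and non-negative")
        self.gantry_deg = normalize_angle(self.gantry_deg)


@dataclass(frozen=True)
class FilterConfig:
    """Qualification thresholds.

    ``cbct_min_mean`` rejects blank reference frames; IMR frames must
    have a mean ROI intensity inside ``[imr_min_mean, imr_max_mean]``
    (inclusive) and more than ``imr_prev_ratio`` times the previous
    grabbed frame's mean.  Intensity units are native detector counts
    and every threshold is configurable.
    """

    cbct_min_mean: float = 40.0
    imr_min_mean: float = 1500.0
    imr_max_mean: float = 200000.0
    imr_prev_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.cbct_min_mean < 0:
            raise ValueError("cbct_min_mean must be >= 0")
        if not self.imr_min_mean < self.imr_max_mean:
            raise ValueError("need imr_min_mean < imr_max_mean")
        if self.imr_prev_ratio <= 1:
            raise ValueError("imr_prev_ratio must be > 1")


def mean_roi_intensity(frame: ProjectionImage, roi: ROITemplate) -> float:
    """Arithmetic mean of the frame's pixels inside the ROI mask."""
    if frame.pixels.shape != roi.mask.shape:
        raise ValueError(
            f"frame grid {frame.pixels.shape} does not match ROI grid {roi.mask.shape}"
        )
    return float(frame.pixels[roi.mask].mean())


def qualify_cbct(
    frame: ProjectionImage, roi: ROITemplate, cfg: FilterConfig = FilterConfig()
) -> bool:
    """Accept a CBCT projection as a tracking reference.

    Minimal filtering: accept iff the mean ROI intensity is strictly
    larger than ``cbct_min_mean`` (rejects blank frames).
    """
    if frame.kind is not FrameKind.CBCT:
        raise ValueError("qualify_cbct expects a CBCT-reference frame")
    return mean_roi_intensity(frame, roi) > cfg.cbct_min_mean


def qualify_imr(
    frame: ProjectionImage,
    roi: ROITemplate,
    prev_mean: float | None,
    cfg: FilterConfig = FilterConfig(),
    latched: bool = False,
) -> bool:
    """Accept an IMR frame for registration.

    Accept iff the beam is on, the mean ROI intensity lies in
    ``[imr_min_mean, imr_max_mean]`` and (when a previous frame exists)
    is strictly more than ``imr_prev_ratio`` times the previous grabbed
    frame's mean.  ``latched`` indicates a frame for the current kV
    pulse was already accepted; while latched, frames are rejected until
    the mean falls back below ``imr_min_mean`` (one frame per kV beam).
    """
    if frame.kind is not FrameKind.IMR:
        raise ValueError("qualify_imr expects an IMR frame")
    mean = mean_roi_intensity(frame, roi)
    if latched and mean >= cfg.imr_min_mean:
        return False
    if not frame.beam_on:
        return False
    if not (cfg.imr_min_mean <= mean <= cfg.imr_max_mean):
        return False
    if prev_mean is not None and not (mean > cfg.imr_prev_ratio * prev_mean):
        return False
    return True


@dataclass
class StreamQualifier:
    """Stateful qualifier over a raw grabbed-frame stream.

    Tracks the previous grabbed frame's mean (regardless of verdict) and
    the one-frame-per-pulse latch, so that a kV pulse lighting up several
    consecutive frames yields exactly one accepted IMR frame.
    """

    cfg: FilterConfig = field(default_factory=FilterConfig)
    prev_mean: float | None = None
    latched: bool = False

    def process(self, frame: ProjectionImage, roi: ROITemplate) -> bool:
        mean = mean_roi_intensity(frame, roi)
        if frame.kind is FrameKind.CBCT:
            verdict = qualify_cbct(frame, roi, self.cfg)
        else:
            verdict = qualify_imr(frame, roi, self.prev_mean, self.cfg, self.latched)
            if verdict:
                self.latched = True
            elif mean < self.cfg.imr_min_mean:
                self.latched = False
        self.prev_mean = mean
        return verdict

    def reset(self) -> None:
        self.prev_mean = None
        self.latched = False
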