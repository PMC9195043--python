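"""Headless tracking-session state machine.

A treatment fraction walks through four operational modes in order:
IDLE → CBCT (reference acquisition) → EDIT_ROI (optional template
touch-up) → TRACKING (intrafraction monitoring), with a reset to IDLE
allowed from anywhere.  The session routes grabbed frames through the
qualification filters, pairs accepted IMR frames with the angularly
closest reference, registers them with warm-start chaining, applies the
clinical tolerance check and appends one log record per tracked frame.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import (
    FilterConfig,
    FrameKind,
    ProjectionImage,
    StreamQualifier,
)
from .geometry import (
    DetectorSpec,
    ROITemplate,
    ReferenceSet,
    Shift2D,
    circular_distance,
    pair_reference,
)
from .registration import RegistrationConfig, TrackingResult, register


class SessionMode(enum.Enum):
    IDLE = "idle"
    CBCT = "cbct"
    EDIT_ROI = "edit_roi"
    TRACKING = "tracking"


_ALLOWED_TRANSITIONS = {
    SessionMode.IDLE: {SessionMode.CBCT},
    SessionMode.CBCT: {SessionMode.EDIT_ROI, SessionMode.TRACKING},
    SessionMode.EDIT_ROI: {SessionMode.TRACKING},
    SessionMode.TRACKING: set(),
}


@dataclass(frozen=True)
class LogRecord:
    """One tracked frame: when, where, what the tracker reported."""

    frame_index: int
    gantry_deg: float
    result: TrackingResult
    alert: bool


def check_tolerance(result: TrackingResult, tolerance_mm: float) -> bool:
    """Alert iff either shift component strictly exceeds the clinical tolerance."""
    if tolerance_mm <= 0:
        raise ValueError("tolerance must be positive")
    return abs(result.shift.x) > tolerance_mm or abs(result.shift.y) > tolerance_mm


def edit_roi(
    template: ROITemplate,
    add: np.ndarray | None = None,
    remove: np.ndarray | None = None,
) -> ROITemplate:
    """Apply pixel-set edits to an ROI template.

    ``add`` and ``remove`` are boolean masks on the detector grid (the
    headless equivalent of paint-brush edits).  The edited ROI must stay
    non-empty.
    """
    mask = template.mask.copy()
    if add is not None:
        mask |= np.asarray(add, dtype=bool)
    if remove is not None:
        mask &= ~np.asarray(remove, dtype=bool)
    if not mask.any():
        raise ValueError("ROI edit would empty the template")
    return ROITemplate(mask=mask, angle_deg=template.angle_deg, plan_id=template.plan_id)


class TrackingSession:
    """One fraction's worth of reference building and motion tracking.

    ROI templates are supplied per reference angle; for an arbitrary
    frame angle the angularly closest template is used.  In TRACKING
    mode the first accepted IMR frame starts the search at (0, 0) and
    every subsequent one at the previous optimum (warm-start chain).
    """

    def __init__(
        self,
        spec: DetectorSpec,
        roi_templates: list[ROITemplate],
        filter_cfg: FilterConfig | None = None,
        reg_cfg: RegistrationConfig | None = None,
        tolerance_mm: float = 2.0,
        pairing_tolerance_deg: float = 0.75,
    ) -> None:
        if not roi_templates:
            raise ValueError("at least one ROI template is required")
        self.spec = spec
        self.roi_templates = list(roi_templates)
        self.filter_cfg = filter_cfg or FilterConfig()
        self.reg_cfg = reg_cfg or RegistrationConfig()
        self.tolerance_mm = tolerance_mm
        self.pairing_tolerance_deg = pairing_tolerance_deg

        self.mode = SessionMode.IDLE
        self.references = ReferenceSet()
        self.log: list[LogRecord] = []
        self._qualifier = StreamQualifier(cfg=self.filter_cfg)
        self._warm_start: Shift2D | None = None

    # -- mode control -------------------------------------------------------

    def set_mode(self, mode: SessionMode) -> None:
        if mode is SessionMode.IDLE:
            self.reset()
            return
        if mode is self.mode:
            return
        if mode not in _ALLOWED_TRANSITIONS[self.mode]:
            raise ValueError(f"illegal mode transition {self.mode.value} -> {mode.value}")
        if mode is SessionMode.TRACKING:
            if len(self.references) == 0:
                raise ValueError("cannot enter TRACKING without reference projections")
            # new acquisition phase: the doubling rule must not compare the
            # first IMR frame against the last CBCT reference
            self._qualifier.reset()
        self.mode = mode

    def reset(self) -> None:
        """Return to IDLE, clearing references, log and warm start."""
        self.mode = SessionMode.IDLE
        self.references = ReferenceSet()
        self.log = []
        self._qualifier.reset()
        self._warm_start = None

    # -- frame routing ------------------------------------------------------

    def roi_for_angle(self, gantry_deg: float) -> ROITemplate:
        return min(
            self.roi_templates,
            key=lambda t: circular_distance(t.angle_deg, gantry_deg),
        )

    def ingest_frame(self, frame: ProjectionImage) -> LogRecord | None:
        """Route one grabbed frame according to the current mode.

        CBCT mode appends qualified frames to the reference set; TRACKING
        mode registers qualified IMR frames and logs the result.  Returns
        the log record for a tracked frame, ``None`` otherwise.
        """
        if self.mode in (SessionMode.IDLE, SessionMode.EDIT_ROI):
            return None
        roi = self.roi_for_angle(frame.gantry_deg)

        if self.mode is SessionMode.CBCT:
            if frame.kind is FrameKind.CBCT and self._qualifier.process(frame, roi):
                self.references.add(frame.gantry_deg, frame)
            return None

        # TRACKING
        if len(self.references) == 0:
            raise RuntimeError("TRACKING mode entered without a reference set")
        if frame.kind is not FrameKind.IMR:
            return None
        if not self._qualifier.process(frame, roi):
            return None
        paired = pair_reference(
            frame.gantry_deg, self.references, self.pairing_tolerance_deg
        )
        if paired is None:
            return None
        ref_frame, ref_angle = paired
        result = register(
            ref_frame,  # type: ignore[arg-type]
            frame,
            roi,
            self.spec,
            self.reg_cfg,
            warm_start=self._warm_start,
        )
        self._warm_start = result.shift
        record = LogRecord(
            frame_index=frame.index,
            gantry_deg=frame.gantry_deg,
            result=result,
            alert=check_tolerance(result, self.tolerance_mm),
        )
        self.log.append(record)
        return record

    # -- log export ---------------------------------------------------------

    def log_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "frame_index": r.frame_index,
                "gantry_deg": r.gantry_deg,
                "ref_angle_deg": r.result.ref_angle_deg,
                "x_mm": r.result.shift.x,
                "y_mm": r.result.shift.y,
                "ncc": r.result.objective,
                "converged": r.result.converged,
                "alert": r.alert,
            }
            for r in self.log
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "frame_index",
                "gantry_deg",
                "ref_angle_deg",
                "x_mm",
                "y_mm",
                "ncc",
                "converged",
                "alert",
            ],
        )
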