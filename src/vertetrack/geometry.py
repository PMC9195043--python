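"""Cone-beam projection geometry and unit conversions.

Coordinate conventions
----------------------
Patient coordinates are right-handed and isocenter-centered:

* ``x`` — lateral (patient left positive),
* ``y`` — longitudinal (superior positive),
* ``z`` — vertical (anterior positive for a head-first supine patient).

The gantry rotates about the longitudinal axis.  At gantry 0 deg the kV
source sits above the patient at distance SAD from the isocenter; at
gantry 180 deg it sits below (a posterior beam).  The flat-panel detector
is perpendicular to the beam axis at distance SID from the source, with
its columns along the in-plane lateral direction (beam's-eye-view ``x``)
and its rows along the longitudinal direction (beam's-eye-view ``y``).

Detector pixel coordinates are 0-based with a pixel-center convention:
the central ray hits ``((n_cols - 1) / 2, (n_rows - 1) / 2)``.

Reported 2D shifts live in the beam's-eye view *at the isocenter plane*,
i.e. detector displacements divided by the geometric magnification
SID/SAD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class DetectorSpec:
    """Flat-panel geometry: pixel grid, active area and imaging distances.

    Defaults describe a 1024 x 768 panel with a 39.7 x 29.8 cm active
    area imaged at 150 cm SID / 100 cm SAD.  Pixels are assumed square;
    the column pitch (``active_width / n_cols``) is used everywhere and
    must agree with the row pitch to within 1%.
    """

    n_cols: int = 1024
    n_rows: int = 768
    active_width: float = 397.0   # mm
    active_height: float = 298.0  # mm
    sid: float = 1500.0           # source-to-imager distance, mm
    sad: float = 1000.0           # source-to-axis distance, mm

    def __post_init__(self) -> None:
        for name in ("n_cols", "n_rows", "active_width", "active_height", "sid", "sad"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DetectorSpec.{name} must be positive")
        col_pitch = self.active_width / self.n_cols
        row_pitch = self.active_height / self.n_rows
        if abs(col_pitch - row_pitch) > 0.01 * col_pitch:
            raise ValueError(
                f"non-square pixels: column pitch {col_pitch:.4f} mm vs "
                f"row pitch {row_pitch:.4f} mm differ by more than 1%"
            )

    @property
    def magnification(self) -> float:
        return self.sid / self.sad

    @property
    def center_px(self) -> tuple[float, float]:
        """(col, row) of the central ray, pixel-center convention."""
        return ((self.n_cols - 1) / 2.0, (self.n_rows - 1) / 2.0)

    def scaled(self, factor: float) -> "DetectorSpec":
        """Same active area and distances with the pixel grid scaled by ``factor``."""
        return DetectorSpec(
            n_cols=int(round(self.n_cols * factor)),
            n_rows=int(round(self.n_rows * factor)),
            active_width=self.active_width,
            active_height=self.active_height,
            sid=self.sid,
            sad=self.sad,
        )


def pixel_pitch(spec: DetectorSpec) -> float:
    """Detector pixel size in mm/px (column pitch; square pixels assumed)."""
    return spec.active_width / spec.n_cols


def normalize_angle(degrees: float) -> float:
    """Normalize a gantry angle to [0, 360)."""
    return float(np.mod(degrees, 360.0))


def circular_distance(a: float, b: float) -> float:
    """Smallest absolute angular distance between two gantry angles, deg."""
    d = abs(normalize_angle(a) - normalize_angle(b))
    return min(d, 360.0 - d)


@dataclass(frozen=True)
class Shift2D:
    """A 2D shift in the beam's-eye view at the isocenter plane, mm.

    ``x`` is lateral (along detector columns), ``y`` longitudinal (along
    detector rows).
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("Shift2D components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def detector_shift_to_iso(shift_px: Sequence[float], spec: DetectorSpec) -> Shift2D:
    """Convert a detector-plane pixel shift to isocenter-plane mm.

    Each component is demagnified: ``px * pitch * SAD / SID``.
    """
    pitch = pixel_pitch(spec)
    f = pitch * spec.sad / spec.sid
    return Shift2D(x=float(shift_px[0]) * f, y=float(shift_px[1]) * f)


def iso_to_detector_px(shift: Shift2D, spec: DetectorSpec) -> tuple[float, float]:
    """Exact inverse of :func:`detector_shift_to_iso`."""
    pitch = pixel_pitch(spec)
    f = spec.sid / (spec.sad * pitch)
    return (shift.x * f, shift.y * f)


# ---------------------------------------------------------------------------
# Source / detector frame at a gantry angle
# ---------------------------------------------------------------------------

def source_position(gantry_deg: float, spec: DetectorSpec) -> np.ndarray:
    """kV source position in patient coordinates, mm."""
    g = np.deg2rad(normalize_angle(gantry_deg))
    return spec.sad * np.array([np.sin(g), 0.0, np.cos(g)])


def detector_axes(gantry_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vectors (beam axis d, column axis u, row axis v) at a gantry angle.

    ``d`` points from the source toward the detector, ``u`` spans detector
    columns (BEV lateral), ``v`` spans detector rows (BEV longitudinal).
    """
    g = np.deg2rad(normalize_angle(gantry_deg))
    d = -np.array([np.sin(g), 0.0, np.cos(g)])
    u = np.array([np.cos(g), 0.0, -np.sin(g)])
    v = np.array([0.0, 1.0, 0.0])
    return d, u, v


def project_point(
    point: Sequence[float], gantry_deg: float, spec: DetectorSpec
) -> tuple[float, float]:
    """Perspective-project a 3D point (mm, patient coords) to detector (col, row) px.

    Raises ``ValueError`` if the point lies at or behind the source plane.
    """
    p = np.asarray(point, dtype=float)
    src = source_position(gantry_deg, spec)
    d, u, v = detector_axes(gantry_deg)
    rel = p - src
    depth = float(rel @ d)
    if depth <= 0:
        raise ValueError("point lies at or behind the source plane")
    scale = spec.sid / depth
    u_mm = float(rel @ u) * scale
    v_mm = float(rel @ v) * scale
    pitch = pixel_pitch(spec)
    cc, cr = spec.center_px
    return (cc + u_mm / pitch, cr + v_mm / pitch)


def bev_shift_of_translation(
    translation: Sequence[float], gantry_deg: float, spec: DetectorSpec
) -> Shift2D:
    """Beam's-eye-view 2D shift (iso-plane mm) produced by a rigid 3D translation.

    The ground truth used when scoring a tracked shift against a known
    couch shift: project the translated isocenter point and demagnify the
    detector displacement back to the isocenter plane.
    """
    cc, cr = spec.center_px
    col, row = project_point(translation, gantry_deg, spec)
    return detector_shift_to_iso((col - cc, row - cr), spec)


# ---------------------------------------------------------------------------
# ROI forward projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROITemplate:
    """Per-gantry-angle binary mask on the detector grid."""

    mask: np.ndarray          # bool, shape (n_rows, n_cols)
    angle_deg: float = 0.0
    plan_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError("ROI mask must be non-empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1), half-open."""
        rows = np.any(self.mask, axis=1)
        cols = np.any(self.mask, axis=0)
        r = np.where(rows)[0]
        c = np.where(cols)[0]
        return int(r[0]), int(r[-1]) + 1, int(c[0]), int(c[-1]) + 1


def project_roi(
    mask3d: np.ndarray,
    spacing: float | Sequence[float],
    origin: Sequence[float],
    gantry_deg: float,
    spec: DetectorSpec,
    plan_id: str = "",
) -> ROITemplate:
    """Forward-project a 3D ROI mask onto the detector at one gantry angle.

    Voxel centers of the set voxels are point-projected; the resulting
    scatter of detector pixels is closed with a 3x3 structuring element to
    remove sampling holes.  The 3D mask is expected to already include any
    safety margin (clinically a 2 cm isotropic expansion of the contoured
    vertebrae).
    """
    mask3d = np.asarray(mask3d, dtype=bool)
    if not mask3d.any():
        raise ValueError("3D ROI mask is empty")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    origin = np.asarray(origin, dtype=float)

    idx = np.argwhere(mask3d)                         # (N, 3) voxel indices
    pts = origin + (idx + 0.0) * spacing              # voxel centers, mm

    src = source_position(gantry_deg, spec)
    d, u, v = detector_axes(gantry_deg)
    rel = pts - src
    depth = rel @ d
    if np.any(depth <= 0):
        raise ValueError("ROI voxel lies at or behind the source plane")
    scale = spec.sid / depth
    pitch = pixel_pitch(spec)
    cc, cr = spec.center_px
    cols = np.round(cc + (rel @ u) * scale / pitch).astype(int)
    rows = np.round(cr + (rel @ v) * scale / pitch).astype(int)

    inside = (cols >= 0) & (cols < spec.n_cols) & (rows >= 0) & (rows < spec.n_rows)
    det = np.zeros((spec.n_rows, spec.n_cols), dtype=bool)
    det[rows[inside], cols[inside]] = True
    det = ndimage.binary_closing(det, structure=np.ones((3, 3), dtype=bool))
    if not det.any():
        raise ValueError("projected ROI does not intersect the detector")
    return ROITemplate(mask=det, angle_deg=normalize_angle(gantry_deg), plan_id=plan_id)


# ---------------------------------------------------------------------------
# Reference trajectory
# ---------------------------------------------------------------------------

class ReferenceSet:
    """Angle-indexed collection of reference CBCT projections.

    Entries are kept sorted by gantry angle normalized to one revolution.
    """

    def __init__(self, entries: Sequence[tuple[float, "object"]] = ()) -> None:
        self._entries: list[tuple[float, object]] = []
        for angle, frame in entries:
            self.add(angle, frame)

    def add(self, angle_deg: float, frame: object) -> None:
        a = normalize_angle(angle_deg)
        if any(abs(a - e[0]) < 1e-12 for e in self._entries):
            raise ValueError(f"duplicate reference angle {a}")
        self._entries.append((a, frame))
        self._entries.sort(key=lambda e: e[0])

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[tuple[float, object]]:
        return iter(self._entries)

    @property
    def angles(self) -> np.ndarray:
        return np.array([a for a, _ in self._entries])

    def angular_gaps(self) -> np.ndarray:
        """Diagnostic: circular gaps between consecutive reference angles, deg."""
        a = self.angles
        if len(a) < 2:
            return np.array([360.0]) if len(a) == 1 else np.array([])
        gaps = np.diff(a)
        return np.append(gaps, 360.0 - a[-1] + a[0])


def pair_reference(
    imr_angle_deg: float, refs: ReferenceSet, tolerance_deg: float = 0.75
) -> tuple[object, float] | None:
    """Find the reference projection angularly closest to an IMR frame.

    Returns ``(frame, angle)`` for the reference with minimal circular
    distance if that distance is strictly below ``tolerance_deg``, else
    ``None`` (the frame cannot be tracked).  Ties break toward the
    smaller angle, which the sorted ordering guarantees.
    """
    if len(refs) == 0:
        raise ValueError("reference set is empty")
    best: tuple[float, float, object] | None = None
    for angle, frame in refs:
        dist = circular_distance(imr_angle_deg, angle)
        if best is None or dist < best[0] - 1e-12:
            best = (dist, angle, frame)
    assert best is not None
    dist, angle, frame = best
    if dist < tolerance_deg:
        return frame, angle
    return None


def angular_spacing(n_projections: int) -> float:
    """Angle interval of a full 360 deg trajectory with ``n_projections`` frames."""
    if n_projections < 1:
        raise ValueError("need at least one projection")
    return 360.0 / n_projections
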