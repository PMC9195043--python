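"""2D/2D registration of intrafraction kV frames against CBCT references.

The tracked quantity is the 2D shift (x, y), in the beam's-eye view at
the isocenter plane, that best aligns the reference projection with the
live frame.  The match score is normalized cross-correlation restricted
to the tracking ROI::

    Obj(x, y) = <T2D(x, y) Proj_r, Proj_i> / (||T2D(x, y) Proj_r|| * ||Proj_i||)

with sums and Euclidean norms over ROI pixels only; for non-negative
images the score lies in [0, 1], and 1 means a perfect match
(Cauchy–Schwarz).  ``T2D`` translates the reference by the
detector-plane equivalent of the candidate iso-plane shift using
bilinear interpolation.

The score is maximized by a classical 2D downhill simplex (Nelder–Mead)
run on the sign-flipped objective.  The initial simplex sits at the
start point with two edges of length ``step_init`` along the axes; the
search stops when the relative spread of the three scores,
``2|Obj_H - Obj_L| / (Obj_H + Obj_L)``, falls below ``tol``.  If that
does not happen within ``max_iter`` iterations the simplex is rebuilt at
its current best vertex with the initial edge length, at most
``max_rebuilds`` times.  Candidate shifts beyond ``capture_range`` mm on
either axis score the worst possible value, which confines the search
to the capture-range square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .frames import ProjectionImage
from .geometry import DetectorSpec, ROITemplate, Shift2D, iso_to_detector_px

_SPREAD_EPS = 1e-12


@dataclass(frozen=True)
class RegistrationConfig:
    """Optimizer constants and unit conventions.

    ``step_init`` (mm) is the initial simplex edge; ``tol`` the relative
    spread threshold of the stopping rule; ``max_iter`` the iteration
    budget between rebuilds; ``max_rebuilds`` how many times the simplex
    may be re-initialized at its current best; ``capture_range`` (mm)
    the largest per-axis shift the search may report.  ``zero_mean``
    switches the score to zero-mean (Pearson-style) correlation; the
    default is the plain normalized inner product.
    """

    step_init: float = 2.0
    tol: float = 1e-6
    max_iter: int = 20
    max_rebuilds: int = 4
    capture_range: float = 20.0
    interpolation: str = "bilinear"
    zero_mean: bool = False

    def __post_init__(self) -> None:
        if self.step_init <= 0:
            raise ValueError("step_init must be positive")
        if not (0 < self.tol < 1):
            raise ValueError("tol must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.max_rebuilds < 0:
            raise ValueError("max_rebuilds must be >= 0")
        if self.capture_range <= 0:
            raise ValueError("capture_range must be positive")
        if self.interpolation != "bilinear":
            raise ValueError("only bilinear interpolation is supported")

    @property
    def worst_value(self) -> float:
        """Score assigned outside the capture range (bottom of the score range)."""
        return -1.0 if self.zero_mean else 0.0


@dataclass(frozen=True)
class TrackingResult:
    """Reported 2D shift with score and provenance."""

    shift: Shift2D
    objective: float
    converged: bool
    rebuilds_used: int
    ref_angle_deg: float = float("nan")
    imr_index: int = -1


def translate_image(
    pixels: np.ndarray, shift: Shift2D, spec: DetectorSpec
) -> np.ndarray:
    """Translate an image by the detector-plane equivalent of an iso-plane shift.

    Bilinear resampling; out-of-bounds samples take the nearest-edge
    value.  Positive ``shift.x`` moves content toward higher columns,
    positive ``shift.y`` toward higher rows.
    """
    px, py = iso_to_detector_px(shift, spec)
    return ndimage.shift(
        np.asarray(pixels, dtype=float),
        shift=(py, px),
        order=1,
        mode="nearest",
        prefilter=False,
    )


def _roi_window(
    roi: ROITemplate, shift_px: float, shape: tuple[int, int]
) -> tuple[slice, slice]:
    """Crop window covering the ROI plus the translation reach."""
    r0, r1, c0, c1 = roi.bounding_box()
    pad = int(np.ceil(abs(shift_px))) + 2
    return (
        slice(max(r0 - pad, 0), min(r1 + pad, shape[0])),
        slice(max(c0 - pad, 0), min(c1 + pad, shape[1])),
    )


def ncc_objective(
    ref: ProjectionImage,
    live: ProjectionImage,
    roi: ROITemplate,
    shift: Shift2D,
    spec: DetectorSpec,
    zero_mean: bool = False,
) -> float:
    """Normalized cross-correlation over the ROI at a candidate shift.

    The reference is translated; the ROI mask stays fixed on the live
    frame's grid.  A zero denominator (blank ROI content) scores 0.
    """
    if ref.pixels.shape != live.pixels.shape:
        raise ValueError("reference and live frame grids differ")
    if ref.pixels.shape != roi.mask.shape:
        raise ValueError("ROI grid does not match the frame grid")

    px, py = iso_to_detector_px(shift, spec)
    win = _roi_window(roi, max(abs(px), abs(py)), ref.pixels.shape)
    sub_ref = ref.pixels[win]
    # crop-local translation is exact as long as the window pads the ROI by
    # the shift reach (nearest-edge fills can then only differ outside it)
    moved = ndimage.shift(sub_ref, shift=(py, px), order=1, mode="nearest", prefilter=False)
    a = moved[roi.mask[win]]
    b = live.pixels[win][roi.mask[win]]
    if zero_mean:
        a = a - a.mean()
        b = b - b.mean()
    denom = float(np.linalg.norm(a) * np.linalg.norm(b))
    if denom < _SPREAD_EPS:
        return 0.0
    value = float(a @ b) / denom
    return min(value, 1.0)


def penalized_objective(
    ref: ProjectionImage,
    live: ProjectionImage,
    roi: ROITemplate,
    shift: Shift2D,
    spec: DetectorSpec,
    cfg: RegistrationConfig = RegistrationConfig(),
) -> float:
    """NCC score with the capture-range penalty.

    Shifts whose lateral or longitudinal component exceeds the capture
    range (strictly; the boundary is inside) return the worst score, so
    the simplex cannot settle outside the allowed square.
    """
    if abs(shift.x) > cfg.capture_range or abs(shift.y) > cfg.capture_range:
        return cfg.worst_value
    return ncc_objective(ref, live, roi, shift, spec, zero_mean=cfg.zero_mean)


def downhill_simplex_2d(
    objective: Callable[[Shift2D], float],
    start: Shift2D,
    cfg: RegistrationConfig = RegistrationConfig(),
) -> tuple[Shift2D, float, bool, int]:
    """Maximize a 2D objective with the rebuild-capable downhill simplex.

    Standard Nelder–Mead coefficients (reflection 1, expansion 2,
    contraction 0.5, shrink 0.5) on the sign-flipped objective; initial
    simplex ``{start, start + (step, 0), start + (0, step)}``.  The
    relative-spread stopping rule is evaluated on the raw (positive)
    objective values at the top of every iteration, with a degenerate
    denominator treated as converged.  Returns
    ``(best_shift, best_value, converged, rebuilds_used)``.
    """

    def f(v: np.ndarray) -> float:
        return -objective(Shift2D(float(v[0]), float(v[1])))

    step = cfg.step_init
    verts = np.array(
        [
            [start.x, start.y],
            [start.x + step, start.y],
            [start.x, start.y + step],
        ]
    )
    vals = np.array([f(v) for v in verts])
    converged = False
    rebuilds = 0

    while True:
        for _ in range(cfg.max_iter):
            order = np.argsort(vals, kind="stable")
            verts, vals = verts[order], vals[order]

            obj_h = -vals[0]  # highest score
            obj_l = -vals[-1]  # lowest score
            denom = abs(obj_h + obj_l)
            if denom < _SPREAD_EPS or 2.0 * abs(obj_h - obj_l) / denom < cfg.tol:
                converged = True
                break

            centroid = verts[:2].mean(axis=0)
            worst = verts[2]
            reflected = centroid + (centroid - worst)
            fr = f(reflected)
            if fr < vals[0]:
                expanded = centroid + 2.0 * (centroid - worst)
                fe = f(expanded)
                if fe < fr:
                    verts[2], vals[2] = expanded, fe
                else:
                    verts[2], vals[2] = reflected, fr
            elif fr < vals[1]:
                verts[2], vals[2] = reflected, fr
            else:
                if fr < vals[2]:
                    contracted = centroid + 0.5 * (reflected - centroid)
                    fc = f(contracted)
                    accept = fc <= fr
                else:
                    contracted = centroid + 0.5 * (worst - centroid)
                    fc = f(contracted)
                    accept = fc < vals[2]
                if accept:
                    verts[2], vals[2] = contracted, fc
                else:
                    for i in (1, 2):  # shrink toward the best vertex
                        verts[i] = verts[0] + 0.5 * (verts[i] - verts[0])
                        vals[i] = f(verts[i])

        if converged or rebuilds >= cfg.max_rebuilds:
            break
        rebuilds += 1
        best = verts[np.argmin(vals)]
        verts = np.array([best, best + [step, 0.0], best + [0.0, step]])
        vals = np.array([f(v) for v in verts])

    i_best = int(np.argmin(vals))
    best_shift = Shift2D(float(verts[i_best, 0]), float(verts[i_best, 1]))
    return best_shift, float(-vals[i_best]), converged, rebuilds


def register(
    ref: ProjectionImage,
    live: ProjectionImage,
    roi: ROITemplate,
    spec: DetectorSpec,
    cfg: RegistrationConfig = RegistrationConfig(),
    warm_start: Shift2D | None = None,
) -> TrackingResult:
    """Track one IMR frame against its paired reference projection.

    The search starts at (0, 0) for the first frame of a sequence and at
    the previous frame's optimum thereafter (the warm start), which keeps
    the simplex near the solution during slow drifts.
    """
    start = warm_start if warm_start is not None else Shift2D(0.0, 0.0)

    def objective(s: Shift2D) -> float:
        return penalized_objective(ref, live, roi, s, spec, cfg)

    shift, value, converged, rebuilds = downhill_simplex_2d(objective, start, cfg)
    # the penalty keeps any positively scored vertex inside the capture
    # square; clamp covers the degenerate everything-scored-worst case
    shift = Shift2D(
        float(np.clip(shift.x, -cfg.capture_range, cfg.capture_range)),
        float(np.clip(shift.y, -cfg.capture_range, cfg.capture_range)),
    )
    return TrackingResult(
        shift=shift,
        objective=value,
        converged=converged,
        rebuilds_used=rebuilds,
        ref_angle_deg=ref.gantry_deg,
        imr_index=live.index,
    )


def brute_force_register(
    ref: ProjectionImage,
    live: ProjectionImage,
    roi: ROITemplate,
    spec: DetectorSpec,
    grid_step: float = 0.5,
    search_range: float = 5.0,
    zero_mean: bool = False,
) -> tuple[Shift2D, float]:
    """Exhaustive NCC grid search (test oracle; not used by the tracker)."""
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    offsets = np.arange(-search_range, search_range + grid_step / 2, grid_step)
    best_shift, best_val = Shift2D(0.0, 0.0), -np.inf
    for y in offsets:
        for x in offsets:
            s = Shift2D(float(x), float(y))
            v = ncc_objective(ref, live, roi, s, spec, zero_mean=zero_mean)
            if v > best_val:
                best_shift, best_val = s, v
    return best_shift, best_val
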