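"""Phantom evaluation protocol: shift/rotation series and error statistics.

Reproduces, at desk scale on the digital phantom, the test protocol used
to commission the tracker on a physical thorax phantom: a reference scan
at identity pose, intrafraction frames rendered at known couch
shifts/rotations on an IMRT (nine fixed posterior beams, three images
per beam) or VMAT (partial posterior arcs, an image every 15 deg of
travel) delivery schedule, registration of every frame, and aggregation
of the per-axis errors into per-triplet standard deviations, maxima and
95th-percentile statistics.

Ground truth for a 3D couch shift is its beam's-eye-view 2D projection
at each gantry angle; rotation series are scored against the
pure-translation ground truth to quantify how unmodeled rotations
degrade the 2D tracker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .frames import FrameKind
from .geometry import (
    DetectorSpec,
    ReferenceSet,
    ROITemplate,
    Shift2D,
    bev_shift_of_translation,
    pair_reference,
    project_roi,
)
from .phantom import (
    DEFAULT_PHOTONS_AT_AIR,
    NoiseModel,
    PhantomVolume,
    Pose6D,
    build_spine_phantom,
    render_drr,
    simulate_imr,
    target_roi_mask,
)
from .registration import RegistrationConfig, TrackingResult, register

IMRT_GANTRY_ANGLES = (180.0, 160.0, 140.0, 120.0, 100.0, 260.0, 240.0, 220.0, 200.0)


@dataclass(frozen=True)
class IMRTSchedule:
    """Fixed-gantry delivery: nine posterior beams, images triggered by MU.

    MU-based triggering is abstracted to ``images_per_beam`` frames per
    beam (the first fires at beam-on).
    """

    angles: tuple[float, ...] = IMRT_GANTRY_ANGLES
    images_per_beam: int = 3

    def __post_init__(self) -> None:
        if self.images_per_beam < 1:
            raise ValueError("images_per_beam must be >= 1")

    def triggers(self) -> list[tuple[float, int]]:
        """Ordered (gantry_angle, image_index_within_beam) trigger list."""
        return [(a, i) for a in self.angles for i in range(self.images_per_beam)]


@dataclass(frozen=True)
class VMATSchedule:
    """Arc delivery: partial posterior arcs with angle-triggered imaging.

    Each arc runs from ``start`` to ``stop`` degrees (direction given by
    their order; arcs must not cross 0 deg); a frame is triggered at the
    arc start and every ``trigger_interval`` degrees of travel.
    ``expected_images`` records the nominal per-treatment image count of
    the protocol and is metadata only — the actual count follows from
    the arcs.
    """

    arcs: tuple[tuple[float, float], ...]
    trigger_interval: float = 15.0
    expected_images: int = 20

    def __post_init__(self) -> None:
        if self.trigger_interval <= 0:
            raise ValueError("trigger_interval must be positive")

    def trigger_angles(self) -> list[float]:
        out: list[float] = []
        for start, stop in self.arcs:
            travel = abs(stop - start)
            direction = 1.0 if stop >= start else -1.0
            n = int(math.floor(travel / self.trigger_interval)) + 1
            out.extend(start + direction * self.trigger_interval * k for k in range(n))
        return out

    def triggers(self) -> list[tuple[float, int]]:
        return [(a, 0) for a in self.trigger_angles()]


def default_vmat_schedule() -> VMATSchedule:
    """Four partial posterior arcs covering [50, 179] and [290, 181] deg.

    Each angular range is delivered as two arcs split at its midpoint
    (out and back are clinically equivalent here; only trigger angles
    matter to the tracker).
    """
    return VMATSchedule(
        arcs=((50.0, 114.5), (114.5, 179.0), (290.0, 235.5), (235.5, 181.0)),
    )


# ---------------------------------------------------------------------------
# Tracking a posed phantom through a schedule
# ---------------------------------------------------------------------------

RegisterFn = Callable[..., TrackingResult]


class Evaluator:
    """Caches a rendered reference set + projected ROI templates.

    ``n_reference`` noiseless reference projections are rendered at
    identity pose over a full trajectory; ``reference_angles`` instead
    restricts rendering to the listed angles (a shortcut when only a few
    beams will ever be paired).  ROI templates are forward-projected per
    reference angle from a 3D box around the target vertebra expanded by
    ``roi_margin`` mm.
    """

    def __init__(
        self,
        phantom: PhantomVolume | None = None,
        spec: DetectorSpec | None = None,
        reg_cfg: RegistrationConfig | None = None,
        n_reference: int = 90,
        reference_angles: Sequence[float] | None = None,
        render_step: float | None = None,
        photons_at_air: float = DEFAULT_PHOTONS_AT_AIR,
        roi_margin: float = 20.0,
        vertebra_size: float = 25.0,
        pairing_tolerance_deg: float = 0.75,
    ) -> None:
        self.phantom = phantom if phantom is not None else build_spine_phantom()
        self.spec = spec if spec is not None else DetectorSpec().scaled(0.25)
        self.reg_cfg = reg_cfg or RegistrationConfig()
        self.render_step = render_step
        self.photons_at_air = photons_at_air
        self.pairing_tolerance_deg = pairing_tolerance_deg
        self.n_reference = n_reference

        if reference_angles is None:
            from .geometry import angular_spacing

            spacing = angular_spacing(n_reference)
            reference_angles = [i * spacing for i in range(n_reference)]
        self.references = ReferenceSet()
        for i, angle in enumerate(reference_angles):
            frame = render_drr(
                self.phantom,
                Pose6D(),
                angle,
                self.spec,
                step=render_step,
                photons_at_air=photons_at_air,
                kind=FrameKind.CBCT,
                index=i,
            )
            self.references.add(angle, frame)

        self._roi3d = target_roi_mask(
            self.phantom, vertebra_size=vertebra_size, margin=roi_margin
        )
        self._roi_cache: dict[float, ROITemplate] = {}

    def roi(self, angle_deg: float) -> ROITemplate:
        if angle_deg not in self._roi_cache:
            self._roi_cache[angle_deg] = project_roi(
                self._roi3d, self.phantom.spacing, self.phantom.origin, angle_deg, self.spec
            )
        return self._roi_cache[angle_deg]

    def track_pose(
        self,
        pose: Pose6D,
        schedule: IMRTSchedule | VMATSchedule,
        noise: NoiseModel | None = None,
        register_fn: RegisterFn = register,
    ) -> pd.DataFrame:
        """Render and register every scheduled frame at a fixed phantom pose.

        Frames are processed in trigger order with warm-start chaining
        (the first starts at (0, 0), each subsequent one at the previous
        optimum).  When a :class:`NoiseModel` is given, every frame gets
        an independent seed derived from it.  Returns one row per frame
        with the reported shift and score.
        """
        rows = []
        warm: Shift2D | None = None
        for k, (angle, img_i) in enumerate(schedule.triggers()):
            paired = pair_reference(angle, self.references, self.pairing_tolerance_deg)
            if paired is None:
                raise ValueError(f"no reference within pairing tolerance of {angle} deg")
            ref_frame, ref_angle = paired
            frame_noise = (
                None
                if noise is None
                else NoiseModel(noise.photons_at_air, seed=noise.seed + k)
            )
            live = simulate_imr(
                self.phantom,
                pose,
                angle,
                self.spec,
                noise=frame_noise,
                step=self.render_step,
                photons_at_air=self.photons_at_air,
                index=k,
            )
            result = register_fn(
                ref_frame,
                live,
                self.roi(ref_angle),
                self.spec,
                self.reg_cfg,
                warm_start=warm,
            )
            warm = result.shift
            rows.append(
                {
                    "beam": angle,
                    "image": img_i,
                    "x_mm": result.shift.x,
                    "y_mm": result.shift.y,
                    "ncc": result.objective,
                    "converged": result.converged,
                }
            )
        return pd.DataFrame(rows)


def _error_rows(
    tracked: pd.DataFrame,
    translation: Sequence[float],
    spec: DetectorSpec,
    test: str,
) -> list[dict]:
    rows = []
    for _, r in tracked.iterrows():
        truth = bev_shift_of_translation(translation, r["beam"], spec)
        for axis, reported, expected in (
            ("x", r["x_mm"], truth.x),
            ("y", r["y_mm"], truth.y),
        ):
            rows.append(
                {
                    "test": test,
                    "beam": r["beam"],
                    "image": int(r["image"]),
                    "axis": axis,
                    "error": reported - expected,
                }
            )
    return rows


def run_translation_series(
    evaluator: Evaluator,
    shifts: Sequence[Sequence[float]],
    schedule: IMRTSchedule | VMATSchedule | None = None,
    noise: NoiseModel | None = None,
    register_fn: RegisterFn = register,
) -> pd.DataFrame:
    """Track the phantom at each pure 3D translation; return per-frame errors.

    ``shifts`` is a sequence of (lateral, longitudinal, vertical) couch
    shifts in mm.  Errors are reported - ground truth, per axis, where
    ground truth is the beam's-eye-view projection of the applied shift.
    """
    schedule = schedule or IMRTSchedule()
    rows: list[dict] = []
    for case_i, t3 in enumerate(shifts):
        pose = Pose6D(t_lat=t3[0], t_long=t3[1], t_vert=t3[2])
        case_noise = (
            None
            if noise is None
            else NoiseModel(noise.photons_at_air, seed=noise.seed + 1000 * case_i)
        )
        tracked = evaluator.track_pose(pose, schedule, noise=case_noise, register_fn=register_fn)
        label = f"shift_{t3[0]:g}_{t3[1]:g}_{t3[2]:g}"
        rows.extend(_error_rows(tracked, t3, evaluator.spec, label))
    return pd.DataFrame(rows)


def run_rotation_series(
    evaluator: Evaluator,
    degrees: Sequence[float],
    axis: str,
    base_shift: Sequence[float] = (5.0, 5.0, 5.0),
    schedule: IMRTSchedule | VMATSchedule | None = None,
    noise: NoiseModel | None = None,
    register_fn: RegisterFn = register,
) -> pd.DataFrame:
    """Add rotations about one axis to a base 3D shift and track.

    ``axis`` is ``rotation`` (yaw, about vertical), ``pitch`` (about
    lateral) or ``roll`` (about longitudinal).  Errors are computed
    against the pure-translation ground truth — i.e. as if no rotation
    had been applied — quantifying the 2D tracker's rotation tolerance.
    """
    if axis not in ("rotation", "pitch", "roll"):
        raise ValueError("axis must be one of rotation|pitch|roll")
    schedule = schedule or IMRTSchedule()
    rows: list[dict] = []
    for case_i, deg in enumerate(degrees):
        pose = Pose6D(
            t_lat=base_shift[0],
            t_long=base_shift[1],
            t_vert=base_shift[2],
            **{axis: deg},
        )
        case_noise = (
            None
            if noise is None
            else NoiseModel(noise.photons_at_air, seed=noise.seed + 1000 * case_i)
        )
        tracked = evaluator.track_pose(pose, schedule, noise=case_noise, register_fn=register_fn)
        rows.extend(_error_rows(tracked, base_shift, evaluator.spec, f"{axis}_{deg:g}deg"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The 50-test repeatability matrix
# ---------------------------------------------------------------------------

def repeatability_cases() -> list[tuple[str, Pose6D]]:
    """The 50-test matrix: 5 translation cases x (none + 3 axes x 3 angles).

    Translation cases: zero shift, 5 mm superior-inferior, 5 mm
    anterior-posterior, 5 mm right-left, and 5 mm along all three axes;
    each repeated with no rotation and with 1, 2, 3 deg of rotation,
    pitch and roll.
    """
    translations = [
        ("none", (0.0, 0.0, 0.0)),
        ("si5", (0.0, 5.0, 0.0)),
        ("ap5", (0.0, 0.0, 5.0)),
        ("rl5", (5.0, 0.0, 0.0)),
        ("all5", (5.0, 5.0, 5.0)),
    ]
    variants: list[tuple[str, dict]] = [("rot0", {})]
    for axis in ("rotation", "pitch", "roll"):
        for deg in (1.0, 2.0, 3.0):
            variants.append((f"{axis}{deg:g}", {axis: deg}))
    cases = []
    for t_name, t3 in translations:
        for v_name, kw in variants:
            cases.append(
                (
                    f"{t_name}_{v_name}",
                    Pose6D(t_lat=t3[0], t_long=t3[1], t_vert=t3[2], **kw),
                )
            )
    return cases


TrackCaseFn = Callable[[str, Pose6D, IMRTSchedule], pd.DataFrame]


def run_repeatability_suite(
    evaluator: Evaluator | None = None,
    schedule: IMRTSchedule | None = None,
    noise: NoiseModel | None = None,
    track_case_fn: TrackCaseFn | None = None,
) -> pd.DataFrame:
    """Run all 50 repeatability tests; return the pooled error table.

    ``track_case_fn(case_id, pose, schedule) -> errors`` may replace the
    default render-and-register pipeline (e.g. for bookkeeping checks of
    the statistics layer).
    """
    schedule = schedule or IMRTSchedule()
    rows = []
    for case_i, (case_id, pose) in enumerate(repeatability_cases()):
        if track_case_fn is not None:
            df = track_case_fn(case_id, pose, schedule)
        else:
            if evaluator is None:
                raise ValueError("an Evaluator is required without a track_case_fn")
            case_noise = (
                None
                if noise is None
                else NoiseModel(noise.photons_at_air, seed=noise.seed + 1000 * case_i)
            )
            tracked = evaluator.track_pose(pose, schedule, noise=case_noise)
            df = pd.DataFrame(
                _error_rows(tracked, pose.translation, evaluator.spec, case_id)
            )
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def nearest_rank_percentile(values: Sequence[float], pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    k = max(int(math.ceil(pct / 100.0 * v.size)), 1)
    return float(v[k - 1])


@dataclass(frozen=True)
class ErrorStats:
    """Aggregate tracking-error statistics.

    ``triplet_std`` holds one sample standard deviation (divisor n-1)
    per (test, beam, axis) group of repeated images; ``max_abs`` and
    ``p95_abs`` are maxima / nearest-rank 95th percentiles of |error|
    per axis and pooled over both ("both").
    """

    triplet_std: pd.DataFrame
    max_abs: dict[str, float]
    p95_abs: dict[str, float]
    n_errors: int

    def __post_init__(self) -> None:
        for key in self.p95_abs:
            assert self.p95_abs[key] <= self.max_abs[key] + 1e-12

    def summary_frame(self) -> pd.DataFrame:
        """Two-row table mirroring a max / 95th-percentile report."""
        cols = ["x", "y", "both"]
        return pd.DataFrame(
            {
                c: [self.max_abs[c], self.p95_abs[c]]
                for c in cols
            },
            index=["max_mm", "p95_mm"],
        )


def compute_error_stats(errors: pd.DataFrame) -> ErrorStats:
    """Aggregate an error table into :class:`ErrorStats`.

    ``errors`` needs columns ``beam``, ``axis``, ``error`` and
    optionally ``test`` (defaulting to a single test) and ``image``.
    """
    if errors.empty:
        raise ValueError("empty error table")
    df = errors.copy()
    if "test" not in df.columns:
        df["test"] = "test0"

    triplet_std = (
        df.groupby(["test", "beam", "axis"], sort=True)["error"]
        .std(ddof=1)
        .reset_index()
        .rename(columns={"error": "std"})
    )

    abs_err = df["error"].abs()
    max_abs: dict[str, float] = {}
    p95_abs: dict[str, float] = {}
    for axis in ("x", "y"):
        sel = abs_err[df["axis"] == axis]
        if len(sel):
            max_abs[axis] = float(sel.max())
            p95_abs[axis] = nearest_rank_percentile(sel, 95.0)
    max_abs["both"] = float(abs_err.max())
    p95_abs["both"] = nearest_rank_percentile(abs_err, 95.0)
    return ErrorStats(
        triplet_std=triplet_std,
        max_abs=max_abs,
        p95_abs=p95_abs,
        n_errors=len(df),
    )


# ---------------------------------------------------------------------------
# Desk-scale acceptance analogs
# ---------------------------------------------------------------------------

TRANSLATION_SHIFT_MAGNITUDES = (0.0, 0.6, 1.2, 1.8, 2.4, 3.0)


def all_axes_shifts(magnitudes: Sequence[float]) -> list[tuple[float, float, float]]:
    return [(m, m, m) for m in magnitudes]


def translation_series_analog(
    evaluator: Evaluator,
    magnitudes: Sequence[float] = TRANSLATION_SHIFT_MAGNITUDES,
) -> tuple[ErrorStats, pd.DataFrame]:
    """Noiseless all-axes translation series on the IMRT schedule."""
    errors = run_translation_series(evaluator, all_axes_shifts(magnitudes))
    return compute_error_stats(errors), errors


def rotation_tolerance_analog(
    evaluator: Evaluator,
    rotation_deg: float = 1.0,
    base_shift: Sequence[float] = (5.0, 5.0, 5.0),
) -> tuple[ErrorStats, pd.DataFrame]:
    """Unmodeled yaw added to a 5 mm all-axes shift, IMRT schedule."""
    errors = run_rotation_series(
        evaluator, [rotation_deg], "rotation", base_shift=base_shift
    )
    return compute_error_stats(errors), errors


def plot_error_vs_gantry(errors: pd.DataFrame, path: str) -> None:
    """Scatter per-axis errors against gantry angle (protocol-style figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for axis, marker in (("x", "o"), ("y", "s")):
        sel = errors[errors["axis"] == axis]
        ax.scatter(sel["beam"], sel["error"], s=12, marker=marker, label=f"{axis} (mm)")
    ax.set_xlabel("gantry angle (deg)")
    ax.set_ylabel("tracking error (mm)")
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
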