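"""Synthetic thorax/spine phantom and cone-beam DRR renderer.

Stands in for an anthropomorphic thorax phantom imaged by a linac's
on-board kV imager: an elliptic-cylinder soft-tissue body containing a
longitudinal column of high-attenuation vertebra-like blocks.  DRRs
(digitally reconstructed radiographs) are rendered by casting a ray from
the source through each detector pixel, integrating the linear
attenuation coefficient along the ray (trapezoid rule at a step no
larger than half a voxel) and applying Beer–Lambert attenuation to a
nominal air-level photon count.  Optional Poisson noise emulates quantum
mottle.

The phantom pose is a rigid 6-DoF transform applied about the isocenter
(yaw about the vertical axis, then pitch about the lateral axis, then
roll about the longitudinal axis, then translation); rays are sampled in
world coordinates and the sample points inverse-transformed into the
static attenuation grid, so no volume resampling occurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frames import FrameKind, ProjectionImage
from .geometry import DetectorSpec, detector_axes, pixel_pitch, source_position

DEFAULT_PHOTONS_AT_AIR = 50000.0


@dataclass(frozen=True)
class Pose6D:
    """Rigid phantom pose: translations in mm, rotations in degrees.

    ``rotation`` is yaw about the vertical axis, ``pitch`` about the
    lateral axis, ``roll`` about the longitudinal axis, applied in that
    order about the isocenter, followed by the translation.
    """

    t_lat: float = 0.0
    t_long: float = 0.0
    t_vert: float = 0.0
    rotation: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.t_lat, self.t_long, self.t_vert], dtype=float)

    def rotation_matrix(self) -> np.ndarray:
        """World = R @ phantom + t, with R = R_roll @ R_pitch @ R_yaw."""
        yaw = np.deg2rad(self.rotation)
        pit = np.deg2rad(self.pitch)
        rol = np.deg2rad(self.roll)
        cz, sz = np.cos(yaw), np.sin(yaw)
        r_yaw = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])  # about z (vertical)
        cx, sx = np.cos(pit), np.sin(pit)
        r_pitch = np.array([[1.0, 0.0, 0.0], [0.0, cx, -sx], [0.0, sx, cx]])  # about x (lateral)
        cy, sy = np.cos(rol), np.sin(rol)
        r_roll = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])  # about y (longitudinal)
        return r_roll @ r_pitch @ r_yaw


IDENTITY_POSE = Pose6D()


@dataclass(frozen=True)
class NoiseModel:
    """Poisson quantum noise; ``photons_at_air`` is the unattenuated count."""

    photons_at_air: float = DEFAULT_PHOTONS_AT_AIR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons_at_air <= 0:
            raise ValueError("photons_at_air must be positive")


@dataclass
class PhantomVolume:
    """Voxelized linear-attenuation volume.

    ``mu`` is indexed ``[ix, iy, iz]`` along the lateral, longitudinal
    and vertical patient axes; ``origin`` is the position (mm, patient
    coords) of voxel center ``(0, 0, 0)`` relative to the isocenter.
    """

    mu: np.ndarray              # 1/mm
    spacing: float              # mm, isotropic
    origin: np.ndarray          # mm, 3-vector

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.ndim != 3:
            raise ValueError("mu must be a 3D grid")
        if np.any(self.mu < 0):
            raise ValueError("attenuation coefficients must be non-negative")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mu.shape  # type: ignore[return-value]

    def bounding_radius(self) -> float:
        """Max distance from the isocenter to any grid corner, mm."""
        extent = (np.array(self.shape) - 1) * self.spacing
        corners = np.array(
            [self.origin + extent * np.array(b) for b in np.ndindex(2, 2, 2)]
        )
        return float(np.linalg.norm(corners, axis=1).max())


def build_spine_phantom(
    n_vertebrae: int = 5,
    vertebra_mu: float = 0.06,
    tissue_mu: float = 0.02,
    body_radius: float = 80.0,
    vertebra_size: float = 25.0,
    disc_gap: float = 5.0,
    spacing: float = 2.0,
) -> PhantomVolume:
    """Build the default thorax-like digital phantom.

    An elliptic-cylinder soft-tissue body (lateral semi-axis
    ``body_radius``, vertical semi-axis ``0.65 * body_radius``) runs
    along the longitudinal axis.  Inside it, ``n_vertebrae`` cubic
    vertebral bodies of edge ``vertebra_size`` with small posterior
    spinous-process flanges are stacked with ``disc_gap`` of soft tissue
    between them; the column is centered so the middle vertebra sits at
    the isocenter (the tracking target).  Attenuation takes exactly the
    values {0, tissue_mu, vertebra_mu}.
    """
    if min(vertebra_size, disc_gap, body_radius, spacing) <= 0:
        raise ValueError("dimensions must be positive")
    if n_vertebrae > 0 and vertebra_mu <= tissue_mu:
        raise ValueError("vertebra_mu must exceed tissue_mu")

    a = body_radius                 # lateral semi-axis
    b = 0.65 * body_radius          # vertical semi-axis
    period = vertebra_size + disc_gap
    column_half = (n_vertebrae * period - disc_gap) / 2.0 if n_vertebrae else 0.0
    half_x = a + 2 * spacing
    half_y = max(column_half, vertebra_size) + 3 * spacing
    half_z = b + 2 * spacing

    nx = int(np.ceil(2 * half_x / spacing)) + 1
    ny = int(np.ceil(2 * half_y / spacing)) + 1
    nz = int(np.ceil(2 * half_z / spacing)) + 1
    origin = -spacing * (np.array([nx, ny, nz]) - 1) / 2.0

    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs = origin[2] + spacing * np.arange(nz)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")

    mu = np.zeros((nx, ny, nz))
    body = (gx / a) ** 2 + (gz / b) ** 2 <= 1.0
    mu[body] = tissue_mu

    if n_vertebrae > 0:
        centers = (np.arange(n_vertebrae) - (n_vertebrae - 1) / 2.0) * period
        if column_half > half_y or vertebra_size / 2 > min(a, b):
            raise ValueError("vertebral column does not fit inside the body grid")
        half = vertebra_size / 2.0
        for yc in centers:
            in_y = np.abs(gy - yc) <= half
            vert_body = in_y & (np.abs(gx) <= half) & (np.abs(gz) <= half)
            # posterior spinous-process flange (posterior = -z)
            flange = (
                in_y
                & (np.abs(gy - yc) <= 0.3 * vertebra_size)
                & (np.abs(gx) <= 0.2 * vertebra_size)
                & (gz < -half)
                & (gz >= -half - 0.6 * vertebra_size)
            )
            mu[vert_body | flange] = vertebra_mu

    return PhantomVolume(mu=mu, spacing=spacing, origin=origin)


def target_roi_mask(
    phantom: PhantomVolume, vertebra_size: float = 25.0, margin: float = 20.0
) -> np.ndarray:
    """3D box mask around the isocenter vertebra expanded by ``margin`` mm.

    Emulates the clinical ROI: the contoured target vertebra expanded
    isotropically (2 cm by default) before forward projection.
    """
    half = vertebra_size / 2.0 + margin
    idx = np.indices(phantom.shape)
    pts = phantom.origin[:, None, None, None] + phantom.spacing * idx
    return (
        (np.abs(pts[0]) <= half) & (np.abs(pts[1]) <= half) & (np.abs(pts[2]) <= half)
    )


# ---------------------------------------------------------------------------
# DRR rendering
# ---------------------------------------------------------------------------

def render_drr(
    phantom: PhantomVolume,
    pose: Pose6D,
    gantry_deg: float,
    spec: DetectorSpec,
    noise: NoiseModel | None = None,
    step: float | None = None,
    photons_at_air: float = DEFAULT_PHOTONS_AT_AIR,
    kind: FrameKind = FrameKind.CBCT,
    beam_on: bool = False,
    index: int = 0,
) -> ProjectionImage:
    """Render one cone-beam DRR of the posed phantom.

    For each detector pixel a ray is cast from the source; the path
    integral of ``mu`` is accumulated by the trapezoid rule with a step
    of ``step`` mm (default half a voxel), sampling the static grid at
    inverse-posed ray points with trilinear interpolation.  Intensity is
    ``photons * exp(-integral)``; Poisson noise is applied when a
    :class:`NoiseModel` is given (which then also sets the photon level).
    """
    if step is None:
        step = 0.5 * phantom.spacing
    if noise is not None:
        photons_at_air = noise.photons_at_air

    src = source_position(gantry_deg, spec)
    d_axis, u_axis, v_axis = detector_axes(gantry_deg)
    pitch = pixel_pitch(spec)
    cc, cr = spec.center_px

    cols = (np.arange(spec.n_cols) - cc) * pitch
    rows = (np.arange(spec.n_rows) - cr) * pitch
    u_mm, v_mm = np.meshgrid(cols, rows)                      # (n_rows, n_cols)
    det_pts = (
        src
        + spec.sid * d_axis
        + u_mm[..., None] * u_axis
        + v_mm[..., None] * v_axis
    )
    dirs = det_pts - src
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    dirs = dirs.reshape(-1, 3)

    # sample range: a symmetric window about the isocenter depth that is
    # guaranteed to contain the posed volume
    radius = phantom.bounding_radius() + float(np.linalg.norm(pose.translation)) + 2 * phantom.spacing
    t0, t1 = spec.sad - radius, spec.sad + radius
    n_steps = max(int(np.ceil((t1 - t0) / step)) + 1, 2)
    ts = np.linspace(t0, t1, n_steps)
    dt = ts[1] - ts[0]
    weights = np.full(n_steps, dt)
    weights[0] = weights[-1] = 0.5 * dt

    rot = pose.rotation_matrix()
    trans = pose.translation
    inv_spacing = 1.0 / phantom.spacing

    path = np.zeros(dirs.shape[0])
    for t, w in zip(ts, weights):
        world = src + t * dirs                                 # (N, 3)
        local = (world - trans) @ rot                          # R^T applied to rows
        coords = ((local - phantom.origin) * inv_spacing).T    # (3, N)
        mu = ndimage.map_coordinates(phantom.mu, coords, order=1, cval=0.0)
        path += w * mu

    intensity = photons_at_air * np.exp(-path).reshape(spec.n_rows, spec.n_cols)
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        intensity = rng.poisson(intensity).astype(float)

    return ProjectionImage(
        pixels=intensity,
        gantry_deg=gantry_deg,
        kind=kind,
        beam_on=beam_on,
        index=index,
    )


def simulate_cbct(
    phantom: PhantomVolume,
    spec: DetectorSpec,
    n_projections: int = 895,
    noise: NoiseModel | None = None,
    step: float | None = None,
    photons_at_air: float = DEFAULT_PHOTONS_AT_AIR,
):
    """Render a full-trajectory reference scan at identity pose.

    ``n_projections`` DRRs at equally spaced angles covering 360 deg
    (starting at 0).  Returns a :class:`~vertetrack.geometry.ReferenceSet`
    keyed by angle.
    """
    from .geometry import ReferenceSet, angular_spacing

    if n_projections < 1:
        raise ValueError("need at least one projection")
    spacing = angular_spacing(n_projections)
    refs = ReferenceSet()
    for i in range(n_projections):
        frame_noise = (
            None
            if noise is None
            else NoiseModel(noise.photons_at_air, seed=noise.seed + i)
        )
        frame = render_drr(
            phantom,
            IDENTITY_POSE,
            gantry_deg=i * spacing,
            spec=spec,
            noise=frame_noise,
            step=step,
            photons_at_air=photons_at_air,
            kind=FrameKind.CBCT,
            index=i,
        )
        refs.add(i * spacing, frame)
    return refs


def simulate_imr(
    phantom: PhantomVolume,
    pose: Pose6D,
    gantry_deg: float,
    spec: DetectorSpec,
    beam_on: bool = True,
    noise: NoiseModel | None = None,
    step: float | None = None,
    photons_at_air: float = DEFAULT_PHOTONS_AT_AIR,
    index: int = 0,
) -> ProjectionImage:
    """Render a single intrafraction kV frame of the posed phantom."""
    return render_drr(
        phantom,
        pose,
        gantry_deg,
        spec,
        noise=noise,
        step=step,
        photons_at_air=photons_at_air,
        kind=FrameKind.IMR,
        beam_on=beam_on,
        index=index,
    )
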