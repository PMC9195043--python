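"""On-disk formats: 16-bit TIFF projections, PNG ROI masks, CSV manifests, YAML config."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .frames import FilterConfig, FrameKind, ProjectionImage
from .geometry import DetectorSpec, ROITemplate, ReferenceSet
from .registration import RegistrationConfig

UINT16_MAX = 65535


def write_projection(path: str | Path, frame: ProjectionImage) -> None:
    """Write a projection as 16-bit TIFF (intensities clipped to the range)."""
    data = np.clip(np.rint(frame.pixels), 0, UINT16_MAX).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_projection(
    path: str | Path,
    gantry_deg: float,
    kind: FrameKind = FrameKind.CBCT,
    beam_on: bool = False,
    index: int = 0,
) -> ProjectionImage:
    return ProjectionImage(
        pixels=tifffile.imread(str(path)).astype(float),
        gantry_deg=gantry_deg,
        kind=kind,
        beam_on=beam_on,
        index=index,
    )


def write_reference_set(
    directory: str | Path,
    refs: ReferenceSet,
    roi: ROITemplate | None = None,
    filter_cfg: FilterConfig | None = None,
) -> Path:
    """Write references as TIFFs plus a CSV manifest.

    Manifest columns: index, filename, angle_deg, mean_roi_intensity
    (NaN when no ROI is supplied), qualified.
    """
    from .frames import mean_roi_intensity, qualify_cbct

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = filter_cfg or FilterConfig()
    rows = []
    for i, (angle, frame) in enumerate(refs):
        fname = f"proj_{i:04d}.tif"
        write_projection(directory / fname, frame)  # type: ignore[arg-type]
        mean = float("nan")
        qualified = True
        if roi is not None:
            mean = mean_roi_intensity(frame, roi)  # type: ignore[arg-type]
            qualified = qualify_cbct(frame, roi, cfg)  # type: ignore[arg-type]
        rows.append(
            {
                "index": i,
                "filename": fname,
                "angle_deg": angle,
                "mean_roi_intensity": mean,
                "qualified": qualified,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_reference_set(directory: str | Path, qualified_only: bool = True) -> ReferenceSet:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    refs = ReferenceSet()
    for _, row in manifest.iterrows():
        if qualified_only and not bool(row["qualified"]):
            continue
        frame = read_projection(
            directory / row["filename"],
            gantry_deg=float(row["angle_deg"]),
            kind=FrameKind.CBCT,
            index=int(row["index"]),
        )
        refs.add(float(row["angle_deg"]), frame)
    return refs


# ---------------------------------------------------------------------------
# ROI templates: 1-bit PNG + JSON sidecar, filenames angle-sorted
# ---------------------------------------------------------------------------

def _roi_stem(angle_deg: float) -> str:
    return f"roi_{angle_deg:07.2f}"


def write_roi_templates(
    directory: str | Path,
    templates: Sequence[ROITemplate],
    spec: DetectorSpec,
) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in templates:
        stem = _roi_stem(t.angle_deg)
        png = directory / f"{stem}.png"
        iio.imwrite(png, (t.mask.astype(np.uint8) * 255))
        sidecar = {
            "angle_deg": t.angle_deg,
            "plan_id": t.plan_id,
            "detector": {
                "n_cols": spec.n_cols,
                "n_rows": spec.n_rows,
                "active_width": spec.active_width,
                "active_height": spec.active_height,
                "sid": spec.sid,
                "sad": spec.sad,
            },
        }
        (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
        paths.append(png)
    return sorted(paths)


def read_roi_templates(directory: str | Path) -> tuple[list[ROITemplate], DetectorSpec]:
    directory = Path(directory)
    templates = []
    spec: DetectorSpec | None = None
    for png in sorted(directory.glob("roi_*.png")):
        meta = json.loads(png.with_suffix(".json").read_text())
        mask = np.asarray(iio.imread(png)) > 0
        templates.append(
            ROITemplate(
                mask=mask, angle_deg=float(meta["angle_deg"]), plan_id=meta.get("plan_id", "")
            )
        )
        spec = DetectorSpec(**meta["detector"])
    if not templates or spec is None:
        raise FileNotFoundError(f"no ROI templates found in {directory}")
    return templates, spec


def read_roi_mask(path: str | Path, angle_deg: float = 0.0) -> ROITemplate:
    """Read a single mask PNG without requiring a sidecar."""
    return ROITemplate(mask=np.asarray(iio.imread(path)) > 0, angle_deg=angle_deg)


# ---------------------------------------------------------------------------
# Frame-stream manifest (raw grabbed frames)
# ---------------------------------------------------------------------------

def read_frame_stream(directory: str | Path) -> list[ProjectionImage]:
    """Read a grabbed-frame stream: TIFFs + frames.csv manifest.

    Manifest columns: index, filename, angle_deg, kind (cbct|imr), beam_on.
    Frames are returned in index order.
    """
    directory = Path(directory)
    manifest = pd.read_csv(directory / "frames.csv").sort_values("index")
    frames = []
    for _, row in manifest.iterrows():
        frames.append(
            read_projection(
                directory / row["filename"],
                gantry_deg=float(row["angle_deg"]),
                kind=FrameKind(str(row["kind"]).lower()),
                beam_on=bool(row["beam_on"]),
                index=int(row["index"]),
            )
        )
    return frames


def write_frame_stream(directory: str | Path, frames: Sequence[ProjectionImage]) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for frame in frames:
        fname = f"frame_{frame.index:04d}.tif"
        write_projection(directory / fname, frame)
        rows.append(
            {
                "index": frame.index,
                "filename": fname,
                "angle_deg": frame.gantry_deg,
                "kind": frame.kind.value,
                "beam_on": frame.beam_on,
            }
        )
    manifest = directory / "frames.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML config with optional detector/filter/registration sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {
        "detector": DetectorSpec(**raw.get("detector", {})),
        "filters": FilterConfig(**raw.get("filters", {})),
        "registration": RegistrationConfig(**raw.get("registration", {})),
    }
    out["tolerance_mm"] = float(raw.get("tolerance_mm", 2.0))
    return out
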