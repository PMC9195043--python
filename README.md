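# vertetrack

Markerless 2D tracking of vertebral position during paraspinal
stereotactic body radiotherapy (SBRT), for medical physicists and
researchers commissioning intrafraction motion monitoring.

Spine SBRT delivers ablative doses in 1–3 fractions and tolerates only a
few millimeters of intrafraction motion. The vertebrae themselves are
excellent high-contrast landmarks, so no implanted fiducials are
needed: each intrafraction kV image (IMR — intrafraction motion review)
acquired by the linac's on-board imager is registered against the raw
projection, at the nearest gantry angle, of a cone-beam CT scan taken
the same day immediately before delivery. Using same-day CBCT
projections (rather than planning-CT DRRs) as the template means the
reference shares the kV chain's intensity response and systematic
errors, and reflects the actual daily setup.

## Method

The tracked quantity is the 2D shift (x lateral, y longitudinal) in the
beam's-eye view at the isocenter plane. It maximizes normalized
cross-correlation over the per-angle tracking ROI:

```
Obj(x, y) = ⟨T₂D(x, y) Proj_r, Proj_i⟩ / (‖T₂D(x, y) Proj_r‖ · ‖Proj_i‖)
```

where `Proj_r` is the paired reference projection (within 0.75° of the
IMR gantry angle), `Proj_i` the live frame, and `T₂D` a bilinear
translation by the detector-plane equivalent of the candidate shift
(magnification SID/SAD = 1.5). The score lies in [0, 1]. It is
maximized by a classical 2D downhill simplex on the sign-flipped
objective: initial simplex `{(x₀,y₀), (x₀+Δs,y₀), (x₀,y₀+Δs)}` with
Δs = 2 mm; warm start (x₀,y₀) = (0,0) for the first frame and the
previous optimum thereafter; stop when the relative spread
`2|Obj_H − Obj_L|/(Obj_H + Obj_L) < σ = 10⁻⁶`; after N = 20 iterations
the simplex rebuilds at its current best with step Δs, up to n = 4
times. Candidate shifts beyond the 2 cm capture range score the worst
value, confining the search.

The package also ships a digital thorax/spine phantom with a cone-beam
DRR renderer (SID 150 cm, SAD 100 cm, 1024 × 768 panel with a
39.7 × 29.8 cm active area), frame-qualification filters, a headless
four-mode session state machine (IDLE → CBCT → EDIT_ROI → TRACKING) and
an evaluation harness reproducing the commissioning protocol (IMRT and
VMAT schedules, translation/rotation series, per-triplet standard
deviations, maxima and 95th-percentile errors). See
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

```python
import numpy as np
from vertetrack import (
    DetectorSpec, Pose6D, build_spine_phantom, target_roi_mask,
    project_roi, render_drr, simulate_imr, register, bev_shift_of_translation,
)

spec = DetectorSpec().scaled(0.25)          # 256x192 panel, full active area
phantom = build_spine_phantom()             # 5-vertebra digital thorax

# reference projection at the posterior beam and its ROI template
ref = render_drr(phantom, Pose6D(), gantry_deg=180.0, spec=spec)
roi = project_roi(target_roi_mask(phantom), phantom.spacing,
                  phantom.origin, 180.0, spec)

# intrafraction frame after a 3 mm lateral / 2 mm superior couch shift
couch = (3.0, 2.0, 0.0)
live = simulate_imr(phantom, Pose6D(*couch), gantry_deg=180.0, spec=spec)

result = register(ref, live, roi, spec)
truth = bev_shift_of_translation(couch, 180.0, spec)
print(f"reported shift: x={result.shift.x:+.3f} mm, y={result.shift.y:+.3f} mm")
print(f"ground truth:   x={truth.x:+.3f} mm, y={truth.y:+.3f} mm")
print(f"NCC={result.objective:.6f}  converged={result.converged}")
```

prints

```
reported shift: x=-3.008 mm, y=+2.013 mm
ground truth:   x=-3.000 mm, y=+2.000 mm
NCC=0.999989  converged=True
```

A +3 mm lateral couch shift reads −3 mm in the beam's-eye view at
gantry 180° (the posterior beam looks up at the patient), and the
tracker recovers both components to ~0.01 mm on the noiseless phantom.

The same pipeline is available from the shell:

```
vertetrack simulate --out data --shift 2 0 0 --noise-seed 7
vertetrack qualify  --stream data/stream --roi data/roi
vertetrack track    --refs data/refs --stream data/stream --roi data/roi \
                    --tolerance 2.0 --out log.csv
vertetrack evaluate --suite imrt_translation --out results/
```

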