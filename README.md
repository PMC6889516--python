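# embryoheart

Quantitative 4D analysis of the tubular embryonic heart: boundary tracking
from time-resolved volumetric image series, chamber function metrics, and
hemodynamic post-processing.

At early looping stages (around HH25 in avian embryos) the heart is a bent
muscular tube whose chambers contract by large fractions of their volume each
cycle. 4D imaging (e.g. high-frequency ultrasound reconstructed over the
cardiac cycle) yields an image series `I(x, t)`; the scientific questions are
how much blood each structure moves (stroke volume, ejection fraction), how
the wall deforms (area stretch), what forces the blood exerts on the wall
(wall shear stress and its oscillatory index), how much work ejection costs,
and where blood stagnates (virtual-tracer retention, e.g. in atrial
appendages).

## What the package does

- **`core_io`** — typed containers and readers/writers for 4D images
  (NIfTI / TIFF / NRRD), triangulated surfaces with per-face structure labels
  (PLY / STL / VTK), displacement fields, dense field series (velocity, WSS),
  waveforms (CSV), and the cyclic motion model (NPZ).
- **`registration`** — pairwise free-form deformation (B-spline lattice,
  default 0.1 mm knot spacing) image registration with SSD or mutual-
  information similarity and a bending-energy regularizer; consecutive frame
  pairs are composed into frame-0-referenced fields around the full cardiac
  ring (forward and backward through the inverted wrap-around pair, which
  halves accumulated drift).
- **`motion_model`** — a cyclic motion model, Fourier in time (K harmonics)
  and B-spline in space, least-squares fitted to the composed fields; any
  surface can then be tracked continuously through the cycle.
- **`segmentation`** — intensity thresholding with largest-component and
  hole-filling cleanup, marching-cubes surface extraction, and a
  physiology-driven threshold search: the candidate whose implied
  atrioventricular-junction velocity best matches an independent reference
  (e.g. Doppler) wins.
- **`cardiac_metrics`** — watertight mesh volumes (per structure label),
  volume waveforms, stroke volume and ejection fraction, per-face area
  stretch and stretch rate.
- **`hemodynamics`** — oscillatory shear index, per-structure WSS summaries,
  flow rate through a plane, ejection work from exact swept-volume flux
  quadrature (`W = ∮∮ p v·n dA dt`), pressure-volume loops, Reynolds numbers
  (blood viscosity 0.0015 Pa·s).
- **`particles`** — virtual tracer seeding (default 500 particles), RK4
  advection through the periodic velocity field, per-structure retention
  after each of (default) 5 cycles.
- **`phantom`** — analytic test objects with exactly known motion, volumes,
  velocities and wall shear: a contracting thick-walled ellipsoid image
  phantom, a Poiseuille tube bench, and a channel-with-appendage flow for
  retention studies.
- **`cli`** — a `click` pipeline (`embryoheart pipeline|demo|<stage>`) that
  chains phantom → registration → motion fit → threshold search → tracking →
  metrics → hemodynamics → particles with per-stage caching and pinned-format
  JSON reports.

## Worked example

The self-validating experiment: generate a contracting-ellipsoid phantom
(contraction amplitude α = 0.25, 40³ voxels at 0.036 mm, 12 frames over a
0.48 s cycle, Gaussian intensity noise), register neighbouring frames, fit a
K = 2 motion model, track the true end-diastolic endocardial surface, and
compare against the analytic ground truth:

```python
import numpy as np, trimesh
from embryoheart.phantom import PhantomSpec, render_image_series
from embryoheart.registration import RegistrationConfig, register_cycle, compose_chain
from embryoheart.motion_model import fit_motion_model, track_surface
from embryoheart.core_io import TrackedSurface
from embryoheart.cardiac_metrics import volume_waveform, stroke_and_ef

spec = PhantomSpec(alpha=0.25, grid_shape=(40, 40, 40), spacing=0.036,
                   n_frames=12, noise_seed=2)
img = render_image_series(spec)
cfg = RegistrationConfig(grid_spacing=0.1, max_iterations=150, pyramid_levels=3)
chain = compose_chain(register_cycle(img, cfg))          # ~2 min on one core
model, _ = fit_motion_model(chain, spec.cycle_duration,
                            n_frames=spec.n_frames, n_harmonics=2)
ico = trimesh.creation.icosphere(subdivisions=3)
surf = TrackedSurface(
    vertices0=spec.center + np.asarray(ico.vertices) * np.array(spec.semi_axes),
    faces=np.asarray(ico.faces))
tracked = track_surface(surf, model, spec.frame_times)
vol = volume_waveform(tracked)
sv, ef = stroke_and_ef(vol)
```

Measured on this configuration: the tracked volume waveform (normalized to
its end-diastolic value) deviates from the analytic waveform by at most
**1.4–1.6 %** across the cycle (noise-seed dependent), and the measured
ejection fraction is **0.584** against the closed form
`1 − (1 − α)³ = 0.578`. Other headline oracle results, from
`results/acceptance.json`:

| quantity | measured | expected |
|---|---|---|
| motion-model refit coefficient RMS | 4.6e-16 | < 1e-8 |
| 2-voxel sinusoidal warp, mean endpoint error | 0.014 voxels | < 0.5 |
| OSI: steady / sinusoidal / 75-25 reversal | 0 / 0.5 / 0.25 | 0 / 0.5 / 0.25 |
| ejection work vs `P·ΔV` | 2e-15 relative | < 1 % |
| Poiseuille mean WSS vs `4μQ/(πR³)` | 5e-7 relative | < 1 % |
| RK4 advection convergence order | 4.00 | 4 |
| appendage vs channel retention after 5 cycles | 0.98 vs 0.00 | appendage higher |
| velocity-matched threshold (blood 140 / tissue 60) | 100, NRMSE 1.5e-4 | in the gap, < 5 % |

A smaller end-to-end run with a console summary:

```bash
embryoheart demo --out demo_out        # ~2 min, reduced phantom
embryoheart pipeline --config my.yaml --out run_out
```

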