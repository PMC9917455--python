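# mcamtools

Simulation and image-processing toolkit for **multi-camera array microscopes
(MCAM)** — instruments that tile a rectangular grid of micro-cameras with
partially overlapping fields of view over a macroscopic arena (hundreds of
cm²) and computationally combine the per-camera streams into gigapixel-scale
images. Such systems let behavioral biologists watch dozens of freely moving
model organisms (larval zebrafish, *C. elegans*, fruit flies, ants, slime
mold) at a resolution fine enough to resolve eyes, tail curvature and
individual pigmentation patterns.

The package is aimed at users of array microscopes and at developers of
large-FOV imaging pipelines. It implements the complete computational path
from raw per-camera framesets to behavioral readouts, plus a ground-truthed
scene simulator so every stage can be validated quantitatively on one desk
CPU, without any recorded data.

## What is inside

| module | role |
| --- | --- |
| `mcamtools.optics` | thin-lens geometry: magnification `m = f/(u−f)`, per-camera FOV and array span, overlap fractions, Rayleigh resolution `λ/(2NA²)`, disparity↔depth `u = f(1 + B/s)`, data-volume arithmetic |
| `mcamtools.simulate` / `render` | ground-truthed scenes (fish / worm / blob / textured bead organisms with 3-D poses, articulation, per-identity speckle) rendered through the camera model: projection `−m(p−c)`, defocus blur, cos⁴ vignetting, Bayer sampling, shot + read noise |
| `mcamtools.preprocess` | per-pixel flat-field correction from white-diffuser images; bilinear RGGB demosaic |
| `mcamtools.stitch` | Fourier stitching: phase-correlation pair registration with sub-pixel refinement, global least-squares calibration template (estimated once, reused for every frame), feathered mosaic assembly |
| `mcamtools.detect` | tiled detection over arbitrarily large mosaics with cross-tile non-max suppression; pluggable detector contract with a classical difference-of-Gaussians reference detector; occluder augmentation |
| `mcamtools.stereo` | stereoscopic depth from adjacent-camera pairs: binary 256-bit descriptors, mutual-best Hamming matching, MAD-robust mean disparity, thin-lens inversion, 3-D track assembly |
| `mcamtools.track` / `identity` / `nnet` | optimal gated track linking; triplet-loss identity embedder (3 conv blocks + 2 FC layers → 64-d embeddings, pure-numpy training) with temporal train/test splits |
| `mcamtools.behavior` | occupancy heatmaps, skeleton-based tail and eye kinematics, block-matching optical-flow activity, connectivity-based individual/swarm counting and densities |

A thin `mcam` CLI wraps the library (`mcam simulate`, `mcam flatfield`,
`mcam calibrate`, `mcam stitch`, `mcam detect`, `mcam track`,
`mcam metrics …`).

## Worked example

Simulate a two-camera stereo pair observing a textured bead 1 mm above the
plane of best focus, and recover its depth from binocular disparity:

```python
import numpy as np
from mcamtools import optics, simulate, render, stereo

cam = optics.CameraSpec(focal_length_mm=25, numerical_aperture=0.03,
                        pixel_pitch_um=1.4, sensor_px=(3600, 512))
cfg = optics.ArrayConfig(camera=cam, grid=(1, 2), pitch_mm=19.0,
                         working_distance_mm=150.0)
geom = optics.DepthGeometry.from_array_config(cfg)

bead = simulate.OrganismSpec(kind="point_bead", position_mm=(0, 0), z_mm=1.0,
                             length_mm=1.2, width_mm=1.2)
scene = simulate.SceneSpec(extent_mm=(40, 20), organisms=[bead])
fs = render.render_frameset(scene, cfg, seed=1)

a = fs.frames[(0, 0)][::-1, ::-1] / 255.0   # un-rotate the optical inversion
b = fs.frames[(0, 1)][::-1, ::-1] / 255.0
def roi(img):
    dev = np.abs(img - np.median(img))
    iy, ix = np.unravel_index(dev.argmax(), img.shape)
    return (ix - 120, iy - 120, ix + 120, iy + 120)

disparity, n, spread = stereo.pair_disparity(a, b, roi(a), roi(b))
est = stereo.estimate_depth(disparity, geom, n_features=n)
print(f"disparity {disparity:.1f} px from {n} features -> z = {est.z_mm:+.3f} mm")
```

Output:

```
disparity -2736.2 px from 57 features -> z = +1.001 mm
```

The magnitude of the disparity (2736 px ≈ 3.83 mm on the sensor) exceeds the
focal-plane value `m·B = 0.2 × 19 mm = 2714 px`, so the bead is nearer than
the 150 mm focus distance; inverting `u = f(1 + B/s)` puts it 1.00 mm toward
the cameras — within a micrometre of the simulated 1.0 mm here, and within
≈ 25 µm RMS across the full ±2.5 mm range (see below). Near focus, one pixel
of disparity corresponds to ≈ 46 µm of depth.

Useful geometry facts the same config reproduces:

```python
optics.object_space_fov(cfg)        # per-camera FOV 30.24 x 17.02 mm at u=150
optics.overlap_fractions(cfg)       # long-axis overlap 37%, short-axis gap
optics.resolution_metrics(cam, 150) # axial Rayleigh 0.278 mm, 7 um object pixels
optics.raw_frame_bytes(optics.load_preset("mcam96"))  # 962 MiB per snapshot
```

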