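# cortexmetrics

Quantification of cortical actomyosin network organization and
contractility from fluorescence time-lapse stacks, built for the basal
network that drives *Drosophila* cellularization.

During cellularization the plasma membrane invaginates between cortical
nuclei, and an actomyosin network at the leading (basal) edge encloses
dark polygonal or circular *basal openings*. The network passes through
distinct stages — a diffuse priming signal, an angular hexagonal array
resistant to constriction, and separated contractile rings — and the
geometry and kinetics of the openings report on how the network is
organized and how much force it transmits. This package implements that
read-out chain for people analyzing such movies:

- **basal-plane detection** — locate the basal signal peak in the
  apicobasal intensity profile, sum 3–5 slices around it into a top-view
  projection, and measure furrow **ingression depth** (apical cortex peak
  to basal peak); align per-sample depth-versus-time curves and zero the
  mean trend at a reference depth (4 µm).
- **opening segmentation** — a marker-controlled watershed on the
  inverted, contrast-enhanced frame (Sobel gradient, disk-opened regional
  maxima as foreground markers with a stability-plateau radius choice,
  skeletonized background markers, minima imposition).
- **morphometrics** — per-opening area and **angularity**

  $$Q = \left(\frac{P_{\text{hull}}}{P_{\text{ellipse}}}\right)^2,$$

  the squared ratio of the convex-hull perimeter to the perimeter of the
  ellipse with the region's moment-equivalent major and minor axes.
  Q = 1 for a circle, ≈ 1.094 for a regular hexagon, ≈ 1.216 for a
  square — a sensitive detector of the hexagon-to-ring transition.
- **contractility kinetics** — mean opening area over time per region,
  activated/control fold change, and linear constriction rates (µm²/min,
  or µm/min on the effective diameter), plus the basal myosin-II
  intensity fold change after optogenetic activation.
- **laser-ablation recoil** — mean displacement curves from tracked
  interfaces, maximum displacement at saturation (125 s), and the initial
  recoil velocity (linear fit over 1–4 s), a proxy for network tension.
- **fiber metrics** — fiber width from the distance transform along
  skeletonized fibers, fiber density relative to a designated single
  reference fiber, relative density against a control median, and
  knockdown efficiency (< 15 % of control integrated signal flags an
  efficient depletion).
- **synthetic scenes** — a ground-truth generator for every input regime
  (network lattices, constriction movies, axial two-peak stacks, recoil
  tracks, fiber images), so the whole pipeline is verifiable without raw
  microscopy.

## Worked example

```python
import numpy as np
import cortexmetrics as cm

# hexagonal-phase scene with Poisson noise at peak SNR 10, plus ground truth
grid, truth = cm.make_network_frame(
    "hexagonal", n_cells=(3, 3),
    noise_params={"peak_photons": 100, "blur_sigma_um": 0.1}, seed=7)

labels = cm.segment_openings(grid, cm.PipelineConfig())
shapes = [cm.opening_shape(labels, lid) for lid in labels.label_ids]
print(f"openings segmented: {len(shapes)} (ground truth: {len(truth.opening_centers)})")
print(f"mean area: {np.mean([s.area for s in shapes]):.1f} um^2 "
      f"(truth {truth.true_areas[0][0]:.1f} um^2)")
print(f"mean angularity: {np.mean([s.angularity for s in shapes]):.3f} "
      f"(analytic hexagon value {truth.true_angularity[0]:.3f})")

# post-ablation recoil read-outs from synthetic saturating tracks
table, _ = cm.make_recoil_tracks(d_max=6.0, tau=3.0, n_tracks=10,
                                 noise_sd=0.05, seed=7)
tracks = cm.tracks_from_table(table)
print(f"initial recoil velocity: "
      f"{cm.initial_recoil_velocity(tracks, (1.0, 4.0)):.3f} um/s")
print(f"max displacement at 125 s: "
      f"{cm.max_displacement(tracks, 125.0)[1]['mean_um']:.2f} um")
```

prints

```
openings segmented: 9 (ground truth: 9)
mean area: 41.5 um^2 (truth 42.4 um^2)
mean angularity: 1.086 (analytic hexagon value 1.094)
initial recoil velocity: 0.900 um/s
max displacement at 125 s: 5.99 um
```

All nine openings are recovered, the watershed areas sit within a few
percent of the analytic truth, the measured angularity matches the
continuum hexagon value, and the recoil fit reproduces the least-squares
slope of the underlying exponential (d_max/τ = 2 µm/s sampled at 1–4 s
gives 0.90 µm/s) with the curve saturated at ≈ 6 µm by 125 s.

A `cortexmetrics` command-line tool wraps the same stages for shell use:

```sh
cortexmetrics simulate --scene network --phase hexagonal --seed 1 --out scene/
cortexmetrics segment scene/scene.tif --out seg/
cortexmetrics ablation tracks.csv --out recoil/
```

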