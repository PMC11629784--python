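# psam — pseudo-spectral angle mapping for multiplexed immunofluorescence

Highly multiplexed immunofluorescence (PhenoCycler/CODEX-style iterative
staining) produces image stacks with tens of marker channels per tissue
section. `psam` classifies these images without any training data: every
pixel is treated as a vector **A** of marker intensities and compared with
a small library of *reference pseudo-spectra* — hand-written vectors **B**
of ideal expression levels (0 / 0.5 / 1 over the ordered marker panel,
one reference per expected cell class) — by cosine similarity,

```
cos(θ) = (A · B) / (‖A‖ ‖B‖)
```

The technique is the immunofluorescence analogue of the spectral angle
mapper of remote sensing. Because the cosine depends only on the
*relative* marker profile, classification is invariant to staining
intensity and robust to batch effects. The package provides:

- **Reference libraries** (`psam.library`) — CSV-backed marker panels and
  compartment-tagged (nucleus vs. membrane) reference pseudo-spectra,
  including a packaged 13-marker, 16-reference immune-phenotyping library
  (3 nucleus + 13 membrane classes).
- **Preprocessing** (`psam.preprocess`) — blank-cycle autofluorescence
  subtraction, per-wavelength standardization by background SD,
  99th-percentile min–max normalization, Otsu tissue masking.
- **Pixel classification** (`psam.mapping`) — one cosine class map per
  reference; the per-pixel argmax over the stacked maps
  (`class(i,j) = argmax_x Θ(i,j,x)`) is the pixel class; prevalence and
  mean-score summaries and the maximum-intensity projection.
- **Compartment geometry** (`psam.cells`) — externally produced nucleus
  instance masks (e.g. Cellpose) dilated by ~1 μm (7 px at 0.1507 μm/px)
  into whole-cell masks with Voronoi conflict resolution; membrane rings;
  soft masks from inverted distance transforms.
- **Cell classification** (`psam.classify`) — soft-mask-weighted mean of
  each thresholded (≥ 0.5) class map over the matching compartment; per-
  compartment argmax with "unclassified" / "generic nucleus" fallbacks;
  mean-pixel-intensity (MPI) z-score validation tables.
- **Interstitial proximity** (`psam.proximity`) — Gaussian-decay maps
  `w(d) = exp(−d²/2σ²)` (σ = 22.36 px ⇒ half-weight 4 μm from a cell
  boundary) and the cell-class × pixel-class proximity-score matrix.
- **A synthetic-tissue simulator** (`psam.simulate`) — ground-truthed
  images, blank cycles and nucleus masks so the whole pipeline is testable
  without any real data.

Segmentation itself, stitching/registration and spectral unmixing are
out of scope: nucleus masks and aligned stacks are consumed as inputs.

## Worked example

Simulate a 512×512 acquisition (120 cells, 5 membrane + 2 nucleus
classes, Gaussian noise sd 0.1), classify pixels and cells, and score
interstitial proximity:

```python
from psam import (SimulationConfig, simulate_tissue, compute_class_stack,
                  compute_tissue_mask, argmax_class_map, threshold_stack,
                  CompartmentGeometry, score_cells, assign_classes,
                  class_prevalence, proximity_score_matrix)

cfg = SimulationConfig(seed=7, n_cells=120, image_size=(512, 512),
                       noise_sd=0.1, autofluorescence_level=0.0,
                       interstitial_protrusion_rate=0.4)
img, blank, truth = simulate_tissue(cfg)

stack = compute_class_stack(img, cfg.library)          # 8 cosine maps
tissue = compute_tissue_mask(img)
pixels = argmax_class_map(stack, tissue)               # per-pixel classes

geom = CompartmentGeometry.from_nuclei(truth.nuclei, radius_px=7)
cells = assign_classes(score_cells(threshold_stack(stack, 0.5), geom, cfg.library))

merged = cells.frame.merge(truth.cells, on="cell_id", suffixes=("_pred", "_true"))
recovered = ((merged.membrane_class_pred == merged.membrane_class_true)
             & (merged.nucleus_class_pred == merged.nucleus_class_true)).mean()
print(f"cells: {len(cells)}   recovered classes: {recovered:.1%}")

prevalence = class_prevalence(pixels)
top = sorted(prevalence.items(), key=lambda kv: -kv[1])[:3]
print("top pixel classes:", ", ".join(f"{k} {v:.3f}" for k, v in top))

membrane = [r.name for r in cfg.library if r.compartment == "membrane"]
matrix = proximity_score_matrix(cells, geom, pixels, tissue, cell_classes=membrane)
print(matrix[membrane].round(2))
```

which prints

```
cells: 120   recovered classes: 100.0%
top pixel classes: class M5 0.194, class M1 0.192, class M3 0.172
          class M1  class M2  class M3  class M4  class M5
class M1      0.84      0.43      0.46      0.54      0.43
class M2      0.37      0.83      0.33      0.40      0.44
class M3      0.42      0.41      0.83      0.40      0.41
class M4      0.42      0.47      0.51      0.84      0.48
class M5      0.53      0.53      0.54      0.50      0.88
```

Every simulated cell's membrane and nucleus class is recovered from the
noisy image; pixel prevalence reflects the (uniform) painted class mix;
and the proximity matrix peaks on its diagonal because each class's
interstitial "protrusion" pixels were painted hugging that class's own
cells — the signature the proximity score is designed to detect.

The same pipeline is available from the shell:

```bash
psam simulate --seed 7 --out sim/
psam run --image sim/image.tif --nuclei sim/nuclei.tif \
         --library sim/library.csv --out run/
```

which writes class maps, the pixel class map, the cell table, z-score and
proximity matrices, and a JSON manifest of all parameters and input
hashes under `run/`.

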