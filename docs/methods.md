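# Methods

## The model

`psam` implements pseudo-spectral angle mapping: supervised pixel and
cell classification of multiplexed immunofluorescence stacks where the
only supervision is a library of hand-specified reference pseudo-spectra.
A reference is a vector over the ordered marker panel with entries
0 (absent), 0.5 (low) and 1 (high expression), tagged with the
subcellular compartment (nucleus or membrane/cytoplasm) its markers
localize to. Pixel classification is the argmax over per-reference
cosine-similarity maps; cell classification aggregates thresholded maps
over compartment geometry derived from externally provided nucleus
instance masks.

Assumptions the method rests on:

- channels are aligned (stitching and cycle registration happen
  upstream) and stacked in the panel's canonical marker order;
- intensities are non-negative, so every cosine lies in [0, 1] and the
  0.5 threshold has a fixed meaning;
- relative marker profile, not absolute brightness, carries the class
  signal — the cosine is invariant to positive rescaling of a pixel
  vector, which is what makes the method robust to staining-intensity
  batch effects;
- a nucleus mask dilated by ~1 μm approximates the whole cell well
  enough for compartment scoring.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| normalization percentile | 99 | % | per-channel min–max cap; top 1% of pixels saturate at 1 |
| class-map threshold | 0.5 | cosine | rejects low-similarity pixels before cell scoring |
| dilation radius | 7 | px | ~1 μm at 0.1507 μm/px; derived as round(1 μm / pixel size) for other instruments |
| proximity σ | 22.36 | px | Gaussian decay length; puts the half-weight point 4 μm from a cell boundary |
| proximity cutoff | 3σ | px | weights truncated beyond it; changes no score by more than exp(−4.5) ≈ 0.011 |
| tissue mask closing radius / min object | 5 / 64 | px | morphological cleanup of the Otsu mask |
| pixel size | 0.1507 | μm/px | physical scale; converts μm-specified lengths to pixels |

The proximity decay is the half-Gaussian `w(d) = exp(−d²/2σ²)` with `d`
the Euclidean distance to the nearest boundary pixel of the target
class's whole-cell instances. The σ = 22.36 px default reproduces the
stated calibration — weight ≈ 0.494 at 4 μm (26.54 px) — which an
exponential decay `exp(−d/σ)` would not (0.305); that calibration is why
the half-Gaussian form was adopted.

## Preprocessing chain

For each stained channel: subtract the wavelength-matched blank-cycle
channel, clip at zero, divide by the blank channel's standard deviation
(each excitation wavelength has its own dynamic range), then min–max
normalize to the channel's 99th percentile. Clipping negative
differences is a deliberate choice — fluorescence is physically
non-negative and the cosine mapping assumes non-negative vectors. The
percentile and minimum are computed over the whole channel by default
(a tissue-only mode exists as a flag). Only the first blank cycle is
used; a trailing blank is accepted but ignored.

## Numerical choices

- **Class maps are computed and held in float64.** The mapping's defining
  invariance — bit-level stability of maps under positive rescaling of
  the image or of single pixel vectors, to 1e−12 — is unachievable in
  float32 (ulp ≈ 6e−8); maps are only downcast to float32 when written
  to TIFF.
- **Zero pixel vectors score 0** against every reference: the cosine is
  undefined at zero and 0 is the unique value that preserves
  thresholding semantics.
- **Argmax ties break to the lowest library index** (numpy first-match),
  with the tie count logged; this makes pixel and cell classification
  order-stable and reproducible.
- **Voronoi dilation** assigns contested pixels by distance to the
  nucleus *mask* (not centroid), computed as one distance transform per
  instance swept in ascending label order with a strict-improvement
  update. This makes the lower-label tie rule exact — a single
  nearest-feature transform would leave equidistant pixels to the
  library's internal tie-breaking. Distances are exact square roots of
  integer sums, so float equality comparisons are safe at image scale.
  Each instance's transform is restricted to its bounding box grown by
  the radius, which is lossless (no pixel farther away can be assigned
  to that instance) and keeps the sweep linear in total nucleus area.
- **Soft masks** weight a compartment pixel by its Euclidean distance to
  the instance's complement, normalized to a maximum of 1; the image
  border counts as complement. The innermost pixel scores 1 and edges
  score least, blurring segmentation-boundary error out of cell scores.
  The "inverted distance transform" wording admits a center-low reading;
  the center-high reading implemented here is the one that de-weights
  edges.
- **Cell scores are weight-normalized means** Σ(w·s)/Σ(w) over the
  compartment support, so small cells are not penalized relative to
  large ones. A cell with an empty membrane ring (fully contested by
  crowding) scores 0 on all membrane references and is logged, not an
  error.
- **Pixel classification uses the unthresholded stack** (with the tissue
  mask); the 0.5 threshold applies only to cell scoring. This mirrors
  the method's published sequencing and is exposed as a flag.
- **Undefined quantities stay undefined**: a class with no assigned
  pixels has NaN mean score, and a proximity-matrix entry with no
  qualifying interstitial pixels is NaN — never silently 0.
- **Degenerate channels** (99th percentile equal to the minimum) are set
  to zero with a warning; zero-variance blank channels are an error
  since standardization divides by their SD.

## The simulator

`simulate_tissue` emulates exactly the structure the method assumes:
non-overlapping nucleus discs (radius 3–5 px) placed by seeded rejection
sampling, each painted with its nucleus reference's levels, surrounded
by a 7 px annulus painted with its membrane reference's levels; a
constant autofluorescence floor on all channels; i.i.d. Gaussian noise
clipped at zero; blank cycles sharing the autofluorescence mean with
independent noise; and optional interstitial "protrusion" blobs painted
with a cell's membrane profile just outside its footprint — the
out-of-plane signal the proximity score targets. Defaults: 512×512
frame, 200 cells, noise sd 0.1, autofluorescence 0.05, protrusion rate
0.25, intensities on the post-normalization [0, 1] scale (a raw-scale
mode paints amplified counts plus the blank offset so preprocessing is
exercised end to end).

Nuclei are placed so that the *dilated* whole-cell discs stay pairwise
disjoint. This keeps painted membrane annuli pure — no mixed profiles at
cell–cell contacts — which is what makes perfect recovery at zero noise
a well-posed expectation. The annulus width equals the dilation radius
so painted membranes and reconstructed membrane rings coincide (up to
the discrete-disc boundary, where the reconstructed ring is a subset of
the painted annulus; leftover painted pixels become realistic
boundary-hugging interstitial signal).

What the simulator does *not* emulate — and hence what passing tests do
not demonstrate about real tissue: point-spread blur and lateral signal
bleed between touching cells, cycle-to-cycle misregistration, stitching
seams, irregular (non-disc) nuclei, spatially varying autofluorescence,
antibody cross-reactivity, and segmentation errors in the input nucleus
masks. Recovery rates on simulated data are an upper bound on real-data
performance.

The packaged 13-marker, 16-reference library reproduces the published
panel *structure* (3 nucleus + 13 membrane references). Ten marker names
and the anchor phenotypes (e.g. exhausted CD8 T cell =
CD45/CD3/CD8/PD1) follow the published description; three placeholder
markers carry a `-like` suffix, and value vectors for classes not
spelled out in the source text are a reconstruction from standard
immunophenotypes. The generic-nucleus reference is DAPI-only. Treat the
packaged library as a structurally faithful template, not a validated
panel.

## Problem sizes

The test suite and examples run at desk scale: 8×8 oracle fixtures for
the cosine map, ≤64×64 fixtures for the brute-force Voronoi comparison,
256–320 px simulations for pipeline properties, and 512×512 / 150–200
cell simulations for end-to-end recovery and proximity structure. These
sizes exercise every code path; whole-slide inputs differ only in array
size.

## Known limitations

- Class maps are held in memory (float64); giga-pixel whole-slide runs
  would need tiling above roughly 10⁸ pixels per map, which is not
  implemented.
- The Voronoi sweep is linear in instance count × bounding-box area;
  extremely dense masks (thousands of touching instances) will be the
  slow stage.
- Nucleus and membrane classes are reported separately, never merged
  into joint phenotypes.
- Reference levels are restricted to {0, 0.5, 1} by default; a
  permissive mode accepts any level in [0, 1], but the cosine itself
  imposes no calibration on intermediate levels.
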