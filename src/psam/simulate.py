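"""Ground-truthed synthetic multiplexed tissue.

The simulator emulates the statistical structure the mapping method
assumes: cells of known classes whose nucleus discs carry their nucleus
reference's marker levels and whose surrounding membrane annuli carry
their membrane reference's levels, plus a constant autofluorescence
floor on every channel, i.i.d. Gaussian noise clipped at zero, blank
cycles sharing the autofluorescence mean, and optional interstitial
"protrusion" blobs painted with a cell's membrane profile just outside
its segmentation — the out-of-plane-cell signal the proximity analysis
targets.

Nuclei are placed by seeded rejection sampling so that the dilated
whole-cell discs are pairwise disjoint; each emitted image therefore has
an exact ground truth (nucleus label mask, per-cell classes, painted
interstitial class map) that the pipeline can be scored against.

Intensities are painted on the post-normalization [0, 1] scale by
default; ``raw_scale`` paints amplified raw counts plus the blank offset
so the preprocessing chain is exercised too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image import BlankStack, MultiplexImage
from .library import (
    MarkerPanel,
    ReferenceLibrary,
    ReferencePseudoSpectrum,
    DEFAULT_PIXEL_SIZE_UM,
)

DEFAULT_IMAGE_SIZE = (512, 512)
DEFAULT_N_CELLS = 200
DEFAULT_NUCLEUS_RADIUS = (3, 5)
DEFAULT_ANNULUS_WIDTH = 7
DEFAULT_NOISE_SD = 0.1
DEFAULT_AUTOFLUORESCENCE = 0.05
DEFAULT_PROTRUSION_RATE = 0.25
PROTRUSION_RADIUS_PX = 3
RAW_SCALE_AMPLITUDE = 1000.0

#: Excitation wavelengths cycled over panel channels (nm).
WAVELENGTHS = ("405", "488", "561", "637", "730")


def make_demo_library(
    n_membrane: int = 5,
    n_nucleus: int = 2,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> ReferenceLibrary:
    """A small synthetic immune-style library for simulations.

    The panel is a DNA stain, ``n_nucleus - 1`` extra nuclear markers, a
    shared pan-leukocyte-style membrane marker and one distinguishing
    marker per membrane class.  Nucleus references are the DNA-only
    generic nucleus plus one DNA+Nuc<j> class each; membrane reference i
    is pan + M<i>.  Any two membrane references have cosine 0.5 and the
    two nucleus references 0.71, comfortable margins for noisy recovery.
    """
    if n_membrane < 1 or n_nucleus < 1:
        raise ValueError("need at least one reference per compartment")
    nuc_markers = [f"Nuc{j}" for j in range(1, n_nucleus)]
    mem_markers = [f"M{i}" for i in range(1, n_membrane + 1)]
    markers = ["DNA", *nuc_markers, "PanM", *mem_markers]
    panel = MarkerPanel(markers=tuple(markers), pixel_size_um=pixel_size_um)

    def vec(on: list[str]) -> np.ndarray:
        v = np.zeros(len(markers))
        for m in on:
            v[markers.index(m)] = 1.0
        return v

    refs = [ReferencePseudoSpectrum("generic nucleus", "nucleus", vec(["DNA"]))]
    refs += [
        ReferencePseudoSpectrum(f"Nuc{j}+ nucleus", "nucleus", vec(["DNA", f"Nuc{j}"]))
        for j in range(1, n_nucleus)
    ]
    refs += [
        ReferencePseudoSpectrum(f"class M{i}", "membrane", vec(["PanM", f"M{i}"]))
        for i in range(1, n_membrane + 1)
    ]
    return ReferenceLibrary(panel=panel, references=tuple(refs))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated acquisition.

    ``class_proportions`` maps (membrane class, nucleus class) pairs to
    sampling probabilities; None means uniform over all pairs.
    ``annulus_width_px`` should match the dilation radius used downstream
    so painted membranes and reconstructed membrane rings agree.
    """

    library: ReferenceLibrary = field(default_factory=make_demo_library)
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE
    n_cells: int = DEFAULT_N_CELLS
    class_proportions: dict[tuple[str, str], float] | None = None
    nucleus_radius_px: tuple[int, int] = DEFAULT_NUCLEUS_RADIUS
    annulus_width_px: int = DEFAULT_ANNULUS_WIDTH
    noise_sd: float = DEFAULT_NOISE_SD
    autofluorescence_level: float = DEFAULT_AUTOFLUORESCENCE
    interstitial_protrusion_rate: float = DEFAULT_PROTRUSION_RATE
    raw_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd < 0 or self.autofluorescence_level < 0:
            raise ValueError("noise_sd and autofluorescence_level must be >= 0")
        if not 0 <= self.interstitial_protrusion_rate <= 1:
            raise ValueError("interstitial_protrusion_rate must lie in [0, 1]")
        lo, hi = self.nucleus_radius_px
        if lo < 1 or hi < lo:
            raise ValueError("nucleus_radius_px must be a (min, max) with 1 <= min <= max")
        self.library.require_both_compartments()

    def class_pairs(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        """(membrane, nucleus) class pairs and their probabilities."""
        mem = [self.library.references[i].name
               for i in self.library.compartment_indices("membrane")]
        nuc = [self.library.references[i].name
               for i in self.library.compartment_indices("nucleus")]
        if self.class_proportions is None:
            pairs = [(m, n) for m in mem for n in nuc]
            probs = np.full(len(pairs), 1.0 / len(pairs))
            return pairs, probs
        pairs = list(self.class_proportions)
        for m, n in pairs:
            if m not in mem or n not in nuc:
                raise ValueError(f"unknown class pair {(m, n)!r}")
        probs = np.array([self.class_proportions[p] for p in pairs], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("class_proportions must sum to 1")
        return pairs, probs


@dataclass
class GroundTruth:
    """What the simulator painted, for scoring the pipeline against."""

    nuclei: np.ndarray
    cells: pd.DataFrame  # cell_id, row, col, radius, membrane_class, nucleus_class
    interstitial: np.ndarray  # library reference index; -1 where nothing painted
    painted: np.ndarray  # bool: any cell or protrusion pixel

    @property
    def n_cells(self) -> int:
        return len(self.cells)


class PlacementError(RuntimeError):
    """Rejection sampling could not place all requested nuclei."""


def _place_nuclei(cfg: SimulationConfig, rng: np.random.Generator):
    """Non-overlapping nucleus centres such that dilated cells stay disjoint."""
    rows, cols = cfg.image_size
    lo, hi = cfg.nucleus_radius_px
    margin_extra = cfg.annulus_width_px + PROTRUSION_RADIUS_PX * 2 + 2
    centres: list[tuple[int, int]] = []
    radii: list[int] = []
    max_attempts = 500 * cfg.n_cells
    attempts = 0
    while len(centres) < cfg.n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(centres)}/{cfg.n_cells} nuclei after "
                f"{max_attempts} attempts; reduce n_cells or enlarge the image"
            )
        attempts += 1
        r = int(rng.integers(lo, hi + 1))
        margin = r + margin_extra
        if 2 * margin >= min(rows, cols):
            raise PlacementError("image too small for the requested nucleus radius")
        cy = int(rng.integers(margin, rows - margin))
        cx = int(rng.integers(margin, cols - margin))
        # Dilated whole-cell discs must not touch: centre separation beyond
        # r_i + r_j + 2 * annulus + 1 keeps membranes pure.
        ok = all(
            (cy - py) ** 2 + (cx - px) ** 2
            > (r + pr + 2 * cfg.annulus_width_px + 1) ** 2
            for (py, px), pr in zip(centres, radii)
        )
        if ok:
            centres.append((cy, cx))
            radii.append(r)
    return centres, radii


def simulate_tissue(cfg: SimulationConfig) -> tuple[MultiplexImage, BlankStack, GroundTruth]:
    """Paint a synthetic acquisition and its exact ground truth.

    Fully reproducible from ``cfg.seed``.  Returns the stained stack, a
    blank cycle (autofluorescence + independent noise) and the ground
    truth.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.image_size
    lib = cfg.library
    n_ch = lib.panel.n_markers
    ref_values = {r.name: r.values for r in lib}
    ref_index = {r.name: i for i, r in enumerate(lib.references)}

    centres, radii = _place_nuclei(cfg, rng)
    pairs, probs = cfg.class_pairs()
    choice = rng.choice(len(pairs), size=cfg.n_cells, p=probs)

    clean = np.zeros((n_ch, rows, cols), dtype=np.float64)
    nuclei = np.zeros((rows, cols), dtype=np.int32)
    interstitial = np.full((rows, cols), -1, dtype=np.int32)
    yy, xx = np.mgrid[0:rows, 0:cols]

    records = []
    protrusion_flags = rng.random(cfg.n_cells) < cfg.interstitial_protrusion_rate
    protrusion_angles = rng.uniform(0, 2 * np.pi, size=cfg.n_cells)
    for k, ((cy, cx), r) in enumerate(zip(centres, radii), start=1):
        mem_name, nuc_name = pairs[choice[k - 1]]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nucleus = d2 <= r ** 2
        annulus = (d2 <= (r + cfg.annulus_width_px) ** 2) & ~nucleus
        nuclei[nucleus] = k
        clean[:, nucleus] = ref_values[nuc_name][:, None]
        clean[:, annulus] = ref_values[mem_name][:, None]
        records.append({
            "cell_id": k, "row": cy, "col": cx, "radius": r,
            "membrane_class": mem_name, "nucleus_class": nuc_name,
        })

    # Whole-cell footprint (any class) — protrusions must stay outside it.
    cell_footprint = np.zeros((rows, cols), dtype=bool)
    for (cy, cx), r in zip(centres, radii):
        cell_footprint |= ((yy - cy) ** 2 + (xx - cx) ** 2) <= (r + cfg.annulus_width_px) ** 2

    for k, ((cy, cx), r) in enumerate(zip(centres, radii), start=1):
        if not protrusion_flags[k - 1]:
            continue
        mem_name = records[k - 1]["membrane_class"]
        theta = protrusion_angles[k - 1]
        dist = r + cfg.annulus_width_px + PROTRUSION_RADIUS_PX + 1
        py = int(round(cy + dist * np.sin(theta)))
        px = int(round(cx + dist * np.cos(theta)))
        blob = ((yy - py) ** 2 + (xx - px) ** 2 <= PROTRUSION_RADIUS_PX ** 2)
        blob &= ~cell_footprint & (interstitial < 0)
        if not blob.any():
            continue
        clean[:, blob] = ref_values[mem_name][:, None]
        interstitial[blob] = ref_index[mem_name]

    painted = cell_footprint | (interstitial >= 0)

    scale = RAW_SCALE_AMPLITUDE if cfg.raw_scale else 1.0
    auto = cfg.autofluorescence_level * scale
    sd = cfg.noise_sd * scale
    stained = clean * scale + auto
    if sd > 0:
        stained = stained + rng.normal(0.0, sd, size=stained.shape)
    stained = np.clip(stained, 0, None)

    blank = np.full((n_ch, rows, cols), auto, dtype=np.float64)
    if sd > 0:
        blank = blank + rng.normal(0.0, sd, size=blank.shape)
    blank = np.clip(blank, 0, None)

    tags = tuple(WAVELENGTHS[i % len(WAVELENGTHS)] for i in range(n_ch))
    image = MultiplexImage(
        data=stained.astype(np.float32),
        channel_names=lib.panel.markers,
        pixel_size_um=lib.panel.pixel_size_um,
    )
    blank_stack = BlankStack(data=blank.astype(np.float32), wavelength_tags=tags)
    truth = GroundTruth(
        nuclei=nuclei,
        cells=pd.DataFrame(records),
        interstitial=interstitial,
        painted=painted,
    )
    return image, blank_stack, truth


def simulate_blank_pair(cfg: SimulationConfig) -> tuple[BlankStack, BlankStack]:
    """Two blank cycles sharing the autofluorescence mean, independent noise.

    Emulates the pre- and post-staining blank acquisitions of an
    iterative-staining run.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ch = cfg.library.panel.n_markers
    rows, cols = cfg.image_size
    scale = RAW_SCALE_AMPLITUDE if cfg.raw_scale else 1.0
    auto = cfg.autofluorescence_level * scale
    sd = cfg.noise_sd * scale
    tags = tuple(WAVELENGTHS[i % len(WAVELENGTHS)] for i in range(n_ch))
    stacks = []
    for _ in range(2):
        data = np.full((n_ch, rows, cols), auto, dtype=np.float64)
        if sd > 0:
            data = data + rng.normal(0.0, sd, size=data.shape)
        stacks.append(BlankStack(data=np.clip(data, 0, None).astype(np.float32),
                                 wavelength_tags=tags))
    return stacks[0], stacks[1]
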