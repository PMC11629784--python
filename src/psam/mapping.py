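"""The pseudo-spectral angle mapping core.

Every pixel of an aligned multiplexed image is a vector **A** of marker
intensities; every reference pseudo-spectrum is a vector **B** of ideal
expression levels over the same ordered panel.  The class map of a
reference is the image of cosine similarities

    cos(theta) = (A · B) / (||A|| ||B||)

so a pixel scores 1 when its relative marker profile matches the
reference exactly, regardless of absolute brightness, and 0 when the
profiles are disjoint.  Stacking one map per reference gives the class
map stack; the per-pixel argmax over that stack is the pixel class.

For non-negative intensities every similarity lies in [0, 1], and the
mapping is invariant to positive rescaling of any pixel vector — the
property that makes the method robust to staining-intensity batch
effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .image import MultiplexImage, TissueMask
from .library import ReferenceLibrary, ReferencePseudoSpectrum

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5

#: Label assigned to off-tissue (slide background) pixels.
BACKGROUND_LABEL = -1


@dataclass
class ClassMapStack:
    """One cosine-similarity map per library reference.

    ``maps`` has shape (n_references, rows, cols) with values in [0, 1].
    ``threshold`` records the cutoff applied when ``thresholded`` is True:
    retained values are then 0 or >= threshold.
    """

    maps: np.ndarray
    reference_names: tuple[str, ...]
    thresholded: bool = False
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps)
        self.reference_names = tuple(self.reference_names)
        if self.maps.ndim != 3:
            raise ValueError("class map stack must be (reference, row, col)")
        if len(self.reference_names) != self.maps.shape[0]:
            raise ValueError("one reference name per map required")

    @property
    def n_references(self) -> int:
        return self.maps.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]

    def map_for(self, name: str) -> np.ndarray:
        return self.maps[self.reference_names.index(name)]

    def subset(self, indices: list[int]) -> "ClassMapStack":
        return replace(
            self,
            maps=self.maps[indices],
            reference_names=tuple(self.reference_names[i] for i in indices),
        )


@dataclass
class PixelClassMap:
    """Per-pixel winning reference index and its similarity score.

    ``labels`` indexes into ``reference_names``; off-tissue pixels carry
    the sentinel ``BACKGROUND_LABEL`` (-1).
    """

    labels: np.ndarray
    scores: np.ndarray
    reference_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.scores = np.asarray(self.scores)
        self.reference_names = tuple(self.reference_names)
        if self.labels.shape != self.scores.shape:
            raise ValueError("labels and scores must share shape")

    @property
    def on_tissue(self) -> np.ndarray:
        return self.labels != BACKGROUND_LABEL


def cosine_similarity_map(
    img: MultiplexImage, ref: ReferencePseudoSpectrum
) -> np.ndarray:
    """Cosine similarity of every pixel vector against one reference.

    Zero pixel vectors (possible after background subtraction) score 0:
    the cosine is undefined there and 0 preserves thresholding semantics.
    """
    b = np.asarray(ref.values, dtype=np.float64)
    if img.n_channels != b.size:
        raise ValueError(
            f"image has {img.n_channels} channels but reference "
            f"{ref.name!r} has {b.size} values"
        )
    b_norm = np.linalg.norm(b)
    if b_norm == 0:
        raise ValueError(f"reference {ref.name!r} has zero norm")
    data = np.asarray(img.data, dtype=np.float64)
    dots = np.tensordot(b, data, axes=([0], [0]))
    pixel_norms = np.sqrt((data * data).sum(axis=0))
    out = np.zeros(img.shape, dtype=np.float64)
    np.divide(dots, pixel_norms * b_norm, out=out, where=pixel_norms > 0)
    return out


def compute_class_stack(img: MultiplexImage, lib: ReferenceLibrary) -> ClassMapStack:
    """Map the image against every library reference, in library order."""
    if img.channel_names != lib.panel.markers:
        raise ValueError(
            "image channels are not aligned to the library panel; "
            "call align_image_to_library first"
        )
    maps = np.stack([cosine_similarity_map(img, ref) for ref in lib])
    return ClassMapStack(maps=maps, reference_names=tuple(lib.names))


def threshold_stack(stack: ClassMapStack, t: float = DEFAULT_THRESHOLD) -> ClassMapStack:
    """Zero out similarities below ``t`` (low-confidence rejections)."""
    if not 0 <= t < 1:
        raise ValueError("threshold must lie in [0, 1)")
    maps = np.where(stack.maps < t, 0, stack.maps).astype(stack.maps.dtype)
    return replace(stack, maps=maps, thresholded=True, threshold=float(t))


def argmax_class_map(stack: ClassMapStack, tissue: TissueMask) -> PixelClassMap:
    """Per-pixel winning class over the stack; off-tissue pixels -> -1.

    Ties go to the lowest reference index (numpy argmax is first-match),
    with the tie count logged.
    """
    if stack.n_references == 0:
        raise ValueError("empty class map stack")
    if tissue.shape != stack.shape:
        raise ValueError("tissue mask shape does not match stack")
    labels = np.argmax(stack.maps, axis=0).astype(np.int32)
    scores = np.take_along_axis(stack.maps, labels[None].astype(np.intp), axis=0)[0]
    n_ties = int(((stack.maps == scores[None]).sum(axis=0) > 1)[tissue.mask].sum())
    if n_ties:
        logger.info("argmax ties at %d on-tissue pixels (lowest index kept)", n_ties)
    labels[~tissue.mask] = BACKGROUND_LABEL
    scores = scores.copy()
    scores[~tissue.mask] = 0
    return PixelClassMap(labels=labels, scores=scores,
                         reference_names=stack.reference_names)


def max_intensity_projection(
    stack: ClassMapStack, tissue: TissueMask | None = None
) -> tuple[np.ndarray, PixelClassMap]:
    """Per-pixel maximum over the stack plus the corresponding argmax map."""
    if stack.n_references == 0:
        raise ValueError("empty class map stack")
    if tissue is None:
        tissue = TissueMask.full(stack.shape)
    pcm = argmax_class_map(stack, tissue)
    return stack.maps.max(axis=0), pcm


def save_class_stack(stack: ClassMapStack, path) -> None:
    """Write a stack as multi-page float32 TIFF + JSON sidecar (names, threshold)."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.maps, dtype=np.float32),
                     photometric="minisblack")
    meta = {
        "reference_names": list(stack.reference_names),
        "thresholded": stack.thresholded,
        "threshold": stack.threshold,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_class_stack(path) -> ClassMapStack:
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    maps = np.asarray(tifffile.imread(path), dtype=np.float64)
    if maps.ndim == 2:
        maps = maps[None]
    return ClassMapStack(maps=maps, reference_names=tuple(meta["reference_names"]),
                         thresholded=meta["thresholded"], threshold=meta["threshold"])


#: uint16 sentinel encoding the background label on disk.
_BACKGROUND_U16 = 65535


def save_pixel_class_map(pcm: PixelClassMap, path) -> None:
    """Write labels as uint16 TIFF (background -> 65535) + legend JSON."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    labels = pcm.labels.astype(np.int64).copy()
    labels[labels == BACKGROUND_LABEL] = _BACKGROUND_U16
    tifffile.imwrite(path, labels.astype(np.uint16))
    legend = {"reference_names": list(pcm.reference_names),
              "background_value": _BACKGROUND_U16}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(legend, indent=1))
    tifffile.imwrite(path.with_name(path.stem + "_scores" + path.suffix),
                     np.asarray(pcm.scores, dtype=np.float32))


def load_pixel_class_map(path) -> PixelClassMap:
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    legend = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = tifffile.imread(path).astype(np.int64)
    labels = raw.copy()
    labels[raw == legend["background_value"]] = BACKGROUND_LABEL
    scores_path = path.with_name(path.stem + "_scores" + path.suffix)
    scores = (np.asarray(tifffile.imread(scores_path), dtype=np.float64)
              if scores_path.exists() else np.zeros(labels.shape))
    return PixelClassMap(labels=labels.astype(np.int32), scores=scores,
                         reference_names=tuple(legend["reference_names"]))


def class_prevalence(pcm: PixelClassMap) -> dict[str, float]:
    """Fraction of on-tissue pixels assigned to each class; sums to 1."""
    on = pcm.on_tissue
    total = int(on.sum())
    if total == 0:
        raise ValueError("no on-tissue pixels; cannot compute prevalence")
    counts = np.bincount(pcm.labels[on], minlength=len(pcm.reference_names))
    return {
        name: counts[i] / total for i, name in enumerate(pcm.reference_names)
    }


def mean_class_score(stack: ClassMapStack, pcm: PixelClassMap) -> dict[str, float]:
    """Mean winning similarity per assigned class.

    Classes with no assigned pixels map to NaN (undefined), never 0 — an
    absent class has no score, not a zero one.
    """
    if stack.shape != pcm.labels.shape:
        raise ValueError("stack and pixel class map shapes disagree")
    out: dict[str, float] = {}
    on = pcm.on_tissue
    for i, name in enumerate(stack.reference_names):
        sel = on & (pcm.labels == i)
        out[name] = float(pcm.scores[sel].mean()) if sel.any() else float("nan")
    return out
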