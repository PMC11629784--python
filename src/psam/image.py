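"""In-memory containers and TIFF I/O for multiplexed image stacks.

A multiplexed immunofluorescence acquisition is a channel-major stack —
one fluorescence channel per marker — over a single tissue section.  The
containers here carry the channel names and physical pixel size alongside
the array so downstream stages can align channels to a reference panel
and convert between pixels and micrometres.

Stacks are read and written with :mod:`tifffile`.  Channel names come
from OME-TIFF metadata when present, else from a sidecar YAML list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from os import PathLike
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from .library import DEFAULT_PIXEL_SIZE_UM, ReferenceLibrary

logger = logging.getLogger(__name__)


@dataclass
class MultiplexImage:
    """A channel × row × column stack of non-negative marker intensities.

    ``channel_wavelengths``, when set, gives the excitation-wavelength tag
    of each channel and is used to pair stained channels with blank-cycle
    channels for background correction.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel_wavelengths: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        if self.channel_wavelengths is not None:
            self.channel_wavelengths = tuple(str(t) for t in self.channel_wavelengths)
            if len(self.channel_wavelengths) != self.data.shape[0]:
                raise ValueError("one wavelength tag per channel required")
        if self.data.ndim != 3:
            raise ValueError(
                f"image data must be (channel, row, col), got shape {self.data.shape}"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (row, col) shape."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    def with_data(self, data: np.ndarray) -> "MultiplexImage":
        return replace(self, data=data)


@dataclass
class BlankStack:
    """A reporter-free imaging cycle capturing tissue autofluorescence.

    ``wavelength_tags`` carries the excitation tag of each blank channel
    (e.g. ``"488"``); stained channels are paired to blank channels by the
    same tag, since each excitation wavelength has its own
    autofluorescence profile.
    """

    data: np.ndarray
    wavelength_tags: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelength_tags = tuple(str(t) for t in self.wavelength_tags)
        if self.data.ndim != 3:
            raise ValueError("blank data must be (channel, row, col)")
        if len(self.wavelength_tags) != self.data.shape[0]:
            raise ValueError("one wavelength tag per blank channel required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel_for(self, tag: str) -> np.ndarray:
        tag = str(tag)
        if tag not in self.wavelength_tags:
            raise KeyError(
                f"no blank channel with wavelength tag {tag!r}; "
                f"available: {list(self.wavelength_tags)}"
            )
        return self.data[self.wavelength_tags.index(tag)]


@dataclass
class TissueMask:
    """Boolean row × column mask; True marks tissue, False slide background."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("tissue mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_tissue(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "TissueMask":
        return cls(np.ones(shape, dtype=bool))


def align_image_to_library(image: MultiplexImage, lib: ReferenceLibrary) -> MultiplexImage:
    """Reorder (and subset) image channels to the library's panel order.

    Channel order is the contract of the whole method: pixel vectors are
    compared to reference vectors position by position.  Extra channels
    not in the panel are dropped with a warning; a missing panel marker is
    an error.
    """
    wanted = lib.panel.markers
    missing = [m for m in wanted if m not in image.channel_names]
    if missing:
        raise ValueError(f"image is missing panel marker channels: {missing}")
    extra = [c for c in image.channel_names if c not in wanted]
    if extra:
        logger.warning("dropping %d channels not in panel: %s", len(extra), extra)
    order = [image.channel_names.index(m) for m in wanted]
    if order == list(range(image.n_channels)):
        return image
    wavelengths = image.channel_wavelengths
    return MultiplexImage(
        data=image.data[order],
        channel_names=wanted,
        pixel_size_um=image.pixel_size_um,
        channel_wavelengths=None if wavelengths is None
        else tuple(wavelengths[i] for i in order),
    )


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".channels.yaml")


def read_image(
    path: str | PathLike,
    channel_names: Sequence[str] | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> MultiplexImage:
    """Read a channel-major TIFF stack.

    Channel names are taken, in order of precedence, from the explicit
    argument, OME metadata, or a ``<file>.channels.yaml`` sidecar list.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        names = list(channel_names) if channel_names is not None else _ome_channel_names(tf)
    if data.ndim == 2:
        data = data[None]
    if names is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            names = yaml.safe_load(sidecar.read_text())
        else:
            names = [f"channel_{i}" for i in range(data.shape[0])]
            logger.warning("%s: no channel names found; using positional names", path)
    return MultiplexImage(data=np.asarray(data, dtype=np.float32),
                          channel_names=tuple(names), pixel_size_um=pixel_size_um)


def _ome_channel_names(tf: tifffile.TiffFile) -> list[str] | None:
    if not tf.is_ome or tf.ome_metadata is None:
        return None
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        names = [c.get("Name") for c in root.iter(f"{{{ns['ome']}}}Channel")]
        if names and all(names):
            return names
    except Exception:  # malformed metadata falls back to sidecar
        logger.debug("failed to parse OME channel names", exc_info=True)
    return None


def write_image(image: MultiplexImage, path: str | PathLike) -> None:
    """Write a stack as multi-page float32 TIFF plus a channel-name sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image.data, dtype=np.float32),
                     photometric="minisblack")
    _sidecar_path(path).write_text(yaml.safe_dump(list(image.channel_names)))


def read_blank(path: str | PathLike, wavelength_tags: Sequence[str] | None = None) -> BlankStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if wavelength_tags is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            wavelength_tags = yaml.safe_load(sidecar.read_text())
        else:
            wavelength_tags = [str(i) for i in range(data.shape[0])]
    return BlankStack(data=np.asarray(data, dtype=np.float32),
                      wavelength_tags=tuple(wavelength_tags))


def write_blank(blank: BlankStack, path: str | PathLike) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(blank.data, dtype=np.float32),
                     photometric="minisblack")
    _sidecar_path(path).write_text(yaml.safe_dump(list(blank.wavelength_tags)))


def read_tissue_mask(path: str | PathLike) -> TissueMask:
    return TissueMask(tifffile.imread(path) > 0)


def write_tissue_mask(mask: TissueMask, path: str | PathLike) -> None:
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))


def read_label_mask(path: str | PathLike) -> np.ndarray:
    labels = tifffile.imread(path)
    return np.asarray(labels, dtype=np.int32)


def write_label_mask(labels: np.ndarray, path: str | PathLike) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))
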