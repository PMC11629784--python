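"""Reference pseudo-spectrum libraries.

A reference pseudo-spectrum is the ideal marker-expression vector of one
cell class over an ordered marker panel: 1 for markers the class expresses
highly, 0.5 for low expression, 0 otherwise.  Each reference is tagged with
the subcellular compartment (nucleus or membrane/cytoplasm) its markers
localise to.  The library — the ordered panel plus the named references —
is the entire supervision signal of pseudo-spectral angle mapping: no
training data, no annotations.

Libraries are stored as plain CSV, one row per reference::

    name,compartment,DAPI,CD45,CD3,...
    CD4 T cell,membrane,0,1,1,...

The marker-column order in the file defines the canonical panel order that
every image must be aligned to before mapping.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from os import PathLike
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Expression levels a strict-mode reference may use.
ALLOWED_LEVELS = (0.0, 0.5, 1.0)

COMPARTMENTS = ("nucleus", "membrane")

#: Default physical pixel size (μm per pixel) of the instrument the built-in
#: library was designed for.
DEFAULT_PIXEL_SIZE_UM = 0.1507


class LibraryValidationError(ValueError):
    """A reference library violates a structural invariant."""


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered marker panel with its physical pixel size.

    Parameters
    ----------
    markers
        Marker names in canonical order.  Every image channel stack and
        every reference vector must follow this order.
    pixel_size_um
        Physical size of one pixel in micrometres.
    """

    markers: tuple[str, ...]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        if not self.markers:
            raise LibraryValidationError("marker panel is empty")
        if any(not m for m in self.markers):
            raise LibraryValidationError("marker names must be non-empty")
        if len(set(self.markers)) != len(self.markers):
            dupes = sorted({m for m in self.markers if list(self.markers).count(m) > 1})
            raise LibraryValidationError(f"duplicate marker names: {dupes}")
        if not self.pixel_size_um > 0:
            raise LibraryValidationError("pixel_size_um must be positive")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def index_of(self, marker: str) -> int:
        return self.markers.index(marker)


@dataclass(frozen=True)
class ReferencePseudoSpectrum:
    """One cell class's ideal expression vector over a panel.

    ``values[i]`` is the expected expression of ``panel.markers[i]``:
    0 (absent), 0.5 (low) or 1 (high).  A zero-norm vector is invalid —
    cosine similarity is undefined against it.
    """

    name: str
    compartment: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if not self.name:
            raise LibraryValidationError("reference name must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise LibraryValidationError(
                f"reference {self.name!r}: compartment must be one of "
                f"{COMPARTMENTS}, got {self.compartment!r}"
            )
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise LibraryValidationError(f"reference {self.name!r}: values must be 1-D")
        object.__setattr__(self, "values", values)
        if not np.any(values > 0):
            raise LibraryValidationError(
                f"reference {self.name!r} is all-zero: cosine similarity is "
                "undefined against a zero-norm vector"
            )

    def validate_levels(self, strict: bool = True) -> None:
        """Check the expression levels.

        In strict mode every level must be one of ``ALLOWED_LEVELS``; in
        permissive mode any value in [0, 1] is accepted.
        """
        v = self.values
        if strict:
            ok = np.isin(v, ALLOWED_LEVELS)
            if not ok.all():
                bad = sorted(set(v[~ok].tolist()))
                raise LibraryValidationError(
                    f"reference {self.name!r}: levels {bad} outside {{0, 0.5, 1}}"
                )
        elif (v < 0).any() or (v > 1).any():
            raise LibraryValidationError(
                f"reference {self.name!r}: levels must lie in [0, 1]"
            )

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class ReferenceLibrary:
    """An ordered collection of reference pseudo-spectra over one panel."""

    panel: MarkerPanel
    references: tuple[ReferencePseudoSpectrum, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "references", tuple(self.references))
        if not self.references:
            raise LibraryValidationError("library has no references")
        names = [r.name for r in self.references]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise LibraryValidationError(f"duplicate reference names: {dupes}")
        for ref in self.references:
            if ref.values.shape != (self.panel.n_markers,):
                raise LibraryValidationError(
                    f"reference {ref.name!r} has {ref.values.size} values for a "
                    f"{self.panel.n_markers}-marker panel"
                )

    def __len__(self) -> int:
        return len(self.references)

    def __iter__(self):
        return iter(self.references)

    def __getitem__(self, name: str) -> ReferencePseudoSpectrum:
        for ref in self.references:
            if ref.name == name:
                return ref
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.references]

    @property
    def matrix(self) -> np.ndarray:
        """(n_references, n_markers) value matrix in library order."""
        return np.stack([r.values for r in self.references])

    def compartment_indices(self, compartment: str) -> list[int]:
        """Library indices of the references tagged with ``compartment``."""
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        return [i for i, r in enumerate(self.references) if r.compartment == compartment]

    def subset(self, names: Sequence[str]) -> "ReferenceLibrary":
        """A new library restricted to ``names``, preserving library order."""
        wanted = set(names)
        missing = wanted - set(self.names)
        if missing:
            raise KeyError(f"references not in library: {sorted(missing)}")
        return ReferenceLibrary(
            panel=self.panel,
            references=tuple(r for r in self.references if r.name in wanted),
        )

    def require_both_compartments(self) -> None:
        """Cell classification needs at least one reference per compartment."""
        for comp in COMPARTMENTS:
            if not self.compartment_indices(comp):
                raise LibraryValidationError(
                    f"library has no {comp}-compartment reference; cell "
                    "classification needs at least one per compartment"
                )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_library_rows(
    header: Sequence[str],
    rows: Iterable[Sequence[str]],
    pixel_size_um: float,
    strict_levels: bool,
) -> ReferenceLibrary:
    if len(header) < 3 or header[0] != "name" or header[1] != "compartment":
        raise LibraryValidationError(
            "library CSV must have header 'name,compartment,<marker1>,...'"
        )
    panel = MarkerPanel(markers=tuple(header[2:]), pixel_size_um=pixel_size_um)
    references = []
    for row in rows:
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != 2 + panel.n_markers:
            raise LibraryValidationError(
                f"row for {row[0]!r} has {len(row) - 2} levels for a "
                f"{panel.n_markers}-marker panel"
            )
        try:
            values = np.array([float(c) for c in row[2:]])
        except ValueError as exc:
            raise LibraryValidationError(
                f"reference {row[0]!r}: non-numeric level ({exc})"
            ) from None
        ref = ReferencePseudoSpectrum(
            name=row[0].strip(), compartment=row[1].strip(), values=values
        )
        ref.validate_levels(strict=strict_levels)
        references.append(ref)
    return ReferenceLibrary(panel=panel, references=tuple(references))


def load_library(
    path: str | PathLike,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    strict_levels: bool = True,
) -> ReferenceLibrary:
    """Load a reference library from CSV.

    The marker-column order in the file defines the panel order.  With
    ``strict_levels`` (default), every level must be 0, 0.5 or 1; set it
    False to accept arbitrary levels in [0, 1].
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LibraryValidationError(f"{path}: empty library file") from None
        return _parse_library_rows(header, reader, pixel_size_um, strict_levels)


def write_library(lib: ReferenceLibrary, path: str | PathLike) -> None:
    """Write a library as CSV (inverse of :func:`load_library`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "compartment", *lib.panel.markers])
        for ref in lib.references:
            writer.writerow(
                [ref.name, ref.compartment]
                + [_format_level(v) for v in ref.values]
            )


def _format_level(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def builtin_psc_library() -> ReferenceLibrary:
    """The packaged 13-marker, 16-reference immune-phenotyping library.

    Thirteen markers yield 16 references: three nucleus-compartment classes
    (a generic DNA-stain-only nucleus, Foxp3+ and pSTAT3+ nuclei) and 13
    membrane-compartment immune phenotypes.  Ten marker names (DAPI, Foxp3,
    pSTAT3, CD45, CD3, CD4, CD8, PD1, ICOS, IgG) and the anchor phenotypes
    (e.g. exhausted CD8 T cell = CD45/CD3/CD8/PD1) follow the published
    panel description; the remaining three markers and the value vectors of
    the classes not spelled out there are a reconstruction using standard
    immunophenotypes, with placeholder markers flagged by a ``-like``
    suffix.  Structure (panel size, reference count, compartment split) is
    exact; individual placeholder vectors are illustrative.
    """
    text = resources.files("psam.data").joinpath("psc_library.csv").read_text("utf-8")
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    lib = _parse_library_rows(
        header, reader, pixel_size_um=DEFAULT_PIXEL_SIZE_UM, strict_levels=True
    )
    lib.require_both_compartments()
    return lib
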