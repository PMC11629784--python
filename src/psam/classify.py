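"""Compartment-aware cell classification from thresholded class maps.

Each segmented cell gets one score per reference: the soft-mask-weighted
mean of that reference's (thresholded) class map over the matching
compartment — nucleus references over the nucleus soft mask, membrane
references over the membrane soft mask.  The weighted mean is
weight-normalized, sum(w * s) / sum(w), so small cells are not penalized.

Classes follow by per-compartment argmax with explicit fallbacks: a cell
scoring zero on every membrane reference is "unclassified"; one scoring
zero on every nucleus reference has a "generic nucleus".

Mean pixel intensity (MPI) per channel over the whole-cell mask is kept
for validation only — z-scored across all cells and averaged per class,
the resulting class x channel matrix should mirror each class's expected
expression profile if classification worked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .cells import CompartmentGeometry, soft_mask
from .image import MultiplexImage
from .library import ReferenceLibrary
from .mapping import ClassMapStack

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"
GENERIC_NUCLEUS = "generic nucleus"


@dataclass
class CellTable:
    """Per-cell scores, class assignments and MPI, as a DataFrame.

    Columns: ``cell_id``, ``centroid_row``, ``centroid_col``,
    ``score:<reference>`` per library reference, ``nucleus_class`` /
    ``membrane_class`` once assigned, and ``mpi:<marker>`` per channel
    once computed.
    """

    frame: pd.DataFrame
    library: ReferenceLibrary = field(repr=False)

    def __post_init__(self) -> None:
        if self.frame["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.frame["cell_id"].to_numpy()

    def scores(self, compartment: str) -> pd.DataFrame:
        """Score columns for one compartment, indexed by cell_id."""
        names = [self.library.references[i].name
                 for i in self.library.compartment_indices(compartment)]
        cols = [f"score:{n}" for n in names]
        out = self.frame.set_index("cell_id")[cols]
        out.columns = names
        return out

    def mpi(self) -> pd.DataFrame:
        cols = [c for c in self.frame.columns if c.startswith("mpi:")]
        if not cols:
            raise ValueError("MPI columns not computed; call mpi_table first")
        out = self.frame.set_index("cell_id")[cols]
        out.columns = [c.removeprefix("mpi:") for c in cols]
        return out

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def score_cells(
    stack: ClassMapStack,
    geom: CompartmentGeometry,
    lib: ReferenceLibrary,
    min_support_px: int = 1,
) -> CellTable:
    """Soft-mask-weighted compartment scores for every cell.

    ``stack`` should already be thresholded (default cutoff 0.5) so that
    low-confidence similarities contribute nothing.  A cell whose
    membrane support is empty (fully contested by Voronoi crowding, or
    below ``min_support_px``) scores 0 on all membrane references, with a
    log message rather than an error.
    """
    if not stack.thresholded:
        logger.warning(
            "scoring cells on an unthresholded stack; low-similarity pixels "
            "will contribute to scores"
        )
    if stack.shape != geom.shape:
        raise ValueError("stack and geometry shapes disagree")
    if tuple(stack.reference_names) != tuple(lib.names):
        raise ValueError("stack references do not match library")
    lib.require_both_compartments()
    nuc_idx = lib.compartment_indices("nucleus")
    mem_idx = lib.compartment_indices("membrane")

    labels = geom.labels
    objects = ndi.find_objects(geom.whole_cell)
    centroids = ndi.center_of_mass(geom.nuclei > 0, geom.nuclei, labels)

    rows = []
    n_empty_membrane = 0
    for lab, centroid in zip(labels, centroids):
        sl = objects[lab - 1]
        row: dict[str, float] = {
            "cell_id": int(lab),
            "centroid_row": float(centroid[0]),
            "centroid_col": float(centroid[1]),
        }
        for compartment, idx in (("nucleus", nuc_idx), ("membrane", mem_idx)):
            mask_img = geom.nuclei if compartment == "nucleus" else geom.membrane
            support = mask_img[sl] == lab
            if support.sum() < max(min_support_px, 1):
                if compartment == "membrane":
                    n_empty_membrane += 1
                else:  # a labelled instance always has nucleus pixels
                    logger.warning("cell %d has empty nucleus support", lab)
                for i in idx:
                    row[f"score:{stack.reference_names[i]}"] = 0.0
                continue
            w = soft_mask(support)
            wsum = w.sum()
            sub = stack.maps[(slice(None), *sl)]
            for i in idx:
                row[f"score:{stack.reference_names[i]}"] = float(
                    (sub[i] * w).sum() / wsum
                )
        rows.append(row)
    if n_empty_membrane:
        logger.info("%d cells with empty membrane support scored 0", n_empty_membrane)
    if not rows:
        raise ValueError("no cell instances in geometry")
    return CellTable(frame=pd.DataFrame(rows), library=lib)


def assign_classes(table: CellTable) -> CellTable:
    """Fill nucleus_class / membrane_class by per-compartment argmax.

    Ties break to the lower library index; an all-zero compartment falls
    back to "unclassified" (membrane) or "generic nucleus" (nucleus).
    """
    frame = table.frame.copy()
    for compartment, fallback, column in (
        ("nucleus", GENERIC_NUCLEUS, "nucleus_class"),
        ("membrane", UNCLASSIFIED, "membrane_class"),
    ):
        scores = table.scores(compartment)
        # idxmax is first-match, honouring library (column) order on ties
        winners = scores.idxmax(axis=1)
        winners[scores.max(axis=1) <= 0] = fallback
        frame[column] = frame["cell_id"].map(winners)
    return CellTable(frame=frame, library=table.library)


def mpi_table(img: MultiplexImage, geom: CompartmentGeometry, table: CellTable) -> CellTable:
    """Mean pixel intensity of every channel over each whole-cell mask."""
    if img.shape != geom.shape:
        raise ValueError("image and geometry shapes disagree")
    frame = table.frame.copy()
    labels = frame["cell_id"].to_numpy()
    for c, marker in enumerate(img.channel_names):
        means = ndi.mean(img.data[c], labels=geom.whole_cell, index=labels)
        frame[f"mpi:{marker}"] = means
    return CellTable(frame=frame, library=table.library)


def class_mpi_zscores(table: CellTable, compartment: str = "membrane") -> pd.DataFrame:
    """Average per-channel MPI z-score for each assigned cell class.

    MPI is z-scored per channel across *all* cells in the table, then
    averaged within each class of the chosen compartment — the standard
    validation heatmap: a class's high-expression markers should carry
    the large positive entries of its row.  Zero-variance channels yield
    a zero column with a warning.
    """
    column = {"nucleus": "nucleus_class", "membrane": "membrane_class"}[compartment]
    if column not in table.frame.columns:
        raise ValueError("classes not assigned; call assign_classes first")
    mpi = table.mpi()
    if len(mpi) < 2:
        raise ValueError("z-scoring needs at least 2 cells")
    sd = mpi.std(axis=0, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "zero-variance channels z-scored to 0: %s", list(mpi.columns[degenerate])
        )
    z = (mpi - mpi.mean(axis=0)).div(sd.where(~degenerate, 1.0), axis=1)
    z.loc[:, degenerate] = 0.0
    classes = table.frame.set_index("cell_id")[column]
    return z.groupby(classes).mean()
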