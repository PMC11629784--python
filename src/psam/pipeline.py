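"""End-to-end run orchestration.

``run_pipeline`` sequences the full analysis — preprocessing, class-map
computation, pixel classification, compartment geometry, cell
classification, MPI validation and proximity scoring — from a single
:class:`RunConfig`, writing every artifact plus a JSON manifest (all
parameters, package version, input hashes) so a run can be re-executed
exactly from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cells import DEFAULT_DILATION_RADIUS_PX, CompartmentGeometry
from .classify import assign_classes, class_mpi_zscores, mpi_table, score_cells
from .image import (
    MultiplexImage,
    TissueMask,
    align_image_to_library,
    read_blank,
    read_image,
    read_label_mask,
    write_image,
    write_label_mask,
    write_tissue_mask,
)
from .library import DEFAULT_PIXEL_SIZE_UM, load_library
from .mapping import (
    DEFAULT_THRESHOLD,
    argmax_class_map,
    class_prevalence,
    compute_class_stack,
    max_intensity_projection,
    mean_class_score,
    save_class_stack,
    save_pixel_class_map,
    threshold_stack,
)
from .preprocess import (
    DEFAULT_CLOSE_RADIUS,
    DEFAULT_MIN_OBJECT,
    DEFAULT_PERCENTILE,
    background_correct,
    compute_tissue_mask,
    normalize_channels,
)
from .proximity import DEFAULT_SIGMA_PX, proximity_score_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Parameter defaults are the method's published operating point:
    class-map threshold 0.5, dilation radius 7 px (~1 μm), proximity
    sigma 22.36 px, normalization percentile 99.
    """

    image: str
    nuclei: str
    out_dir: str
    library: str | None = None  # None -> packaged PSC library
    blank: str | None = None  # None -> skip background correction
    threshold: float = DEFAULT_THRESHOLD
    radius_px: int = DEFAULT_DILATION_RADIUS_PX
    sigma_px: float = DEFAULT_SIGMA_PX
    normalize_percentile: float = DEFAULT_PERCENTILE
    tissue_close_radius: int = DEFAULT_CLOSE_RADIUS
    tissue_min_object: int = DEFAULT_MIN_OBJECT
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    skip_normalize: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | PathLike) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis; returns the artifact directory.

    Stage failures are re-raised with the stage name and input so a long
    run fails loudly and diagnosably.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {"image": cfg.image, "nuclei": cfg.nuclei}
    if cfg.library:
        inputs["library"] = cfg.library
    if cfg.blank:
        inputs["blank"] = cfg.blank
    for name, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"missing input {name!r}: {path}")

    manifest: dict = {
        "psam_version": __version__,
        "parameters": cfg.to_dict(),
        "input_sha256": {k: _hash_file(Path(v)) for k, v in inputs.items()},
        "stages": {},
    }

    def stage(name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return result

    if cfg.library:
        lib = load_library(cfg.library, pixel_size_um=cfg.pixel_size_um)
    else:
        from .library import builtin_psc_library

        lib = builtin_psc_library()
    lib.require_both_compartments()

    img = read_image(cfg.image, pixel_size_um=cfg.pixel_size_um)
    img = align_image_to_library(img, lib)
    if cfg.blank:
        blank = read_blank(cfg.blank)
        img = stage("background_correct", background_correct, img, blank)
    if not cfg.skip_normalize:
        img = stage("normalize", normalize_channels, img, cfg.normalize_percentile)
    write_image(img, out / "preprocessed.tif")

    tissue = stage(
        "tissue_mask", compute_tissue_mask, img,
        cfg.tissue_close_radius, cfg.tissue_min_object,
    )
    write_tissue_mask(tissue, out / "tissue_mask.tif")

    stack = stage("class_maps", compute_class_stack, img, lib)
    save_class_stack(stack, out / "class_maps.tif")
    pcm = stage("pixel_classes", argmax_class_map, stack, tissue)
    save_pixel_class_map(pcm, out / "pixel_classes.tif")

    mip, _ = max_intensity_projection(stack, tissue)
    prevalence = class_prevalence(pcm)
    mean_scores = mean_class_score(stack, pcm)
    _write_table(out / "pixel_summary.csv", prevalence, mean_scores)

    nuclei = read_label_mask(cfg.nuclei)
    if nuclei.shape != img.shape:
        raise ValueError(
            f"nuclei mask shape {nuclei.shape} does not match image {img.shape}"
        )
    geom = stage("geometry", CompartmentGeometry.from_nuclei, nuclei, cfg.radius_px)
    write_label_mask(geom.whole_cell, out / "whole_cell.tif")
    write_label_mask(geom.membrane, out / "membrane.tif")

    thresholded = threshold_stack(stack, cfg.threshold)
    table = stage("score_cells", score_cells, thresholded, geom, lib)
    table = assign_classes(table)
    table = stage("mpi", mpi_table, img, geom, table)
    table.to_csv(out / "cells.csv")

    if len(table) >= 2:
        z = class_mpi_zscores(table)
        z.to_csv(out / "class_mpi_zscores.csv")

    matrix = stage(
        "proximity", proximity_score_matrix, table, geom, pcm, tissue, cfg.sigma_px
    )
    matrix.to_csv(out / "proximity_matrix.csv")

    manifest["mip_min_on_tissue"] = (
        float(mip[tissue.mask].min()) if tissue.mask.any() else None
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _write_table(path: Path, prevalence: dict, mean_scores: dict) -> None:
    import pandas as pd

    pd.DataFrame(
        {"prevalence": prevalence, "mean_class_score": mean_scores}
    ).rename_axis("class").to_csv(path)
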