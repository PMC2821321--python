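"""Seeded generator of synthetic plates for end-to-end testing.

Emulates the two study designs this toolkit targets without any real
microscopy data: fluorescent nuclei imaged in a DNA channel (mitotic nuclei
brighter, smaller and more textured than interphase ones), cell regions
defined by expanding each nucleus, and bacterial "spots" in a second channel
docking onto cells with class-dependent Poisson rates — by default a strong
preference for mitotic cells. A fraction of images can be rendered out of
focus by Gaussian blur. Everything (images, label matrices, manifest, ground
truth) is reproducible from a single seed, and ground truth is kept beside —
never inside — the measurement tables.

Also provides Gaussian feature blobs for classifier tests, where the
separation between class centroids is set in units of the within-class
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import ndimage

from .data import (
    ImageKey,
    ImageRecord,
    LabelMatrix,
    ObjectRef,
    ObjectTable,
    PlateLayout,
    PLATE_96,
    save_label_matrix,
    write_manifest,
)
from .features import expand_to_cells, extract_features, neighbors, relate_children
from .vectors import EvalContext

__all__ = ["PlateSpec", "SyntheticImage", "SyntheticPlate", "generate_plate",
           "generate_feature_blobs"]

CLASS_NORMAL = "normal"
CLASS_MITOTIC = "mitotic"


@dataclass(frozen=True)
class PlateSpec:
    """Study conditions for one synthetic plate.

    Defaults mirror a docking assay in 96-well format: 4 images per well,
    ~30 cells per image, a mitotic index of 8%, and Poisson docking rates
    giving mitotic cells 5x the spot rate of normal cells, with neighbors of
    mitotic cells in between.
    """

    layout: PlateLayout = PLATE_96
    wells: tuple[str, ...] = ("A01", "A02", "B01", "B02")
    images_per_well: int = 4
    cells_per_image: float = 30.0
    mitotic_fraction: float = 0.08
    spot_rate_normal: float = 0.3
    spot_rate_neighbor: float = 1.0
    spot_rate_mitotic: float = 1.5
    blur_fraction: float = 0.0
    blur_sigma: float = 3.0
    image_size: int = 256
    nucleus_radius: int = 6
    cell_expansion: int = 12
    seed: int = 0
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        for r in (self.spot_rate_normal, self.spot_rate_neighbor, self.spot_rate_mitotic):
            if r < 0:
                raise ValueError("spot rates must be >= 0")
        for f in (self.mitotic_fraction, self.blur_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        # rough capacity check: each nucleus claims a square of side 3r
        if self.cells_per_image * (3 * self.nucleus_radius) ** 2 > self.image_size**2:
            raise ValueError("cells_per_image exceeds image capacity")


@dataclass
class SyntheticImage:
    key: ImageKey
    channels: dict[str, np.ndarray]
    labelmatrices: dict[str, LabelMatrix]
    blurred: bool


@dataclass
class SyntheticPlate:
    """All rendered sites of one plate plus the ground truth tables."""

    spec: PlateSpec
    images: list[SyntheticImage]
    truth_objects: pd.DataFrame  # plate, well, site, object_id, true_class,
    #                              mitotic_neighbor, n_spots
    truth_images: pd.DataFrame  # plate, well, site, blurred

    def records(self) -> list[ImageRecord]:
        recs = []
        for im in self.images:
            recs.append(
                ImageRecord(
                    key=im.key,
                    channel_paths={c: f"{_stem(im.key)}_{c}.tif" for c in im.channels},
                    labelmatrix_paths={
                        t: f"{_stem(im.key)}_{t}_labels.tif" for t in im.labelmatrices
                    },
                )
            )
        return recs

    def truth_labels(self, object_type: str = "nuclei") -> dict[ObjectRef, str]:
        return {
            ObjectRef(r.plate, r.well, int(r.site), int(r.object_id)): str(r.true_class)
            for r in self.truth_objects.itertuples()
        }

    def measure(self, kinds: tuple[str, ...] = ("intensity",),
                object_type: str = "nuclei", **params) -> ObjectTable:
        """Extract features for every site's objects of one type, from the
        rendered images only (ground truth never leaks into the table)."""
        tables = [
            extract_features(im.channels, im.labelmatrices[object_type], im.key,
                             kinds=kinds, **params)
            for im in self.images
        ]
        df = pd.concat([t.df for t in tables], ignore_index=True)
        return ObjectTable(df, object_type)

    def build_context(self, table: ObjectTable | None = None) -> EvalContext:
        """Evaluation context with spot-to-cell relations and cell neighbor
        graphs precomputed for every image."""
        ctx = EvalContext()
        if table is not None:
            ctx.tables[table.object_type] = table
        rel: dict[ImageKey, object] = {}
        for im in self.images:
            if "spots" in im.labelmatrices and "cells" in im.labelmatrices:
                rel[im.key] = relate_children(
                    im.labelmatrices["cells"], im.labelmatrices["spots"]
                )
            if "cells" in im.labelmatrices:
                g = neighbors(im.labelmatrices["cells"], 0)
                ctx.neighbor_graphs[("cells", im.key)] = g
                ctx.neighbor_graphs[("nuclei", im.key)] = g  # cell ids = nucleus ids
        if rel:
            ctx.relations[("cells", "spots")] = dict(rel)
            ctx.relations[("nuclei", "spots")] = dict(rel)
        ctx.images = self.records()
        return ctx

    def write(self, outdir: str | Path) -> Path:
        """Write TIFF channels and label matrices, the manifest and the
        ground-truth CSVs; returns the manifest path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records = []
        for im in self.images:
            chan_paths, label_paths = {}, {}
            for c, arr in im.channels.items():
                p = outdir / f"{_stem(im.key)}_{c}.tif"
                import tifffile

                tifffile.imwrite(str(p), arr.astype(np.float32))
                chan_paths[c] = str(p)
            for t, lm in im.labelmatrices.items():
                p = outdir / f"{_stem(im.key)}_{t}_labels.tif"
                save_label_matrix(lm, p)
                label_paths[t] = str(p)
            records.append(
                ImageRecord(key=im.key, channel_paths=chan_paths,
                            labelmatrix_paths=label_paths)
            )
        manifest = outdir / "manifest.csv"
        write_manifest(records, manifest)
        self.truth_objects.to_csv(outdir / "truth_objects.csv", index=False)
        self.truth_images.to_csv(outdir / "truth_images.csv", index=False)
        return manifest


def _stem(key: ImageKey) -> str:
    return f"{key.plate}_{key.well}_s{key.site}"


def _place_centers(
    rng: np.random.Generator, n: int, size: int, min_sep: float, margin: int
) -> np.ndarray:
    """Rejection-sample blob centers with a minimum separation."""
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n and attempts < 200 * max(n, 1):
        attempts += 1
        p = rng.uniform(margin, size - margin, 2)
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep**2 for q in centers):
            centers.append((p[0], p[1]))
    return np.array(centers) if centers else np.empty((0, 2))


def _render_site(
    rng: np.random.Generator, spec: PlateSpec, key: ImageKey
) -> tuple[SyntheticImage, pd.DataFrame]:
    size = spec.image_size
    r_n = spec.nucleus_radius
    r_m = max(2, round(0.7 * r_n))
    n_cells = max(1, int(rng.poisson(spec.cells_per_image)))
    centers = _place_centers(rng, n_cells, size, min_sep=2.6 * r_n, margin=r_n + 2)
    n_cells = len(centers)
    mitotic = rng.random(n_cells) < spec.mitotic_fraction

    Y, X = np.mgrid[0:size, 0:size]
    nuclei_px = np.zeros((size, size), dtype=np.int32)
    dna = rng.normal(0.05, 0.01, (size, size))
    for i, (cy, cx) in enumerate(centers, start=1):
        is_m = mitotic[i - 1]
        r = r_m if is_m else r_n
        amp = 0.75 if is_m else 0.5  # mitotic ~1.5x brighter
        d2 = (Y - cy) ** 2 + (X - cx) ** 2
        mask = d2 <= r**2
        nuclei_px[mask] = i
        blob = amp * np.exp(-d2 / (2 * (r / 1.8) ** 2))
        # condensed-chromatin texture: stronger speckle inside mitotic nuclei
        tex_sd = 0.08 if is_m else 0.03
        texture = rng.normal(0, tex_sd, (size, size))
        dna += blob + np.where(mask, texture, 0.0)
    dna = np.clip(dna, 0.0, 1.0)

    nuclei = LabelMatrix(nuclei_px, "nuclei")
    cells = expand_to_cells(nuclei, spec.cell_expansion)

    # neighbor-of-mitotic from cell adjacency (touching expanded regions)
    graph = neighbors(cells, 0)
    mitotic_ids = {i + 1 for i in range(n_cells) if mitotic[i]}
    neighbor_flag = np.array(
        [
            (i + 1 not in mitotic_ids)
            and bool(graph.neighbors_of(i + 1) & mitotic_ids)
            for i in range(n_cells)
        ]
    )

    rates = np.where(
        mitotic,
        spec.spot_rate_mitotic,
        np.where(neighbor_flag, spec.spot_rate_neighbor, spec.spot_rate_normal),
    )
    n_spots = rng.poisson(rates)

    spot_r = 2
    spots_px = np.zeros((size, size), dtype=np.int32)
    bact = rng.normal(0.03, 0.008, (size, size))
    sid = 0
    for i in range(n_cells):
        cell_mask = cells.pixels == i + 1
        inner = ndimage.binary_erosion(cell_mask, iterations=spot_r + 1)
        pool = np.argwhere(inner if inner.any() else cell_mask)
        for _ in range(int(n_spots[i])):
            sid += 1
            cy, cx = pool[rng.integers(len(pool))]
            d2 = (Y - cy) ** 2 + (X - cx) ** 2
            m = d2 <= spot_r**2
            spots_px[m] = sid
            bact += 0.8 * np.exp(-d2 / (2 * 1.2**2))
    bact = np.clip(bact, 0.0, 1.0)

    blurred = bool(rng.random() < spec.blur_fraction)
    if blurred:
        dna = ndimage.gaussian_filter(dna, spec.blur_sigma)
        bact = ndimage.gaussian_filter(bact, spec.blur_sigma)

    truth = pd.DataFrame(
        {
            "plate": key.plate,
            "well": key.well,
            "site": key.site,
            "object_id": np.arange(1, n_cells + 1),
            "true_class": np.where(mitotic, CLASS_MITOTIC, CLASS_NORMAL),
            "mitotic_neighbor": neighbor_flag.astype(int),
            "n_spots": n_spots,
        }
    )
    image = SyntheticImage(
        key=key,
        channels={"dna": dna, "bacteria": bact},
        labelmatrices={"nuclei": nuclei, "cells": cells,
                       "spots": LabelMatrix(spots_px, "spots")},
        blurred=blurred,
    )
    return image, truth


def generate_plate(spec: PlateSpec, outdir: str | Path | None = None) -> SyntheticPlate:
    """Render every site of the spec's wells; optionally write all files.

    Fully reproducible from ``spec.seed``: identical specs yield identical
    pixels, label matrices and truth tables.
    """
    rng = np.random.default_rng(spec.seed)
    images: list[SyntheticImage] = []
    truths: list[pd.DataFrame] = []
    img_rows = []
    for well in spec.wells:
        for site in range(spec.images_per_well):
            key = ImageKey(spec.plate_id, well, site)
            im, truth = _render_site(rng, spec, key)
            images.append(im)
            truths.append(truth)
            img_rows.append(
                {"plate": key.plate, "well": key.well, "site": key.site,
                 "blurred": int(im.blurred)}
            )
    plate = SyntheticPlate(
        spec=spec,
        images=images,
        truth_objects=pd.concat(truths, ignore_index=True),
        truth_images=pd.DataFrame(img_rows),
    )
    if outdir is not None:
        plate.write(outdir)
    return plate


def generate_feature_blobs(
    n_per_class: int,
    k: int = 2,
    separation: float = 4.0,
    n_features: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian class clusters for classifier tests.

    Class centroids are placed so every pair is ``separation`` apart, in
    units of the (unit) within-class standard deviation. Returns (X, y) with
    string labels ``class0..class{k-1}`` and exact per-class counts.
    """
    if n_features < 2:
        raise ValueError("need at least 2 features")
    if k > n_features:
        raise ValueError("cannot place k equidistant centroids in this dimension")
    rng = np.random.default_rng(seed)
    # centroids at e_i * separation/sqrt(2): every pair is `separation` apart
    centers = np.zeros((k, n_features))
    for i in range(k):
        centers[i, i] = separation / np.sqrt(2)
    X = np.vstack(
        [rng.normal(0, 1.0, (n_per_class, n_features)) + centers[i] for i in range(k)]
    )
    y = np.repeat([f"class{i}" for i in range(k)], n_per_class)
    return X, y
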