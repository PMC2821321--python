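"""Per-object and per-image feature extraction.

Covers the measurements a phenotype classifier for fluorescence microscopy
typically consumes: order-statistic intensity features over an object and its
edge, Haralick texture statistics from a masked grey-level co-occurrence
matrix, directional Gabor responses, bright-region contrast/shape features for
ruffle-like phenotypes, a granularity spectrum (erosion + reconstruction) used
for focus scoring, and inter-object geometry: spot-to-cell relation, neighbor
graphs and nucleus-to-cell expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gabor, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image, disk, reconstruction

from .data import ImageKey, LabelMatrix, NeighborGraph, ObjectTable, RelationTable

__all__ = [
    "IntensityFeatures",
    "BrightRegionFeatures",
    "GranularitySpectrum",
    "intensity_features",
    "inner_boundary",
    "haralick_features",
    "HARALICK_NAMES",
    "gabor_features",
    "bright_region_features",
    "granularity_spectrum",
    "relate_children",
    "neighbors",
    "expand_to_cells",
    "extract_features",
]


# ---------------------------------------------------------------------------
# Intensity

@dataclass(frozen=True)
class IntensityFeatures:
    """Order statistics over an object's pixels and its edge pixels."""

    min: float
    max: float
    mean: float
    median: float
    edge_min: float
    edge_max: float
    edge_mean: float
    edge_median: float

    def as_dict(self) -> dict[str, float]:
        return {
            "int_min": self.min,
            "int_max": self.max,
            "int_mean": self.mean,
            "int_median": self.median,
            "edge_min": self.edge_min,
            "edge_max": self.edge_max,
            "edge_mean": self.edge_mean,
            "edge_median": self.edge_median,
        }


def inner_boundary(labelmatrix: np.ndarray, object_id: int) -> np.ndarray:
    """1-pixel-wide inner boundary: object pixels with a 4-neighbor that is
    background or another object (image borders count as boundary)."""
    mask = labelmatrix == object_id
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~interior


def intensity_features(
    image: np.ndarray, mask: np.ndarray, edge_mask: np.ndarray | None = None
) -> IntensityFeatures:
    """Min/max/mean/median intensity over an object and over its edge region.

    If ``edge_mask`` is omitted the object's 1-pixel inner boundary is used.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty object mask")
    if edge_mask is None:
        edge_mask = inner_boundary(mask.astype(np.int32), 1)
    edge_mask = np.asarray(edge_mask, dtype=bool)
    vals = np.asarray(image, dtype=float)[mask]
    edge = np.asarray(image, dtype=float)[edge_mask]
    if edge.size == 0:
        edge = vals
    return IntensityFeatures(
        float(vals.min()),
        float(vals.max()),
        float(vals.mean()),
        float(np.median(vals)),
        float(edge.min()),
        float(edge.max()),
        float(edge.mean()),
        float(np.median(edge)),
    )


# ---------------------------------------------------------------------------
# Haralick texture

HARALICK_NAMES = [
    "haralick_asm",
    "haralick_contrast",
    "haralick_correlation",
    "haralick_variance",
    "haralick_idm",
    "haralick_sum_average",
    "haralick_sum_variance",
    "haralick_sum_entropy",
    "haralick_entropy",
    "haralick_diff_variance",
    "haralick_diff_entropy",
    "haralick_imc1",
    "haralick_imc2",
]

_GLCM_OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1)]  # 0, 45, 90, 135 degrees


def _quantize(image: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of masked pixels over the object's min-max
    range; returns -1 outside the mask."""
    q = np.full(image.shape, -1, dtype=np.int32)
    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        q[mask] = 0
    else:
        bins = np.clip(
            ((image[mask] - lo) / (hi - lo) * levels).astype(np.int32), 0, levels - 1
        )
        q[mask] = bins
    return q


def masked_glcm(
    image: np.ndarray,
    mask: np.ndarray,
    levels: int = 8,
    distance: int = 1,
) -> list[np.ndarray]:
    """Symmetric, normalized co-occurrence matrices for the four standard
    directions, counting only pixel pairs that both lie inside the mask.
    Directions without any co-occurring pair are omitted."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    q = _quantize(image, mask, levels)
    out = []
    for dr, dc in _GLCM_OFFSETS:
        dr, dc = dr * distance, dc * distance
        h, w = q.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        P = np.zeros((levels, levels), dtype=float)
        np.add.at(P, (a[ok], b[ok]), 1.0)
        P = P + P.T  # symmetrize
        out.append(P / P.sum())
    return out


def _haralick_from_glcm(P: np.ndarray) -> np.ndarray:
    """The 13 classical texture statistics of one normalized GLCM."""
    eps = np.finfo(float).tiny
    n = P.shape[0]
    i = np.arange(n, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux, muy = float(px @ i), float(py @ i)
    sx = math.sqrt(float(px @ (i - mux) ** 2))
    sy = math.sqrt(float(py @ (i - muy) ** 2))

    asm = float((P**2).sum())
    contrast = float((P * (I - J) ** 2).sum())
    if sx * sy > 0:
        correlation = float(((I - mux) * (J - muy) * P).sum() / (sx * sy))
    else:
        correlation = 0.0
    mu = float((P * I).sum())  # == mux for symmetric P
    variance = float((P * (I - mu) ** 2).sum())
    idm = float((P / (1.0 + (I - J) ** 2)).sum())

    # distributions of i+j (0..2n-2) and |i-j| (0..n-1)
    psum = np.zeros(2 * n - 1)
    np.add.at(psum, (I + J).astype(int).ravel(), P.ravel())
    pdiff = np.zeros(n)
    np.add.at(pdiff, np.abs(I - J).astype(int).ravel(), P.ravel())
    ks = np.arange(2 * n - 1, dtype=float)
    kd = np.arange(n, dtype=float)
    sum_avg = float(psum @ ks)
    sum_var = float(psum @ (ks - sum_avg) ** 2)
    sum_ent = float(-(psum * np.log(psum + eps)).sum())
    entropy = float(-(P * np.log(P + eps)).sum())
    diff_avg = float(pdiff @ kd)
    diff_var = float(pdiff @ (kd - diff_avg) ** 2)
    diff_ent = float(-(pdiff * np.log(pdiff + eps)).sum())

    hx = float(-(px * np.log(px + eps)).sum())
    hy = float(-(py * np.log(py + eps)).sum())
    pxy = np.outer(px, py)
    hxy1 = float(-(P * np.log(pxy + eps)).sum())
    hxy2 = float(-(pxy * np.log(pxy + eps)).sum())
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_avg,
            sum_var,
            sum_ent,
            entropy,
            diff_var,
            diff_ent,
            imc1,
            imc2,
        ]
    )


def haralick_features(
    image: np.ndarray,
    mask: np.ndarray,
    levels: int = 8,
    distance: int = 1,
    strict: bool = True,
) -> dict[str, float]:
    """13 Haralick statistics averaged over the 4 co-occurrence directions.

    Masked pixels are quantized to ``levels`` equal-width grey bins over the
    object's own min-max range. A degenerate mask (no co-occurring pixel pair
    in any direction) raises when ``strict`` else yields missing values — the
    batch extractor uses the latter so isolated 1-pixel objects do not abort a
    plate run.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        if strict:
            raise ValueError("mask must contain at least 2 pixels")
        return {n: float("nan") for n in HARALICK_NAMES}
    glcms = masked_glcm(image, mask, levels=levels, distance=distance)
    if not glcms:
        if strict:
            raise ValueError("no co-occurring pixel pair inside the mask")
        return {n: float("nan") for n in HARALICK_NAMES}
    stats = np.mean([_haralick_from_glcm(P) for P in glcms], axis=0)
    return dict(zip(HARALICK_NAMES, stats))


# ---------------------------------------------------------------------------
# Gabor

def gabor_features(
    image: np.ndarray,
    mask: np.ndarray,
    frequency: float = 0.25,
    sigma: float = 2.0,
) -> tuple[float, float]:
    """Mean Gabor response magnitude over the object at 0 and 90 degrees.

    ``gabor_x`` responds to intensity variation along the x (column) axis,
    ``gabor_y`` along the y (row) axis. The object mean is subtracted before
    filtering so a constant object yields exactly (0, 0). Default frequency
    corresponds to a 4-pixel wavelength, sigma = wavelength / 2.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty object mask")
    img = np.asarray(image, dtype=float).copy()
    img -= img[mask].mean()
    img[~mask] = 0.0
    out = []
    # skimage theta=0 modulates along the column (x) axis
    for theta in (0.0, np.pi / 2):  # x-direction, y-direction
        re, im = gabor(img, frequency=frequency, theta=theta, sigma_x=sigma, sigma_y=sigma)
        mag = np.hypot(re, im)
        out.append(float(mag[mask].mean()))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Bright-region (ruffle) features

@dataclass(frozen=True)
class BrightRegionFeatures:
    """Contrast of a bright sub-region against the rest of the object, plus
    shape of the region for the top-fraction method."""

    method: str
    contrast_difference: float
    contrast_zscore: float
    solidity: float = float("nan")
    eccentricity: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        d = {
            f"bright_{self.method}_diff": self.contrast_difference,
            f"bright_{self.method}_zscore": self.contrast_zscore,
        }
        if self.method == "top_fraction":
            d["bright_top_solidity"] = self.solidity
            d["bright_top_eccentricity"] = self.eccentricity
        return d


def bright_region_features(
    image: np.ndarray,
    mask: np.ndarray,
    method: str = "top_fraction",
    fraction: float = 0.05,
    radius: float | None = None,
) -> BrightRegionFeatures:
    """Select the brightest sub-region of an object and measure its contrast.

    Methods: ``otsu`` (pixels above the Otsu threshold of the masked
    intensities), ``circular_mask`` (disk of the given radius centered on the
    intensity-weighted centroid), ``top_fraction`` (pixels at or above the
    (1 - fraction) intensity quantile; additionally reports solidity and
    eccentricity of the selected region).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty object mask")
    img = np.asarray(image, dtype=float)
    vals = img[mask]

    if method == "otsu":
        if np.ptp(vals) == 0:
            bright = mask.copy()
        else:
            bright = mask & (img > threshold_otsu(vals))
    elif method == "circular_mask":
        if radius is None:
            raise ValueError("circular_mask requires a radius")
        w = np.clip(vals, 0, None)
        rr, cc = np.nonzero(mask)
        if w.sum() > 0:
            cy, cx = float((rr * w).sum() / w.sum()), float((cc * w).sum() / w.sum())
        else:
            cy, cx = float(rr.mean()), float(cc.mean())
        Y, X = np.ogrid[: img.shape[0], : img.shape[1]]
        bright = mask & ((Y - cy) ** 2 + (X - cx) ** 2 <= radius**2)
    elif method == "top_fraction":
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        q = np.quantile(vals, 1.0 - fraction)
        bright = mask & (img >= q)
    else:
        raise ValueError(f"unknown bright-region method {method!r}")

    rest = mask & ~bright
    if not bright.any():
        diff = zscore = float("nan")
    elif not rest.any():
        # bright region covers the whole object: no contrast is measurable;
        # a constant object has zero contrast by definition.
        diff = 0.0 if np.ptp(vals) == 0 else float("nan")
        zscore = float("nan")
    else:
        mb, mr = float(img[bright].mean()), float(img[rest].mean())
        diff = mb - mr
        sd = float(img[rest].std())
        zscore = (mb - mr) / sd if sd > 0 else float("nan")

    solidity = eccentricity = float("nan")
    if method == "top_fraction" and bright.any():
        hull = convex_hull_image(bright)
        solidity = float(bright.sum() / hull.sum())
        props = regionprops(bright.astype(np.uint8))[0]
        eccentricity = float(props.eccentricity)
    return BrightRegionFeatures(method, diff, zscore, solidity, eccentricity)


# ---------------------------------------------------------------------------
# Granularity

@dataclass(frozen=True)
class GranularitySpectrum:
    """Per-round drop of the mean image intensity under iterated grey erosion
    followed by morphological reconstruction; low for blurred images."""

    values: np.ndarray

    @property
    def scalar(self) -> float:
        return float(np.sum(self.values))


def granularity_spectrum(
    image: np.ndarray, rounds: int = 16, selem_radius: int = 1
) -> GranularitySpectrum:
    """Granularity spectrum of a whole image.

    ``values[i]`` is the mean intensity of the reconstruction after ``i``
    rounds minus the mean after ``i + 1`` rounds, where one round erodes the
    running image with a disk and reconstructs it under the original. The
    spectrum is non-negative and vanishes for constant images; Gaussian blur
    lowers its sum, which is the scalar used for focus scoring.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    img = np.asarray(image, dtype=float)
    footprint = disk(selem_radius)
    eroded = img
    prev_mean = img.mean()
    values = np.empty(rounds)
    for i in range(rounds):
        eroded = ndimage.grey_erosion(eroded, footprint=footprint)
        recon = reconstruction(np.minimum(eroded, img), img, method="dilation")
        m = recon.mean()
        values[i] = prev_mean - m
        prev_mean = m
    return GranularitySpectrum(values)


# ---------------------------------------------------------------------------
# Inter-object geometry

def relate_children(parent: LabelMatrix, child: LabelMatrix) -> RelationTable:
    """Assign each child object overlapping a parent to exactly one parent.

    A child overlapping several parents goes to the parent with maximal
    overlap area, ties to the lower parent id. Children with zero parent
    overlap stay unassigned.
    """
    if parent.pixels.shape != child.pixels.shape:
        raise ValueError("parent and child label matrices differ in shape")
    p, c = parent.pixels.ravel(), child.pixels.ravel()
    both = (p > 0) & (c > 0)
    pairs: list[tuple[int, int]] = []
    if both.any():
        df = pd.DataFrame({"parent": p[both], "child": c[both]})
        counts = df.groupby(["child", "parent"]).size().reset_index(name="n")
        counts = counts.sort_values(["child", "n", "parent"], ascending=[True, False, True])
        best = counts.drop_duplicates("child")
        pairs = [(int(r.parent), int(r.child)) for r in best.itertuples()]
    child_counts = {int(i): 0 for i in parent.object_ids}
    for pid, _ in pairs:
        child_counts[pid] += 1
    return RelationTable(parent.object_type, child.object_type, pairs, child_counts)


def neighbors(objects: LabelMatrix, distance: int = 0) -> NeighborGraph:
    """Neighbor graph: (a, b) is an edge iff dilating a's mask by ``distance``
    pixels (Euclidean disk) touches b's mask (overlap or 8-adjacency).
    Distance 0 connects exactly the touching objects."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    lm = objects.pixels
    edges: set[tuple[int, int]] = set()
    footprint = disk(distance) if distance > 0 else None
    for oid in objects.object_ids:
        m = lm == oid
        if footprint is not None:
            m = ndimage.binary_dilation(m, structure=footprint)
        m = ndimage.binary_dilation(m, structure=np.ones((3, 3), bool))  # 8-adjacency
        hit = np.unique(lm[m])
        for other in hit:
            if other > 0 and other != oid:
                edges.add((min(int(oid), int(other)), max(int(oid), int(other))))
    return NeighborGraph(objects.object_type, edges)


def expand_to_cells(nuclei: LabelMatrix, max_distance: float) -> LabelMatrix:
    """Define cell regions by expanding each nucleus.

    Every pixel within ``max_distance`` (Euclidean) of a nucleus takes the id
    of the nearest nucleus; equidistant pixels go to the lower id; nucleus
    pixels keep their own id.
    """
    lm = nuclei.pixels
    ids = nuclei.object_ids
    if ids.size == 0:
        return LabelMatrix(np.zeros_like(lm), "cells")
    # Per-label distance maps, stacked in id order so argmin breaks ties
    # toward the lower id. Exact but O(n_labels * n_pixels); fine at the
    # image sizes this toolkit targets.
    dists = np.stack(
        [ndimage.distance_transform_edt(lm != oid) for oid in ids], axis=0
    )
    nearest = np.argmin(dists, axis=0)
    mindist = np.min(dists, axis=0)
    out = ids[nearest].astype(lm.dtype)
    out[mindist > max_distance] = 0
    out[lm > 0] = lm[lm > 0]  # nucleus pixels always keep their id
    return LabelMatrix(out, "cells")


# ---------------------------------------------------------------------------
# Batch extraction

def extract_features(
    channels: dict[str, np.ndarray],
    labelmatrix: LabelMatrix,
    image: ImageKey,
    kinds: tuple[str, ...] = ("intensity",),
    haralick_levels: int = 8,
    haralick_distance: int = 1,
    gabor_frequency: float = 0.25,
    gabor_sigma: float = 2.0,
    bright_fraction: float = 0.05,
    bright_methods: tuple[str, ...] = ("otsu", "top_fraction"),
) -> ObjectTable:
    """Measure every object of one image; one row per object, one column per
    (channel, feature). Degenerate objects get missing values, not errors."""
    rows = []
    for oid in labelmatrix.object_ids:
        mask = labelmatrix.mask(int(oid))
        edge = inner_boundary(labelmatrix.pixels, int(oid))
        row: dict[str, object] = {
            "plate": image.plate,
            "well": image.well,
            "site": image.site,
            "object_id": int(oid),
        }
        for cname, img in channels.items():
            if "intensity" in kinds:
                for k, v in intensity_features(img, mask, edge).as_dict().items():
                    row[f"{cname}_{k}"] = v
            if "haralick" in kinds:
                feats = haralick_features(
                    img, mask, levels=haralick_levels,
                    distance=haralick_distance, strict=False,
                )
                for k, v in feats.items():
                    row[f"{cname}_{k}"] = v
            if "gabor" in kinds:
                gx, gy = gabor_features(
                    img, mask, frequency=gabor_frequency, sigma=gabor_sigma
                )
                row[f"{cname}_gabor_x"] = gx
                row[f"{cname}_gabor_y"] = gy
            if "bright_region" in kinds:
                for method in bright_methods:
                    br = bright_region_features(
                        img, mask, method=method, fraction=bright_fraction
                    )
                    for k, v in br.as_dict().items():
                        row[f"{cname}_{k}"] = v
        rows.append(row)
    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["plate", "well", "site", "object_id"]
    )
    return ObjectTable(df, labelmatrix.object_type)
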