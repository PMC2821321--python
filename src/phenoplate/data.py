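"""Plate geometry, object tables, label matrices, manifests, ARFF export and
model persistence.

The central conventions, shared by every other module:

* pixel arrays are row-major and 0-based; object ids are 1-based, 0 marks
  background (label-matrix convention);
* measurement tables are plain CSV with key columns
  ``plate, well, site, object_id`` followed by one numeric column per feature;
* a trained classifier is persisted as a self-describing JSON document (no
  binary pickles) containing everything needed to reproduce its decision
  function exactly: support vectors, dual coefficients, intercepts, per-feature
  scaling and the class/feature name lists.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "PlateLayout",
    "WellAddress",
    "ImageKey",
    "ObjectRef",
    "ImageRecord",
    "LabelMatrix",
    "ObjectTable",
    "RelationTable",
    "NeighborGraph",
    "Model",
    "FormatError",
    "AddressError",
    "ModelIOError",
    "parse_well_name",
    "load_object_table",
    "write_object_table",
    "load_label_matrix",
    "save_label_matrix",
    "read_manifest",
    "write_manifest",
    "export_arff",
    "save_model",
    "load_model",
]

KEY_COLUMNS = ["plate", "well", "site", "object_id"]


class FormatError(ValueError):
    """A file violates the documented schema."""


class AddressError(ValueError):
    """A well name does not exist on the given plate layout."""


class ModelIOError(ValueError):
    """A persisted model file is missing, truncated or inconsistent."""


@dataclass(frozen=True)
class PlateLayout:
    """Plate geometry: 96-well (8x12), 384-well (16x24) or any positive pair."""

    nrows: int = 8
    ncols: int = 12

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("plate layout dimensions must be positive")
        if self.nrows > 26:
            raise ValueError("row letters beyond 'Z' are not supported")

    @property
    def n_wells(self) -> int:
        return self.nrows * self.ncols

    def wells(self) -> list["WellAddress"]:
        """All wells in row-major (A01, A02, ...) order."""
        return [
            WellAddress(r, c, layout=self)
            for r in range(self.nrows)
            for c in range(self.ncols)
        ]


PLATE_96 = PlateLayout(8, 12)
PLATE_384 = PlateLayout(16, 24)


@dataclass(frozen=True)
class WellAddress:
    """0-based (row, col) plate coordinate with a canonical name like ``B02``."""

    row: int
    col: int
    layout: PlateLayout = PLATE_96

    def __post_init__(self) -> None:
        if not (0 <= self.row < self.layout.nrows):
            raise AddressError(f"row {self.row} outside layout {self.layout}")
        if not (0 <= self.col < self.layout.ncols):
            raise AddressError(f"col {self.col} outside layout {self.layout}")

    @property
    def name(self) -> str:
        return f"{string.ascii_uppercase[self.row]}{self.col + 1:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


_WELL_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")


def parse_well_name(name: str, layout: PlateLayout = PLATE_96) -> WellAddress:
    """Parse a canonical well name (row letter + column number) into coordinates.

    ``format(parse(x)) == x`` for canonical (zero-padded) names of the layout.
    """
    m = _WELL_RE.match(name.strip())
    if not m:
        raise AddressError(f"malformed well name: {name!r}")
    row = string.ascii_uppercase.index(m.group(1).upper())
    col = int(m.group(2)) - 1
    if col < 0:
        raise AddressError(f"malformed well name: {name!r}")
    return WellAddress(row, col, layout=layout)


class ImageKey(NamedTuple):
    """Identity of one imaged site: (plate id, well name, site index)."""

    plate: str
    well: str
    site: int


class ObjectRef(NamedTuple):
    """Identity of one segmented object."""

    plate: str
    well: str
    site: int
    object_id: int

    @property
    def image(self) -> ImageKey:
        return ImageKey(self.plate, self.well, self.site)


@dataclass
class ImageRecord:
    """One imaged site: channel images, label matrices and the focus flag."""

    key: ImageKey
    channel_paths: dict[str, str] = field(default_factory=dict)
    labelmatrix_paths: dict[str, str] = field(default_factory=dict)
    excluded: bool = False

    def __post_init__(self) -> None:
        if not self.channel_paths:
            raise FormatError(f"image {self.key} has no channels")


@dataclass
class LabelMatrix:
    """Integer image: pixel value k marks membership in object k, 0 background."""

    pixels: np.ndarray
    object_type: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if not np.issubdtype(px.dtype, np.integer):
            raise FormatError(f"label matrix must be integer, got {px.dtype}")
        if px.ndim != 2:
            raise FormatError("label matrix must be 2-D")
        if px.size and px.min() < 0:
            raise FormatError("label matrix contains negative values")
        self.pixels = px

    @property
    def object_ids(self) -> np.ndarray:
        """Sorted ids of the objects present (1-based, gaps allowed)."""
        ids = np.unique(self.pixels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.object_ids.size)

    def mask(self, object_id: int) -> np.ndarray:
        return self.pixels == object_id


class ObjectTable:
    """Per-object measurements: one row per segmented object.

    Wraps a :class:`pandas.DataFrame` with key columns ``plate, well, site,
    object_id`` and one numeric column per feature. ``(image, object_id)``
    pairs are unique; feature values are finite or explicitly missing (NaN).
    """

    def __init__(self, df: pd.DataFrame, object_type: str):
        missing = [c for c in KEY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"object table missing key columns: {missing}")
        df = df.reset_index(drop=True).copy()
        df["site"] = df["site"].astype(int)
        df["object_id"] = df["object_id"].astype(int)
        if (df["object_id"] < 1).any():
            raise FormatError("object ids must be >= 1")
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            first = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
            raise FormatError(f"duplicate object reference: {first}")
        feats = [c for c in df.columns if c not in KEY_COLUMNS]
        for c in feats:
            if not np.issubdtype(df[c].dtype, np.number):
                coerced = pd.to_numeric(df[c], errors="coerce")
                bad = coerced.isna() & df[c].notna()
                if bad.any():
                    row = int(bad.idxmax())
                    raise FormatError(
                        f"non-numeric value in column {c!r}, row {row}: "
                        f"{df.loc[row, c]!r}"
                    )
                df[c] = coerced
            inf = ~np.isfinite(df[c].to_numpy(dtype=float))
            inf &= df[c].notna().to_numpy()
            if inf.any():
                raise FormatError(f"non-finite value in column {c!r}")
        self.df = df
        self.object_type = object_type
        self.feature_names: list[str] = feats

    def __len__(self) -> int:
        return len(self.df)

    def refs(self) -> list[ObjectRef]:
        return [
            ObjectRef(p, w, int(s), int(o))
            for p, w, s, o in self.df[KEY_COLUMNS].itertuples(index=False)
        ]

    def image_keys(self) -> list[ImageKey]:
        """Distinct images, in first-appearance order."""
        seen: dict[ImageKey, None] = {}
        for r in self.refs():
            seen.setdefault(r.image, None)
        return list(seen)

    def feature_matrix(self, feature_names: Sequence[str] | None = None) -> np.ndarray:
        names = list(feature_names) if feature_names is not None else self.feature_names
        unknown = [n for n in names if n not in self.df.columns]
        if unknown:
            raise KeyError(f"unknown features: {unknown}")
        return self.df[names].to_numpy(dtype=float)

    def subset(self, refs: Iterable[ObjectRef]) -> "ObjectTable":
        wanted = set(refs)
        keep = [i for i, r in enumerate(self.refs()) if r in wanted]
        return ObjectTable(self.df.iloc[keep], self.object_type)

    def rows_for_image(self, image: ImageKey) -> pd.DataFrame:
        df = self.df
        sel = (
            (df["plate"] == image.plate)
            & (df["well"] == image.well)
            & (df["site"] == image.site)
        )
        return df[sel]


def load_object_table(path: str | Path, object_type: str) -> ObjectTable:
    """Read a measurement CSV (``plate,well,site,object_id,<features...>``)."""
    df = pd.read_csv(path)
    return ObjectTable(df, object_type)


def write_object_table(table: ObjectTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def load_label_matrix(path: str | Path, object_type: str) -> LabelMatrix:
    """Read an integer TIFF/PNG label image; max pixel value = largest id."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        px = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        px = iio.imread(path)
    px = np.asarray(px)
    if not np.issubdtype(px.dtype, np.integer):
        raise FormatError(f"{path}: label matrix pixels must be integers")
    return LabelMatrix(px, object_type)


def save_label_matrix(lm: LabelMatrix, path: str | Path) -> None:
    hi = int(lm.pixels.max()) if lm.pixels.size else 0
    dtype = np.uint16 if hi < 2**16 else np.uint32
    tifffile.imwrite(str(path), lm.pixels.astype(dtype))


# ---------------------------------------------------------------------------
# Manifest: plate/well/site -> image and label-matrix paths

def read_manifest(path: str | Path) -> list[ImageRecord]:
    """Read a manifest CSV mapping each imaged site to its files.

    Columns: ``plate, well, site``, any number of ``channel:<name>`` and
    ``labels:<object type>`` path columns, and an optional ``excluded`` flag.
    """
    df = pd.read_csv(path)
    for c in ("plate", "well", "site"):
        if c not in df.columns:
            raise FormatError(f"manifest missing column {c!r}")
    records = []
    for _, row in df.iterrows():
        channels = {
            c.split(":", 1)[1]: row[c]
            for c in df.columns
            if c.startswith("channel:") and isinstance(row[c], str)
        }
        labels = {
            c.split(":", 1)[1]: row[c]
            for c in df.columns
            if c.startswith("labels:") and isinstance(row[c], str)
        }
        excluded = bool(row["excluded"]) if "excluded" in df.columns else False
        records.append(
            ImageRecord(
                key=ImageKey(str(row["plate"]), str(row["well"]), int(row["site"])),
                channel_paths=channels,
                labelmatrix_paths=labels,
                excluded=excluded,
            )
        )
    return records


def write_manifest(records: Sequence[ImageRecord], path: str | Path) -> None:
    channel_names = sorted({n for r in records for n in r.channel_paths})
    label_names = sorted({n for r in records for n in r.labelmatrix_paths})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "plate": r.key.plate,
            "well": r.key.well,
            "site": r.key.site,
        }
        for n in channel_names:
            row[f"channel:{n}"] = r.channel_paths.get(n, "")
        for n in label_names:
            row[f"labels:{n}"] = r.labelmatrix_paths.get(n, "")
        row["excluded"] = int(r.excluded)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inter-object structures

@dataclass
class RelationTable:
    """Parent/child assignment within one image (e.g. spots docked on cells).

    Each child id appears in at most one pair. ``child_counts`` covers every
    parent id present in the parent label matrix, including zeros.
    """

    parent_type: str
    child_type: str
    pairs: list[tuple[int, int]]  # (parent_id, child_id)
    child_counts: dict[int, int]

    def __post_init__(self) -> None:
        children = [c for _, c in self.pairs]
        if len(children) != len(set(children)):
            raise ValueError("a child object is assigned to more than one parent")

    def count(self, parent_id: int) -> int:
        return self.child_counts.get(parent_id, 0)


@dataclass
class NeighborGraph:
    """Symmetric adjacency between objects of one type within one image."""

    object_type: str
    edges: set[tuple[int, int]]  # stored with a < b

    def __post_init__(self) -> None:
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-edges are not allowed")
            norm.add((min(a, b), max(a, b)))
        self.edges = norm

    def neighbors_of(self, object_id: int) -> set[int]:
        out = set()
        for a, b in self.edges:
            if a == object_id:
                out.add(b)
            elif b == object_id:
                out.add(a)
        return out


# ---------------------------------------------------------------------------
# Trained classifier state

@dataclass
class Model:
    """A trained one-vs-one RBF-kernel SVM plus its data scaling.

    Contains the support vectors (in scaled feature space), the dual
    coefficients and intercepts of all k(k-1)/2 pairwise decision functions,
    the per-feature (min, max) scaling measured on the training data, and the
    class/feature name lists — everything needed to reproduce predictions.
    """

    class_names: list[str]
    feature_names: list[str]
    scaling: dict[str, tuple[float, float]]
    support_vectors: np.ndarray  # (n_sv, n_features), scaled space
    n_support: list[int]  # per class, in class_names order
    dual_coef: np.ndarray  # (k-1, n_sv)
    intercepts: np.ndarray  # (k(k-1)/2,)
    C: float
    gamma: float
    class_weights: dict[str, float]

    def __post_init__(self) -> None:
        k = len(self.class_names)
        if k < 2:
            raise ValueError("a model needs at least 2 classes")
        if len(self.intercepts) != k * (k - 1) // 2:
            raise ValueError("intercept count does not match k(k-1)/2")
        if set(self.scaling) != set(self.feature_names):
            raise ValueError("scaling must have one entry per feature")
        if sum(self.n_support) != self.support_vectors.shape[0]:
            raise ValueError("n_support inconsistent with support vectors")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def class_pairs(self) -> list[tuple[str, str]]:
        """The k(k-1)/2 pairs, in libsvm order; the decision value of a pair
        is positive when it favors the first class of the pair."""
        k = self.n_classes
        return [
            (self.class_names[i], self.class_names[j])
            for i in range(k)
            for j in range(i + 1, k)
        ]

    @property
    def n_pairs(self) -> int:
        return len(self.intercepts)


_MODEL_FORMAT = "phenoplate-svm-model/1"


def save_model(model: Model, path: str | Path) -> None:
    """Persist a model as self-describing JSON (exact decision function)."""
    doc = {
        "format": _MODEL_FORMAT,
        "class_names": model.class_names,
        "feature_names": model.feature_names,
        "scaling": {k: [float(a), float(b)] for k, (a, b) in model.scaling.items()},
        "support_vectors": model.support_vectors.tolist(),
        "n_support": [int(n) for n in model.n_support],
        "dual_coef": model.dual_coef.tolist(),
        "intercepts": np.asarray(model.intercepts).tolist(),
        "C": float(model.C),
        "gamma": float(model.gamma),
        "class_weights": {k: float(v) for k, v in model.class_weights.items()},
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> Model:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != _MODEL_FORMAT:
        raise ModelIOError(f"{path} is not a phenoplate model file")
    try:
        return Model(
            class_names=list(doc["class_names"]),
            feature_names=list(doc["feature_names"]),
            scaling={k: (float(v[0]), float(v[1])) for k, v in doc["scaling"].items()},
            support_vectors=np.asarray(doc["support_vectors"], dtype=float),
            n_support=[int(n) for n in doc["n_support"]],
            dual_coef=np.asarray(doc["dual_coef"], dtype=float),
            intercepts=np.asarray(doc["intercepts"], dtype=float),
            C=float(doc["C"]),
            gamma=float(doc["gamma"]),
            class_weights={k: float(v) for k, v in doc["class_weights"].items()},
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelIOError(f"corrupt model file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# ARFF export (WEKA dialect)

def export_arff(
    table: ObjectTable,
    labels: Mapping[ObjectRef, str],
    path: str | Path,
    relation: str = "phenoplate_objects",
    class_names: Sequence[str] | None = None,
) -> None:
    """Write labeled objects as a WEKA ``.arff`` file.

    Numeric attributes appear in the table's feature order; the nominal class
    attribute comes last and lists every class name. Only labeled objects are
    written.
    """
    if not labels:
        raise ValueError("no labeled objects to export")
    refs = table.refs()
    ref_set = set(refs)
    for r in labels:
        if r not in ref_set:
            raise KeyError(f"labeled object {r} not present in table")
    if class_names is None:
        class_names = sorted(set(labels.values()))
    lines = [f"@relation {relation}", ""]
    for feat in table.feature_names:
        lines.append(f"@attribute {feat} numeric")
    lines.append("@attribute class {" + ",".join(class_names) + "}")
    lines.append("")
    lines.append("@data")
    X = table.feature_matrix()
    for i, r in enumerate(refs):
        if r not in labels:
            continue
        vals = ["?" if np.isnan(v) else repr(float(v)) for v in X[i]]
        vals.append(labels[r])
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")
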