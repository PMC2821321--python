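"""Binary vector algebra over object populations and the image/well/plate
variable system.

A *vector* is a per-image binary array over the objects of one parent type:
classification results (``class_equals``), measurement thresholds
(``attribute_cmp``), parent/child counts (``child_count_cmp``) and
neighborhood membership (``neighbor_in``) all reduce to vectors, and vectors
combine under AND/OR/NOT. Any subpopulation — "infected mitotic cells",
"non-infected neighbors of mitotic cells" — is therefore one logical
expression away.

Summaries stack on top: *image variables* (counts and percentages per image),
*well variables* (summaries of image variables over a well's non-excluded
images, with optional arithmetic such as ratio normalization) and *plate
variables* (summaries over user-chosen wells, e.g. the mean of standard wells
used for per-well log2 normalization).
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import ImageKey, ImageRecord, NeighborGraph, ObjectRef, ObjectTable, RelationTable

__all__ = [
    "VectorValue",
    "VectorDef",
    "ClassEquals",
    "AttributeCmp",
    "ChildCountCmp",
    "NeighborIn",
    "Logic",
    "VectorRegistry",
    "EvalContext",
    "eval_vector",
    "vector_logic",
    "ImageVarDef",
    "WellVarDef",
    "PlateVarDef",
    "eval_image_var",
    "eval_well_var",
    "eval_plate_var",
    "eval_well_series",
]

_CMP = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
    "=": operator.eq,
    "==": operator.eq,
}


@dataclass
class VectorValue:
    """One evaluated vector: binary flags over the parent objects of an image,
    aligned with the sorted object ids."""

    image: ImageKey
    parent_type: str
    ids: np.ndarray  # sorted object ids
    flags: np.ndarray  # uint8 {0,1}, same length

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.flags = np.asarray(self.flags).astype(np.uint8)
        if self.ids.shape != self.flags.shape:
            raise ValueError("ids and flags must have equal length")
        if self.flags.size and not np.isin(self.flags, (0, 1)).all():
            raise ValueError("vector flags must be 0 or 1")

    @property
    def count(self) -> int:
        return int(self.flags.sum())

    def __len__(self) -> int:
        return len(self.flags)


# --- vector definitions -----------------------------------------------------

@dataclass(frozen=True)
class VectorDef:
    name: str
    parent_type: str


@dataclass(frozen=True)
class ClassEquals(VectorDef):
    """Flag objects whose class equals ``class_name``. A human session label
    overrides the model prediction where both exist."""

    class_name: str = ""


@dataclass(frozen=True)
class AttributeCmp(VectorDef):
    """Flag objects whose feature compares true against a threshold."""

    feature: str = ""
    op: str = ">="
    threshold: float = 0.0


@dataclass(frozen=True)
class ChildCountCmp(VectorDef):
    """Flag parent objects by their number of related children (e.g. cells
    with >= 1 docked spot are the infected cells)."""

    child_type: str = ""
    op: str = ">="
    threshold: int = 1


@dataclass(frozen=True)
class NeighborIn(VectorDef):
    """Flag objects with at least one neighbor whose flag in the operand
    vector is 1."""

    operand: str = ""


@dataclass(frozen=True)
class Logic(VectorDef):
    """Element-wise AND/OR/NOT of previously defined vectors."""

    op: str = "AND"
    operands: tuple[str, ...] = ()


class VectorRegistry:
    """Named vector definitions; rejects unknown references, parent-type
    mismatches and cyclic definitions at registration time."""

    def __init__(self) -> None:
        self._defs: dict[str, VectorDef] = {}

    def add(self, vdef: VectorDef) -> VectorDef:
        if vdef.name in self._defs:
            raise ValueError(f"vector {vdef.name!r} already defined")
        for op_name in self._operands(vdef):
            if op_name not in self._defs:
                raise ValueError(
                    f"vector {vdef.name!r} references undefined vector {op_name!r}"
                )
            if self._defs[op_name].parent_type != vdef.parent_type:
                raise ValueError(
                    f"vector {vdef.name!r} mixes parent types with {op_name!r}"
                )
        # definitions may only reference earlier names, so cycles cannot form
        self._defs[vdef.name] = vdef
        return vdef

    @staticmethod
    def _operands(vdef: VectorDef) -> tuple[str, ...]:
        if isinstance(vdef, Logic):
            return vdef.operands
        if isinstance(vdef, NeighborIn):
            return (vdef.operand,)
        return ()

    def __getitem__(self, name: str) -> VectorDef:
        return self._defs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def names(self) -> list[str]:
        return list(self._defs)


# --- evaluation context -----------------------------------------------------

@dataclass
class EvalContext:
    """Everything vector/variable evaluation may reference for a dataset."""

    tables: dict[str, ObjectTable] = field(default_factory=dict)
    predictions: dict[str, dict[ObjectRef, str]] = field(default_factory=dict)
    session_labels: dict[str, dict[ObjectRef, str]] = field(default_factory=dict)
    relations: dict[tuple[str, str], dict[ImageKey, RelationTable]] = field(
        default_factory=dict
    )
    neighbor_graphs: dict[tuple[str, ImageKey], NeighborGraph] = field(
        default_factory=dict
    )
    images: list[ImageRecord] = field(default_factory=list)
    image_measurements: dict[str, dict[ImageKey, float]] = field(default_factory=dict)
    vectors: VectorRegistry = field(default_factory=VectorRegistry)

    def object_ids(self, parent_type: str, image: ImageKey) -> np.ndarray:
        df = self.tables[parent_type].rows_for_image(image)
        return np.sort(df["object_id"].to_numpy(dtype=int))

    def class_of(self, parent_type: str, ref: ObjectRef) -> str | None:
        human = self.session_labels.get(parent_type, {})
        if ref in human:
            return human[ref]
        return self.predictions.get(parent_type, {}).get(ref)

    def non_excluded_images(self) -> list[ImageRecord]:
        return [r for r in self.images if not r.excluded]

    def images_of_well(self, plate: str, well: str, include_excluded: bool = False):
        return [
            r
            for r in self.images
            if r.key.plate == plate
            and r.key.well == well
            and (include_excluded or not r.excluded)
        ]


# --- vector evaluation ------------------------------------------------------

def vector_logic(op: str, *operands: VectorValue) -> VectorValue:
    """Element-wise AND / OR / NOT over vectors of one image and parent type."""
    if not operands:
        raise ValueError("logic needs at least one operand")
    first = operands[0]
    for v in operands[1:]:
        if v.image != first.image or v.parent_type != first.parent_type:
            raise ValueError("logic operands must share image and parent type")
        if len(v) != len(first):
            raise ValueError("logic operands differ in length")
    op = op.upper()
    if op == "NOT":
        if len(operands) != 1:
            raise ValueError("NOT takes exactly one operand")
        flags = 1 - first.flags
    elif op == "AND":
        flags = np.bitwise_and.reduce([v.flags for v in operands])
    elif op == "OR":
        flags = np.bitwise_or.reduce([v.flags for v in operands])
    else:
        raise ValueError(f"unknown logical operation {op!r}")
    return VectorValue(first.image, first.parent_type, first.ids.copy(), flags)


def eval_vector(vdef: VectorDef | str, image: ImageKey, ctx: EvalContext) -> VectorValue:
    """Evaluate a vector definition for one image."""
    if isinstance(vdef, str):
        if vdef not in ctx.vectors:
            raise KeyError(f"undefined vector {vdef!r}")
        vdef = ctx.vectors[vdef]
    ids = ctx.object_ids(vdef.parent_type, image)
    refs = [ObjectRef(image.plate, image.well, image.site, int(i)) for i in ids]

    if isinstance(vdef, ClassEquals):
        flags = np.array(
            [1 if ctx.class_of(vdef.parent_type, r) == vdef.class_name else 0 for r in refs]
        )
    elif isinstance(vdef, AttributeCmp):
        df = ctx.tables[vdef.parent_type].rows_for_image(image)
        df = df.sort_values("object_id")
        vals = df[vdef.feature].to_numpy(dtype=float)
        cmp = _CMP[vdef.op]
        flags = np.array(
            [0 if np.isnan(v) else int(cmp(v, vdef.threshold)) for v in vals]
        )
    elif isinstance(vdef, ChildCountCmp):
        key = (vdef.parent_type, vdef.child_type)
        if key not in ctx.relations or image not in ctx.relations[key]:
            raise KeyError(f"no relation {key} for image {image}")
        rel = ctx.relations[key][image]
        cmp = _CMP[vdef.op]
        flags = np.array([int(cmp(rel.count(int(i)), vdef.threshold)) for i in ids])
    elif isinstance(vdef, NeighborIn):
        base = eval_vector(vdef.operand, image, ctx)
        gkey = (vdef.parent_type, image)
        if gkey not in ctx.neighbor_graphs:
            raise KeyError(f"no neighbor graph for {gkey}")
        graph = ctx.neighbor_graphs[gkey]
        flagged = {int(i) for i, f in zip(base.ids, base.flags) if f}
        flags = np.array(
            [int(bool(graph.neighbors_of(int(i)) & flagged)) for i in ids]
        )
    elif isinstance(vdef, Logic):
        vals = [eval_vector(name, image, ctx) for name in vdef.operands]
        return vector_logic(vdef.op, *vals)
    else:
        raise TypeError(f"unknown vector definition {type(vdef).__name__}")
    if flags.size == 0:
        flags = np.zeros(0, dtype=np.uint8)
    return VectorValue(image, vdef.parent_type, ids, flags)


# --- image / well / plate variables ----------------------------------------

@dataclass(frozen=True)
class ImageVarDef:
    """One number per image.

    ``source`` is a vector name (summarizer ``count`` or ``percent_of``) or a
    named direct per-image measurement (summarizer ``value``). ``percent_of``
    reports ``100 * count(source) / count(reference)`` and is missing (NaN)
    when the reference count is 0.
    """

    name: str
    source: str
    summarizer: str = "count"  # count | percent_of | value
    reference: str | None = None  # vector name for percent_of


@dataclass(frozen=True)
class WellVarDef:
    """Summary of an image variable over a well's non-excluded images
    (``sum`` or ``mean``), optionally followed by a calculation over
    previously defined well/plate variables (nested prefix expressions with
    +, -, *, /, log2; names refer to variables, numbers are literals)."""

    name: str
    image_var: str | None = None
    image_summarizer: str = "sum"  # sum | mean
    calculation: tuple | None = None


@dataclass(frozen=True)
class PlateVarDef:
    """Summary of a well variable over user-chosen wells (e.g. the standard
    wells used for normalization)."""

    name: str
    well_var: str
    wells: tuple[str, ...] = ()
    summarizer: str = "mean"  # mean | sum | median


def eval_image_var(
    vdef: ImageVarDef, image: ImageKey, ctx: EvalContext
) -> float:
    if vdef.summarizer == "value":
        series = ctx.image_measurements.get(vdef.source)
        if series is None:
            raise KeyError(f"unknown image measurement {vdef.source!r}")
        return float(series.get(image, float("nan")))
    vec = eval_vector(vdef.source, image, ctx)
    if vdef.summarizer == "count":
        return float(vec.count)
    if vdef.summarizer == "percent_of":
        if vdef.reference is None:
            raise ValueError(f"{vdef.name}: percent_of needs a reference vector")
        ref = eval_vector(vdef.reference, image, ctx)
        if ref.count == 0:
            return float("nan")
        return 100.0 * vec.count / ref.count
    raise ValueError(f"unknown image summarizer {vdef.summarizer!r}")


def _eval_calc(
    expr, values: Mapping[str, float]
) -> float:
    """Evaluate a small prefix-expression tree over named variables."""
    if isinstance(expr, (int, float)):
        return float(expr)
    if isinstance(expr, str):
        if expr not in values:
            raise KeyError(f"calculation references undefined variable {expr!r}")
        return float(values[expr])
    op, *args = expr
    vals = [_eval_calc(a, values) for a in args]
    if any(math.isnan(v) for v in vals):
        return float("nan")  # missing propagates as missing, never as 0
    if op == "+":
        return vals[0] + vals[1]
    if op == "-":
        return vals[0] - vals[1]
    if op == "*":
        return vals[0] * vals[1]
    if op == "/":
        return vals[0] / vals[1] if vals[1] != 0 else float("nan")
    if op == "log2":
        return math.log2(vals[0]) if vals[0] > 0 else float("nan")
    raise ValueError(f"unknown calculation operator {op!r}")


def eval_well_var(
    vdef: WellVarDef,
    plate: str,
    well: str,
    ctx: EvalContext,
    image_vars: Mapping[str, ImageVarDef] = (),
    prior: Mapping[str, float] | None = None,
) -> float:
    """Evaluate a well variable: summarize the image variable over the well's
    non-excluded images, then apply the optional calculation. A well whose
    images are all excluded yields a missing value."""
    values = dict(prior or {})
    if vdef.image_var is not None:
        records = ctx.images_of_well(plate, well)
        if not records:
            base = float("nan")
        else:
            iv = image_vars[vdef.image_var]
            per_image = [eval_image_var(iv, r.key, ctx) for r in records]
            if vdef.image_summarizer == "sum":
                base = float(np.nansum(per_image)) if not all(
                    math.isnan(v) for v in per_image
                ) else float("nan")
            elif vdef.image_summarizer == "mean":
                base = float(np.nanmean(per_image)) if not all(
                    math.isnan(v) for v in per_image
                ) else float("nan")
            else:
                raise ValueError(f"unknown image summarizer {vdef.image_summarizer!r}")
        values[vdef.name] = base
    if vdef.calculation is None:
        return values.get(vdef.name, float("nan"))
    return _eval_calc(vdef.calculation, values)


def eval_well_series(
    defs: Sequence[WellVarDef],
    wells: Sequence[tuple[str, str]],
    ctx: EvalContext,
    image_vars: Mapping[str, ImageVarDef],
    plate_vars: Sequence[PlateVarDef] = (),
) -> dict[str, dict[tuple[str, str], float]]:
    """Evaluate several well variables over many wells, resolving plate
    variables so calculations can normalize against them (plate values
    broadcast to every well). Definitions are processed in order; each may
    reference the values of the ones before it."""
    out: dict[str, dict[tuple[str, str], float]] = {d.name: {} for d in defs}
    # first pass: plain (calculation-free) well variables
    plain = [d for d in defs if d.calculation is None]
    for d in plain:
        for plate, well in wells:
            out[d.name][(plate, well)] = eval_well_var(d, plate, well, ctx, image_vars)
    # plate variables over the plain well values
    plate_values: dict[str, float] = {}
    for pv in plate_vars:
        plate_values[pv.name] = eval_plate_var(pv, ctx, well_values=out[pv.well_var])
    # second pass: calculated well variables see earlier wells + plate values
    for d in defs:
        if d.calculation is None:
            continue
        for plate, well in wells:
            prior = {name: series.get((plate, well), float("nan"))
                     for name, series in out.items()}
            prior.update(plate_values)
            base = eval_well_var(d, plate, well, ctx, image_vars, prior=prior)
            out[d.name][(plate, well)] = base
    return out


def eval_plate_var(
    vdef: PlateVarDef,
    ctx: EvalContext,
    well_values: Mapping[tuple[str, str], float] | None = None,
    image_vars: Mapping[str, ImageVarDef] = (),
    well_defs: Mapping[str, WellVarDef] = (),
) -> float:
    """Summarize a well variable over the selected wells (any plate)."""
    if not vdef.wells:
        raise ValueError(f"plate variable {vdef.name!r} selects no wells")
    if well_values is None:
        wd = well_defs[vdef.well_var]
        plates = sorted({r.key.plate for r in ctx.images})
        well_values = {
            (p, w): eval_well_var(wd, p, w, ctx, image_vars)
            for p in plates
            for w in vdef.wells
        }
    vals = [
        v
        for (p, w), v in well_values.items()
        if w in vdef.wells and not math.isnan(v)
    ]
    if not vals:
        return float("nan")
    if vdef.summarizer == "mean":
        return float(np.mean(vals))
    if vdef.summarizer == "sum":
        return float(np.sum(vals))
    if vdef.summarizer == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown plate summarizer {vdef.summarizer!r}")
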