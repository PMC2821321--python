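"""Out-of-focus image detection.

Each image is embedded as a 2-D point (number of objects, granularity
scalar): sharp images with many objects sit high on both axes, blurred or
sparse images drop. The user labels a handful of images in/out of focus and a
separating line is fitted (a 2-D linear soft-margin classifier with balanced
class weights on z-scored coordinates); a manual line can be supplied
instead. Images on the out-of-focus side get the ``excluded`` flag — a
reversible marker honored by training candidate selection and by well/plate
summaries, never a deletion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .data import ImageKey, ImageRecord

__all__ = [
    "FocusTrainingPoint",
    "FocusLine",
    "fit_focus_line",
    "classify_focus",
    "apply_focus_line",
]

IN_FOCUS = "in_focus"
OUT_OF_FOCUS = "out_of_focus"


@dataclass(frozen=True)
class FocusTrainingPoint:
    image: ImageKey
    n_objects: int
    granularity: float
    label: str  # in_focus | out_of_focus


@dataclass(frozen=True)
class FocusLine:
    """Separating line w1*n_objects + w2*granularity + b; the positive side
    (>= 0, boundary included) is in focus."""

    w1: float
    w2: float
    b: float

    def __post_init__(self) -> None:
        if self.w1 == 0 and self.w2 == 0:
            raise ValueError("degenerate focus line: zero weights")

    def score(self, n_objects: float, granularity: float) -> float:
        return self.w1 * n_objects + self.w2 * granularity + self.b

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"w1": self.w1, "w2": self.w2, "b": self.b}))

    @classmethod
    def load(cls, path: str | Path) -> "FocusLine":
        d = json.loads(Path(path).read_text())
        return cls(float(d["w1"]), float(d["w2"]), float(d["b"]))


def fit_focus_line(points: Sequence[FocusTrainingPoint]) -> FocusLine:
    """Fit the separating line from user-labeled images.

    A linear soft-margin SVM with balanced class weights is trained on
    z-scored (n_objects, granularity) coordinates and the resulting
    hyperplane is expressed back in the original units, oriented so the
    in-focus side is positive. Requires at least one point of each label.
    """
    labels = {p.label for p in points}
    if labels - {IN_FOCUS, OUT_OF_FOCUS}:
        raise ValueError(f"unknown focus labels: {labels - {IN_FOCUS, OUT_OF_FOCUS}}")
    if len(labels) < 2:
        raise ValueError("need training points of both focus labels")
    X = np.array([[p.n_objects, p.granularity] for p in points], dtype=float)
    y = np.array([1 if p.label == IN_FOCUS else -1 for p in points])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    svc = SVC(kernel="linear", C=1.0, class_weight="balanced").fit(Z, y)
    wz = svc.coef_[0]
    bz = float(svc.intercept_[0])
    # undo the standardization: w.(x-mu)/sd + b
    w = wz / sd
    b = bz - float((wz * mu / sd).sum())
    # sklearn's positive side is the +1 (in_focus) class already; keep sign
    return FocusLine(float(w[0]), float(w[1]), float(b))


def classify_focus(line: FocusLine, n_objects: float, granularity: float) -> str:
    """Deterministic sign rule; a point exactly on the line counts as in
    focus (keep data unless clearly bad)."""
    return IN_FOCUS if line.score(n_objects, granularity) >= 0 else OUT_OF_FOCUS


def apply_focus_line(
    line: FocusLine,
    records: Sequence[ImageRecord],
    coords: dict[ImageKey, tuple[float, float]],
) -> list[ImageKey]:
    """Set the ``excluded`` flag on every record classified out of focus.

    ``coords`` maps each image to its (n_objects, granularity) point.
    Returns the keys of the newly excluded images.
    """
    excluded = []
    for r in records:
        if r.key not in coords:
            continue
        n_obj, gran = coords[r.key]
        r.excluded = classify_focus(line, n_obj, gran) == OUT_OF_FOCUS
        if r.excluded:
            excluded.append(r.key)
    return excluded
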