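"""Label collection and active-learning candidate selection.

Four ways of picking objects to label, mirroring how a screener actually
trains a phenotype classifier:

* *default* — label any object directly (:meth:`TrainingSession.label`);
* *random* — a forced-choice draw: pick an image uniformly among the
  non-excluded images, then one object uniformly within it, avoiding any
  selection bias;
* *correction* — show the current model's predictions for a whole image and
  memorize only the objects the user corrects;
* *decision boundaries* — present the unlabeled objects whose predictions sit
  closest to the current decision boundaries, the most informative ones to
  label next.

A plate-wide *panel* combines both ideas: 8 near-boundary objects spread over
distinct images plus the most confidently positive and negative exemplars.
Sessions can be merged (current + up to 10 previous) into train/validation
splits, and candidates can be presented blinded (no filename) or informed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ImageKey, Model, ObjectRef, ObjectTable
from .svm import boundary_score, decision_values, predict

__all__ = [
    "TrainingSession",
    "Candidate",
    "CandidateSet",
    "pick_random",
    "boundary_candidates",
    "panel_candidates",
    "correction_pass",
    "merge_sessions",
    "present",
    "MAX_MERGED_SESSIONS",
]

MAX_MERGED_SESSIONS = 10


@dataclass
class TrainingSession:
    """Accumulated object labels plus the log of how each was collected.

    One label per object; relabeling overwrites the class but every labeling
    event stays in ``mode_log`` in order.
    """

    labels: dict[ObjectRef, str] = field(default_factory=dict)
    mode_log: list[tuple[ObjectRef, str, int]] = field(default_factory=list)
    blinded: bool = False

    def label(self, ref: ObjectRef, class_name: str, mode: str = "default") -> None:
        self.labels[ref] = class_name
        self.mode_log.append((ref, mode, len(self.mode_log)))

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        last_mode: dict[ObjectRef, str] = {}
        for ref, mode, _ in self.mode_log:
            last_mode[ref] = mode
        rows = [
            {
                "plate": r.plate,
                "well": r.well,
                "site": r.site,
                "object_id": r.object_id,
                "class": c,
                "mode": last_mode.get(r, "default"),
            }
            for r, c in self.labels.items()
        ]
        return pd.DataFrame(
            rows, columns=["plate", "well", "site", "object_id", "class", "mode"]
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "TrainingSession":
        df = pd.read_csv(path)
        s = cls()
        for _, row in df.iterrows():
            ref = ObjectRef(
                str(row["plate"]), str(row["well"]), int(row["site"]), int(row["object_id"])
            )
            s.label(ref, str(row["class"]), mode=str(row["mode"]))
        return s


@dataclass(frozen=True)
class Candidate:
    ref: ObjectRef
    rationale: str  # random | boundary | exemplar_positive | exemplar_negative | correction


@dataclass
class CandidateSet:
    """Ordered, duplicate-free list of objects proposed for labeling."""

    candidates: list[Candidate]

    def __post_init__(self) -> None:
        refs = [c.ref for c in self.candidates]
        if len(refs) != len(set(refs)):
            raise ValueError("duplicate candidates")

    def refs(self) -> list[ObjectRef]:
        return [c.ref for c in self.candidates]

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


def _eligible_refs(
    table: ObjectTable,
    excluded_images: Iterable[ImageKey] = (),
    labeled: Iterable[ObjectRef] = (),
) -> list[ObjectRef]:
    excl = set(excluded_images)
    lab = set(labeled)
    return [r for r in table.refs() if r.image not in excl and r not in lab]


def pick_random(
    table: ObjectTable,
    n: int = 1,
    seed: int = 0,
    excluded_images: Iterable[ImageKey] = (),
    labeled: Iterable[ObjectRef] = (),
) -> CandidateSet:
    """Forced-choice sampling: image uniform among eligible images, then one
    object uniform within the image. Out-of-focus (excluded) images are never
    sampled; already-proposed objects are not repeated within the set."""
    refs = _eligible_refs(table, excluded_images, labeled)
    if not refs:
        raise ValueError("no eligible objects to sample from")
    by_image: dict[ImageKey, list[ObjectRef]] = {}
    for r in refs:
        by_image.setdefault(r.image, []).append(r)
    rng = np.random.default_rng(seed)
    chosen: list[ObjectRef] = []
    chosen_set: set[ObjectRef] = set()
    images = sorted(by_image)
    for _ in range(n):
        pool_images = [k for k in images if any(r not in chosen_set for r in by_image[k])]
        if not pool_images:
            break
        img = pool_images[rng.integers(len(pool_images))]
        pool = [r for r in by_image[img] if r not in chosen_set]
        ref = pool[rng.integers(len(pool))]
        chosen.append(ref)
        chosen_set.add(ref)
    return CandidateSet([Candidate(r, "random") for r in chosen])


def boundary_candidates(
    model: Model,
    table: ObjectTable,
    n: int,
    excluded_images: Iterable[ImageKey] = (),
    labeled: Iterable[ObjectRef] = (),
) -> CandidateSet:
    """The n unlabeled objects closest to the current decision boundaries
    (ascending boundary score; ties by object reference)."""
    refs = _eligible_refs(table, excluded_images, labeled)
    if not refs:
        return CandidateSet([])
    sub = table.subset(refs)
    scores = boundary_score(model, sub.feature_matrix(model.feature_names),
                            model.feature_names)
    order = sorted(zip(scores, sub.refs()), key=lambda t: (t[0], t[1]))
    return CandidateSet([Candidate(r, "boundary") for _, r in order[:n]])


def panel_candidates(
    model: Model,
    table: ObjectTable,
    seed: int = 0,
    excluded_images: Iterable[ImageKey] = (),
    labeled: Iterable[ObjectRef] = (),
) -> CandidateSet:
    """Plate-wide panel of 10 objects from up to 10 distinct images.

    Two exemplars illustrate the positive and negative phenotype (the largest
    and smallest signed decision value of the model's single class pair), and
    8 near-boundary objects fill the panel, at most one per image while at
    least 8 images still have eligible objects. Requires a 2-class model.
    Fewer than 10 eligible objects returns them all.
    """
    if model.n_classes != 2:
        raise ValueError("the panel needs a 2-class (positive/negative) model")
    refs = _eligible_refs(table, excluded_images, labeled)
    if not refs:
        return CandidateSet([])
    sub = table.subset(refs)
    sub_refs = sub.refs()
    X = sub.feature_matrix(model.feature_names)
    signed = decision_values(model, X, model.feature_names).iloc[:, 0].to_numpy()
    scores = boundary_score(model, X, model.feature_names)

    # exemplars first: extreme signed decision values (global argmax/argmin)
    pos_i = int(np.argmax(signed))
    neg_i = int(np.argmin(signed))
    chosen: list[Candidate] = [Candidate(sub_refs[pos_i], "exemplar_positive")]
    if neg_i != pos_i:
        chosen.append(Candidate(sub_refs[neg_i], "exemplar_negative"))
    taken = {c.ref for c in chosen}
    used_images = {c.ref.image for c in chosen}

    order = sorted(zip(scores, sub_refs), key=lambda t: (t[0], t[1]))
    remaining = [r for _, r in order if r not in taken]
    n_images = len({r.image for r in remaining} | used_images)
    spread = n_images >= 8
    boundary_picks: list[ObjectRef] = []
    for r in remaining:
        if len(boundary_picks) == 8:
            break
        if spread and r.image in used_images:
            continue
        boundary_picks.append(r)
        used_images.add(r.image)
    if len(boundary_picks) < 8:  # spread rule exhausted images: fill greedily
        for r in remaining:
            if len(boundary_picks) == 8:
                break
            if r not in boundary_picks:
                boundary_picks.append(r)
    return CandidateSet(
        [Candidate(r, "boundary") for r in boundary_picks] + chosen
    )


def correction_pass(
    model: Model,
    table: ObjectTable,
    image: ImageKey,
    user_labels: Mapping[ObjectRef, str],
    session: TrainingSession,
) -> dict[ObjectRef, str]:
    """Correction mode: predict every object of the image, store only the
    objects whose user label disagrees with the prediction. Returns the
    stored (corrected) labels."""
    df = table.rows_for_image(image)
    if df.empty:
        raise ValueError(f"no objects for image {image}")
    img_refs = {
        ObjectRef(image.plate, image.well, image.site, int(o))
        for o in df["object_id"]
    }
    for r in user_labels:
        if r not in img_refs:
            raise KeyError(f"label for unknown object {r}")
    sub = table.subset(img_refs)
    preds = dict(
        zip(sub.refs(), predict(model, sub.feature_matrix(model.feature_names),
                                model.feature_names))
    )
    stored = {
        r: c for r, c in user_labels.items() if c != preds[r]
    }
    for r, c in stored.items():
        session.label(r, c, mode="correction")
    return stored


def merge_sessions(
    current: TrainingSession,
    previous: Sequence[TrainingSession] = (),
    split: Sequence[str] | None = None,
) -> tuple[dict[ObjectRef, str], dict[ObjectRef, str]]:
    """Combine the current session with up to 10 previous ones.

    ``split[i]`` assigns session i (0 = current, then previous in order) to
    ``"train"``, ``"validate"`` or ``"ignore"``. Conflicting class labels for
    one object across merged sessions are an error, as is an object landing
    in both the train and the validation set.
    """
    if len(previous) > MAX_MERGED_SESSIONS:
        raise ValueError(f"at most {MAX_MERGED_SESSIONS} previous sessions")
    sessions = [current, *previous]
    if split is None:
        split = ["train"] * len(sessions)
    if len(split) != len(sessions):
        raise ValueError("one split assignment per session required")
    out: dict[str, dict[ObjectRef, str]] = {"train": {}, "validate": {}}
    for sess, role in zip(sessions, split):
        if role == "ignore":
            continue
        if role not in out:
            raise ValueError(f"unknown split role {role!r}")
        bucket = out[role]
        for ref, cls in sess.labels.items():
            if ref in bucket and bucket[ref] != cls:
                raise ValueError(
                    f"conflicting labels for {ref}: {bucket[ref]!r} vs {cls!r}"
                )
            bucket[ref] = cls
    overlap = set(out["train"]) & set(out["validate"])
    if overlap:
        raise ValueError(
            f"objects assigned to both train and validation: {sorted(overlap)[:5]}"
        )
    return out["train"], out["validate"]


def present(
    candidate: Candidate,
    filename: str | None = None,
    blinded: bool = False,
    session: TrainingSession | None = None,
) -> dict[str, object]:
    """Presentation record for one candidate: the filename is included only
    in informed (non-blinded) mode."""
    record: dict[str, object] = {
        "ref": candidate.ref,
        "rationale": candidate.rationale,
        "blinded": blinded,
    }
    if not blinded and filename is not None:
        record["filename"] = filename
    if session is not None:
        session.blinded = blinded
    return record
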