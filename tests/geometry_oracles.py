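"""Pixel-level brute-force oracles for the inter-object geometry operations,
shared by the geometry unit tests and the acceptance suite. Each oracle
re-derives the result with explicit loops, independently of the library path
it checks."""

import numpy as np

from phenoplate.data import LabelMatrix


def random_label_matrix(rng, shape=(32, 32), n=4, r=3) -> LabelMatrix:
    px = np.zeros(shape, dtype=np.int32)
    Y, X = np.mgrid[: shape[0], : shape[1]]
    for oid in range(1, n + 1):
        cy, cx = rng.integers(r, shape[0] - r), rng.integers(r, shape[1] - r)
        px[(Y - cy) ** 2 + (X - cx) ** 2 <= r**2] = oid
    return LabelMatrix(px, "obj")


def relate_oracle(parent: LabelMatrix, child: LabelMatrix) -> dict[int, int]:
    """child id -> parent id by max pixel overlap, ties to lower parent."""
    overlap: dict[int, dict[int, int]] = {}
    h, w = parent.pixels.shape
    for i in range(h):
        for j in range(w):
            c, p = int(child.pixels[i, j]), int(parent.pixels[i, j])
            if c > 0 and p > 0:
                overlap.setdefault(c, {}).setdefault(p, 0)
                overlap[c][p] += 1
    return {c: min(ps, key=lambda p: (-ps[p], p)) for c, ps in overlap.items()}


def neighbor_oracle(lm: LabelMatrix, distance: int) -> set[tuple[int, int]]:
    """a,b are neighbors iff some pixel of b, displaced by any 3x3 offset,
    lies within Euclidean `distance` of a pixel of a."""
    pix = {int(o): np.argwhere(lm.pixels == o) for o in lm.object_ids}
    offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    edges = set()
    ids = sorted(pix)
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            a, b = ids[ai], ids[bi]
            found = False
            for qy, qx in pix[b]:
                for oy, ox in offsets:
                    d2 = (pix[a][:, 0] - (qy + oy)) ** 2 + (
                        pix[a][:, 1] - (qx + ox)
                    ) ** 2
                    if (d2 <= distance**2).any():
                        found = True
                        break
                if found:
                    break
            if found:
                edges.add((a, b))
    return edges


def expand_oracle(lm: LabelMatrix, max_distance: float) -> np.ndarray:
    """Nearest-seed assignment with lower-id tie-break, by explicit loops."""
    out = np.zeros_like(lm.pixels)
    seeds = {int(o): np.argwhere(lm.pixels == o) for o in lm.object_ids}
    h, w = lm.pixels.shape
    for i in range(h):
        for j in range(w):
            if lm.pixels[i, j] > 0:
                out[i, j] = lm.pixels[i, j]
                continue
            best_d, best_id = None, 0
            for oid in sorted(seeds):
                d = np.sqrt(
                    ((seeds[oid][:, 0] - i) ** 2 + (seeds[oid][:, 1] - j) ** 2).min()
                )
                if best_d is None or d < best_d - 1e-9:
                    best_d, best_id = d, oid
            if best_d is not None and best_d <= max_distance:
                out[i, j] = best_id
    return out
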