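"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they are checked
against: morphology via explicit min/max over footprint offsets,
component labeling via an explicit flood fill, Pearson via the two-pass
textbook formula.
"""

import numpy as np
from skimage.morphology import disk


def _shifted_extreme(img: np.ndarray, footprint: np.ndarray, op: str) -> np.ndarray:
    """Min/max over in-bounds footprint offsets (out-of-bounds ignored)."""
    r = footprint.shape[0] // 2
    pad_val = 255 if op == "min" else 0
    padded = np.pad(img, r, constant_values=pad_val)
    stack = [
        padded[r + di : r + di + img.shape[0], r + dj : r + dj + img.shape[1]]
        for di in range(-r, r + 1)
        for dj in range(-r, r + 1)
        if footprint[di + r, dj + r]
    ]
    arr = np.stack(stack)
    return arr.min(axis=0) if op == "min" else arr.max(axis=0)


def white_tophat_bruteforce(img: np.ndarray, radius: int) -> np.ndarray:
    fp = disk(radius)
    opened = _shifted_extreme(_shifted_extreme(img, fp, "min"), fp, "max")
    return img.astype(int) - opened.astype(int)


def floodfill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Iterative flood-fill component labeling."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                labels[i, j] = current
                while stack:
                    a, b = stack.pop()
                    for di, dj in nbrs:
                        x, y = a + di, b + dj
                        if 0 <= x < h and 0 <= y < w and mask[x, y] and labels[x, y] == 0:
                            labels[x, y] = current
                            stack.append((x, y))
    return labels


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel by first occurrence in raster order, so two labelings of
    the same partition compare equal."""
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    for idx, v in enumerate(labels.ravel()):
        if v and v not in mapping:
            mapping[v] = len(mapping) + 1
    flat = np.array([mapping.get(v, 0) for v in labels.ravel()])
    return flat.reshape(labels.shape)


def pearson_two_pass(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    am, bm = a.mean(), b.mean()
    num = ((a - am) * (b - bm)).sum()
    den = np.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum())
    return num / den
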