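"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — pure-Python flood fill, O(N*M)
nearest-background search, exhaustive assignment enumeration — and shares
no code with the package paths it validates.
"""

from __future__ import annotations

import math

import numpy as np

_NEIGHBOURS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_fill_components(binary: np.ndarray) -> list[list[tuple[int, int]]]:
    """8-connected components of a 2D binary image via BFS flood fill."""
    binary = np.asarray(binary) > 0
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    nr, nc = binary.shape
    for r0 in range(nr):
        for c0 in range(nc):
            if binary[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr, dc in _NEIGHBOURS8:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nr and 0 <= cc < nc and binary[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                comps.append(comp)
    return comps


def size_filtered_pixels(
    binary: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    d_min_mm: float,
    d_max_mm: float,
) -> set[tuple[int, int]]:
    """Pixels surviving an equivalent-diameter band filter (brute force)."""
    px_area = pixel_spacing_mm[0] * pixel_spacing_mm[1]
    kept: set[tuple[int, int]] = set()
    for comp in flood_fill_components(binary):
        d_eq = 2.0 * math.sqrt(len(comp) * px_area / math.pi)
        if d_min_mm <= d_eq <= d_max_mm:
            kept.update(comp)
    return kept


def brute_force_edt(binary: np.ndarray) -> np.ndarray:
    """Distance from each foreground pixel to the nearest background pixel."""
    binary = np.asarray(binary) > 0
    bg = np.argwhere(~binary)
    out = np.zeros(binary.shape, dtype=float)
    for r, c in np.argwhere(binary):
        d2 = ((bg - (r, c)) ** 2).sum(axis=1)
        out[r, c] = math.sqrt(d2.min()) if len(bg) else math.inf
    return out


def optimal_matching_tp(iou_matrix: np.ndarray, thresh: float) -> int:
    """Maximum-cardinality matching size with edges where IoU > thresh."""
    n_pred, n_gt = iou_matrix.shape
    candidates = [
        [j for j in range(n_gt) if iou_matrix[i, j] > thresh] for i in range(n_pred)
    ]

    def rec(i: int, used: frozenset) -> int:
        if i == n_pred:
            return 0
        best = rec(i + 1, used)
        for j in candidates[i]:
            if j not in used:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())


def nms_oracle(boxes, nms_iou: float):
    """Straightforward reference NMS: repeatedly pick the best remaining box."""
    from cmbscreen.evaluation import iou

    remaining = list(boxes)
    kept = []
    while remaining:
        best = min(
            remaining, key=lambda b: (-b.confidence, b.slice_index, b.cy, b.cx)
        )
        kept.append(best)
        remaining = [b for b in remaining if b is not best and iou(best, b) <= nms_iou]
    return kept
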