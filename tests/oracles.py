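"""Independent brute-force oracles used to validate the fast implementations.

These are deliberately naive (queue-based BFS, nested-loop sweeps) and share
no code with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np

_STEPS_4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
_STEPS_8 = _STEPS_4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def bfs_label(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """Connected-component labeling by breadth-first flooding."""
    steps = _STEPS_8 if connectivity == 8 else _STEPS_4
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    n = 0
    H, W = mask.shape
    for r in range(H):
        for c in range(W):
            if mask[r, c] and labels[r, c] == 0:
                n += 1
                q = deque([(r, c)])
                labels[r, c] = n
                while q:
                    rr, cc = q.popleft()
                    for dr, dc in steps:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < H and 0 <= c2 < W and mask[r2, c2] and labels[r2, c2] == 0:
                            labels[r2, c2] = n
                            q.append((r2, c2))
    return labels, n


def component_signature(mask: np.ndarray, connectivity: int) -> set[frozenset]:
    """Partition of foreground pixels into components, as comparable sets."""
    labels, n = bfs_label(mask, connectivity)
    return {
        frozenset(map(tuple, np.argwhere(labels == lab))) for lab in range(1, n + 1)
    }


def flood_exclude_from_contour(sub: np.ndarray, region: np.ndarray) -> np.ndarray:
    """4-connected flood fill of ``sub`` seeded at the contour of ``region``;
    returns the mask of flooded (contour-connected) sub pixels."""
    sub = np.asarray(sub, dtype=bool)
    region = np.asarray(region, dtype=bool)
    H, W = region.shape
    contour = np.zeros_like(region)
    for r in range(H):
        for c in range(W):
            if region[r, c]:
                for dr, dc in _STEPS_4:
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < H and 0 <= c2 < W) or not region[r2, c2]:
                        contour[r, c] = True
                        break
    visited = np.zeros_like(sub)
    q = deque()
    for r, c in np.argwhere(contour & sub):
        if not visited[r, c]:
            visited[r, c] = True
            q.append((r, c))
    while q:
        rr, cc = q.popleft()
        for dr, dc in _STEPS_4:
            r2, c2 = rr + dr, cc + dc
            if 0 <= r2 < H and 0 <= c2 < W and sub[r2, c2] and not visited[r2, c2]:
                visited[r2, c2] = True
                q.append((r2, c2))
    return visited


def sweep_dmvl_oracle(
    dlgn: np.ndarray, patch: np.ndarray, dm: tuple, vl: tuple
) -> tuple[float, float]:
    """Exhaustive nested-loop offset sweep of lines parallel to the tip
    chord; returns (max patch span, nucleus chord on that line) with the
    same 1-px sampling convention as the implementation."""
    d = np.asarray(dm, dtype=float)
    v = np.asarray(vl, dtype=float)
    u = v - d
    u = u / np.hypot(*u)
    nvec = np.array([-u[1], u[0]])
    H, W = dlgn.shape
    pts = np.argwhere(dlgn).astype(float)
    rel = pts - d
    o_lo = int(np.floor((rel @ nvec).min())) - 1
    o_hi = int(np.ceil((rel @ nvec).max())) + 1
    t_lo = int(np.floor((rel @ u).min())) - 1
    t_hi = int(np.ceil((rel @ u).max())) + 1
    best = (-1.0, -1.0, None)
    for o in range(o_lo, o_hi + 1):
        first_p = last_p = first_n = last_n = None
        for t in range(t_lo, t_hi + 1):
            p = d + o * nvec + t * u
            r, c = int(round(p[0])), int(round(p[1]))
            if not (0 <= r < H and 0 <= c < W):
                continue
            if patch[r, c]:
                if first_p is None:
                    first_p = t
                last_p = t
            if dlgn[r, c]:
                if first_n is None:
                    first_n = t
                last_n = t
        span_p = 0.0 if first_p is None else last_p - first_p + 1.0
        span_n = 0.0 if first_n is None else last_n - first_n + 1.0
        key = (span_p, span_n, -abs(o))
        if best[2] is None or key > (best[0], best[1], best[2]):
            best = (span_p, span_n, -abs(o))
    return best[0], best[1]
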