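"""Centreline extraction: Zhang-Suen thinning, secondary thinning to a
strict <=2-neighbour line, and ordering into an indexed coordinate list.

Zhang-Suen thinning is orientation-unbiased and connectivity-preserving but
leaves a skeleton that is occasionally "too thick" for indexing: staircase
corners where a pixel has a redundant diagonal neighbour, and short spurs
where the thinning initiates at the tube's cut ends.  The secondary pass
removes the redundant corner pixels (a corner pixel is deleted when the two
pixels opposite it in the complementary cardinal directions are set),
conservatively deletes any remaining >2-neighbour pixel whose removal keeps
its punctured 3x3 neighbourhood connected, and finally reduces the skeleton
to its longest geodesic path (double breadth-first search), which prunes
end spurs while preserving the longest path.  The result is a line in which
every pixel has at most two neighbours, so it can be walked end to end and
indexed.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import CentrelineInvariantError

log = logging.getLogger(__name__)

__all__ = [
    "Centreline",
    "zhang_suen_thin",
    "secondary_thin",
    "order_centreline",
    "concentricity_check",
    "neighbour_counts",
]

_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def neighbour_counts(img: np.ndarray) -> np.ndarray:
    """Number of set 8-neighbours at every set pixel (0 elsewhere)."""
    b = (np.asarray(img) != 0).astype(np.uint8)
    kern = np.ones((3, 3), dtype=int)
    kern[1, 1] = 0
    return ndimage.correlate(b.astype(int), kern, mode="constant", cval=0) * b


def _zs_neighbours(b: np.ndarray):
    """P2..P9 (classical clockwise-from-north order) as shifted arrays."""
    pad = np.pad(b, 1, mode="constant")
    h, w = b.shape

    def at(dr, dc):
        return pad[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]

    # N, NE, E, SE, S, SW, W, NW
    return [at(-1, 0), at(-1, 1), at(0, 1), at(1, 1),
            at(1, 0), at(1, -1), at(0, -1), at(-1, -1)]


def zhang_suen_thin(silhouette: np.ndarray) -> np.ndarray:
    """Thin a binary silhouette to a skeleton by Zhang-Suen iteration.

    Two sub-iterations alternate until no pixel changes; the skeleton is a
    subset of the input foreground and each input component stays connected.
    An empty input yields an empty output.
    """
    b = (np.asarray(silhouette) != 0).astype(np.uint8)
    if b.sum() == 0:
        return b
    changed = True
    while changed:
        changed = False
        for sub in (0, 1):
            p = _zs_neighbours(b)
            n, ne, e, se, s, sw, wv, nw = p
            ring = [n, ne, e, se, s, sw, wv, nw]
            bsum = sum(ring)
            # A(P): number of 0->1 transitions in the clockwise ring
            a = sum(((ring[i] == 0) & (ring[(i + 1) % 8] == 1)).astype(np.uint8)
                    for i in range(8))
            if sub == 0:
                cond = (n * e * s == 0) & (e * s * wv == 0)
            else:
                cond = (n * e * wv == 0) & (n * s * wv == 0)
            kill = (b == 1) & (bsum >= 2) & (bsum <= 6) & (a == 1) & cond
            if kill.any():
                b[kill] = 0
                changed = True
    return b


def _punctured_connected(patch: np.ndarray) -> bool:
    """True if the set neighbours in a 3x3 patch (centre excluded) form one
    8-connected component among themselves."""
    p = patch.copy()
    p[1, 1] = 0
    lab, n = ndimage.label(p, structure=np.ones((3, 3), dtype=int))
    return n <= 1


def _corner_rule_pass(b: np.ndarray) -> bool:
    """One sequential pass of the corner rule + conservative completion.

    Deletes any >2-neighbour pixel whose punctured 3x3 neighbourhood stays
    connected after its removal (this subsumes the corner case: a diagonal
    pixel whose two complementary cardinal neighbours are set is always
    redundant).  Most-connected pixels are processed first — they are the
    redundant corner fillers — with row-major order breaking ties, so the
    pass is deterministic.  Returns True if anything was deleted.
    """
    counts = neighbour_counts(b)
    targets = np.argwhere((b == 1) & (counts > 2))
    targets = sorted(map(tuple, targets),
                     key=lambda p: (-int(counts[p]), p[0], p[1]))
    removed = False
    h, w = b.shape
    for r, c in targets:
        if b[r, c] == 0:
            continue
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        patch = np.zeros((3, 3), dtype=np.uint8)
        patch[r0 - r + 1:r1 - r + 1, c0 - c + 1:c1 - c + 1] = b[r0:r1, c0:c1]
        if patch.sum() - 1 <= 2:  # count may be stale after earlier deletions
            continue
        if _punctured_connected(patch):
            b[r, c] = 0
            removed = True
    return removed


def _skeleton_adjacency(pixels: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    pset = set(map(tuple, pixels))
    return {p: [q for q in ((p[0] + dr, p[1] + dc) for dr, dc in _EIGHT) if q in pset]
            for p in pset}


def _bfs_farthest(adj, start):
    """BFS returning (farthest pixel, predecessor map)."""
    prev = {start: None}
    q = deque([start])
    last = start
    while q:
        u = q.popleft()
        last = u
        for v in sorted(adj[u]):
            if v not in prev:
                prev[v] = u
                q.append(v)
    return last, prev


def _longest_path_reduce(b: np.ndarray) -> np.ndarray:
    """Keep only the longest geodesic path of each skeleton (double BFS)."""
    lab, n = ndimage.label(b, structure=np.ones((3, 3), dtype=int))
    out = np.zeros_like(b)
    for k in range(1, n + 1):
        pixels = np.argwhere(lab == k)
        adj = _skeleton_adjacency(pixels)
        start = tuple(pixels[0])
        a, _ = _bfs_farthest(adj, start)
        bpix, prev = _bfs_farthest(adj, a)
        node = bpix
        while node is not None:
            out[node] = 1
            node = prev[node]
    return out


def secondary_thin(skeleton: np.ndarray) -> np.ndarray:
    """Reduce a Zhang-Suen skeleton to a strict <=2-neighbour line.

    Applies the corner rule / conservative completion until stable; if
    genuine junction pixels remain (end spurs), reduces to the longest
    geodesic path and cleans up once more.
    """
    b = (np.asarray(skeleton) != 0).astype(np.uint8)
    if b.sum() == 0:
        return b
    while _corner_rule_pass(b):
        pass
    if (neighbour_counts(b) > 2).any():
        n_before = int(b.sum())
        b = _longest_path_reduce(b)
        log.debug("secondary_thin: pruned %d spur pixel(s) via longest-path reduction",
                  n_before - int(b.sum()))
        while _corner_rule_pass(b):
            pass
    return b


@dataclass
class Centreline:
    """Ordered 1-pixel-wide centreline.

    ``points`` is an (N, 2) int array of (row, col) coordinates indexed
    0..N-1; consecutive points are 8-adjacent and no point repeats.
    """

    points: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def rows(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.points[:, 1]


def order_centreline(skeleton: np.ndarray) -> Centreline:
    """Walk a <=2-neighbour skeleton from endpoint to endpoint.

    If several components remain, the largest is kept (the rest are logged
    and dropped).  Open lines start at the endpoint with the smaller
    row-major coordinate; closed loops start at the smallest row-major
    pixel.  A pixel with three or more neighbours raises
    :class:`CentrelineInvariantError` naming the coordinate.
    """
    b = (np.asarray(skeleton) != 0).astype(np.uint8)
    lab, n = ndimage.label(b, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return Centreline(points=np.empty((0, 2), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(b, lab, index=range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        log.info("order_centreline: keeping largest of %d components (%d px), dropping %d px",
                 n, int(sizes[keep - 1]), int(b.sum() - sizes[keep - 1]))
        b = (lab == keep).astype(np.uint8)
    pixels = np.argwhere(b)
    adj = _skeleton_adjacency(pixels)
    for p, nbrs in adj.items():
        if len(nbrs) > 2:
            raise CentrelineInvariantError(
                f"pixel {p} has {len(nbrs)} neighbours; secondary thinning incomplete")
    endpoints = sorted(p for p, nbrs in adj.items() if len(nbrs) == 1)
    if len(pixels) == 1:
        return Centreline(points=pixels.copy())
    start = endpoints[0] if endpoints else min(adj)
    order = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [q for q in sorted(adj[cur]) if q not in seen]
        if not nxt:
            break
        cur = nxt[0]
        order.append(cur)
        seen.add(cur)
    if len(order) != len(pixels):
        raise CentrelineInvariantError(
            f"walk covered {len(order)} of {len(pixels)} skeleton pixels")
    return Centreline(points=np.array(order, dtype=int))


def concentricity_check(line: Centreline, silhouette: np.ndarray, offset: int = 4) -> np.ndarray:
    """Signed concentricity deviation at every centreline index, in pixels.

    For each index the two opposite normal rays are cast to the silhouette
    contour; the deviation is half the difference of their lengths, so 0
    means the point is exactly mid-way between the walls.  Indices whose
    rays cannot be computed are NaN.  Diagnostic only: the result does not
    feed back into the pipeline.
    """
    from .width_profile import local_gradient, cast_normal_ray

    n = len(line)
    dev = np.full(n, np.nan)
    for i in range(1, n - 1):
        off = min(offset, i, n - 1 - i)
        slope = local_gradient(line, i, offset=off)
        origin = tuple(line.points[i])
        try:
            e1 = cast_normal_ray(silhouette, origin, slope, +1)
            e2 = cast_normal_ray(silhouette, origin, slope, -1)
        except Exception:
            continue
        d1 = float(np.hypot(e1[0] - origin[0], e1[1] - origin[1]))
        d2 = float(np.hypot(e2[0] - origin[0], e2[1] - origin[1]))
        dev[i] = 0.5 * (d1 - d2)
    return dev
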