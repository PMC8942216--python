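"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately slow, pure-Python, and shares no code with
the package: exhaustive even-odd point-in-polygon tests, BFS connected
components, and arg-min/arg-max scans.
"""

from collections import deque


def point_in_polygon_even_odd(px, py, points):
    """Crossing-number test for a single point against a polygon."""
    inside = False
    n = len(points)
    for i in range(n):
        x1, y1 = points[i]
        x2, y2 = points[(i + 1) % n]
        if y1 == y2:
            continue
        if (y1 <= py < y2) or (y2 <= py < y1):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_at:
                inside = not inside
    return inside


def rasterize_polygon_brute_force(points, shape):
    """Even-odd fill evaluated at every pixel centre (r + 0.5, c + 0.5)."""
    H, W = shape
    return [
        [point_in_polygon_even_odd(c + 0.5, r + 0.5, points) for c in range(W)]
        for r in range(H)
    ]


def bfs_components(mask, connectivity=8):
    """Connected components by breadth-first search; returns pixel-set list
    in scan order of each component's first pixel."""
    H = len(mask)
    W = len(mask[0])
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    seen = [[False] * W for _ in range(H)]
    comps = []
    for r in range(H):
        for c in range(W):
            if mask[r][c] and not seen[r][c]:
                comp = []
                q = deque([(r, c)])
                seen[r][c] = True
                while q:
                    rr, cc = q.popleft()
                    comp.append((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < H and 0 <= nc < W and mask[nr][nc] and not seen[nr][nc]:
                            seen[nr][nc] = True
                            q.append((nr, nc))
                comps.append(comp)
    return comps


def largest_component_brute_force(mask, connectivity=8):
    """Pixel set of the largest component (ties: first in scan order)."""
    comps = bfs_components(mask, connectivity)
    if not comps:
        return set()
    best = max(comps, key=len)  # max keeps the first maximal in scan order
    return set(best)


def central_wound_brute_force(mask, min_size, centroid, connectivity=8):
    """Pixel set of the min-centroid-distance component above min_size."""
    comps = [c for c in bfs_components(mask, connectivity) if len(c) > min_size]
    if not comps:
        return set()
    cy, cx = centroid

    def dist2(comp):
        my = sum(r for r, _ in comp) / len(comp)
        mx = sum(c for _, c in comp) / len(comp)
        return (my - cy) ** 2 + (mx - cx) ** 2

    return set(min(comps, key=dist2))
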