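"""Brute-force pixel-graph oracles, written independently of the package
internals: plain Python loops over explicit neighbour lists.

Shared semantics under test (fixed conventions of the skeleton
morphometry): 8-connectivity throughout; endpoints are pixels of degree
<= 1; junctions are pixels of degree >= 3 whose true neighbours fall
into >= 3 separate 8-connected groups (an L-bend corner is a path
pixel); branch walks prefer orthogonal steps over diagonal ones and
lexicographically smaller pixels; geodesic steps weigh 1 / sqrt(2).
"""

import math


def _pixels(mask):
    h, w = len(mask), len(mask[0])
    return [(r, c) for r in range(h) for c in range(w) if mask[r][c]]


def _nb8(mask, p):
    h, w = len(mask), len(mask[0])
    r, c = p
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr][cc]:
                out.append((rr, cc))
    return out


def _adjacent(a, b):
    return max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1


_RING_ORDER = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def _ring_runs(mask, p):
    """Maximal runs of true pixels around the cyclic 8-neighbour ring."""
    h, w = len(mask), len(mask[0])
    r, c = p
    seq = ""
    for dr, dc in _RING_ORDER:
        rr, cc = r + dr, c + dc
        seq += "1" if (0 <= rr < h and 0 <= cc < w and mask[rr][cc]) else "0"
    if "1" not in seq:
        return 0
    runs = sum(1 for i in range(8) if seq[i] == "1" and seq[i - 1] == "0")
    return runs if runs else 1  # all-true ring is one run


def _is_junction(mask, p):
    return len(_nb8(mask, p)) >= 3 and _ring_runs(mask, p) >= 3


def perimeter_oracle(mask):
    """Foreground pixels with a 4-connected background neighbour
    (image border treated as background)."""
    h, w = len(mask), len(mask[0])
    out = set()
    for r, c in _pixels(mask):
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if not (0 <= rr < h and 0 <= cc < w) or not mask[rr][cc]:
                out.add((r, c))
                break
    return out


def node_count_oracle(mask):
    """(branchpoint clusters, endpoints) by explicit classification and
    flood fill over adjacent junction pixels."""
    ep = sum(1 for p in _pixels(mask) if len(_nb8(mask, p)) == 1)
    junctions = [p for p in _pixels(mask) if _is_junction(mask, p)]
    remaining = set(junctions)
    clusters = 0
    while remaining:
        clusters += 1
        stack = [min(remaining)]
        remaining.discard(stack[0])
        while stack:
            q = stack.pop()
            near = [t for t in remaining if _adjacent(t, q)]
            for t in near:
                remaining.discard(t)
            stack.extend(near)
    return clusters, ep


def _step(a, b):
    return math.sqrt(2.0) if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _prefer(cur, cands):
    return sorted(cands, key=lambda q: (_step(cur, q) > 1.0, q))


def branch_signature_oracle(mask):
    """Branch decomposition signatures [(geodesic, euclidean, is_loop)],
    sorted, by a direct re-walk of the node-to-node rules."""
    px = _pixels(mask)
    deg = {p: len(_nb8(mask, p)) for p in px}
    junc = {p for p in px if _is_junction(mask, p)}
    nodes = junc | {p for p in px if deg[p] <= 1}
    visited = set()
    sigs = []

    def emit(path, loop=False):
        geo = sum(_step(a, b) for a, b in zip(path, path[1:]))
        if loop:
            if len(path) >= 3 and _adjacent(path[-1], path[0]):
                geo += _step(path[-1], path[0])
            euc = 0.0
        else:
            euc = math.hypot(path[-1][0] - path[0][0], path[-1][1] - path[0][1])
        sigs.append((round(geo, 6), round(euc, 6), euc == 0.0))

    for n in sorted(nodes):
        if deg[n] == 0:
            emit([n], loop=True)
            continue
        for first in _prefer(n, [q for q in _nb8(mask, n) if q not in nodes]):
            if first in visited:
                continue
            path = [n, first]
            visited.add(first)
            cur = first
            while True:
                terms = [q for q in _nb8(mask, cur) if q in nodes and q != path[-2]]
                if terms:
                    path.append(_prefer(cur, terms)[0])
                    break
                cands = [q for q in _nb8(mask, cur) if q not in nodes and q not in visited]
                if not cands:
                    break
                cur = _prefer(cur, cands)[0]
                path.append(cur)
                visited.add(cur)
            emit(path)

    for a in sorted(nodes):
        for b in _nb8(mask, a):
            if b in nodes and a < b and not (a in junc and b in junc):
                emit([a, b])

    leftover = [p for p in px if p not in visited and p not in nodes]
    leftover_set = set(leftover)
    for start in sorted(leftover):
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        cur = start
        while True:
            cands = [q for q in _nb8(mask, cur) if q in leftover_set and q not in visited]
            if not cands:
                break
            cur = _prefer(cur, cands)[0]
            path.append(cur)
            visited.add(cur)
        emit(path, loop=True)
    return sorted(sigs)
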