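"""Linear (array-backed) oct-tree with depth-dependent bit-interleaved keys.

The simulation box is recursively bisected into octants up to a configurable
maximum depth ``d``.  Every particle receives a ``3*d``-bit identifier built
from its per-level octant choices (3 bits per level, x/y/z high-bits, most
significant level first — a Morton-style key whose length follows the tree
depth instead of being fixed).  Sorting particles by identifier makes every
box at every depth a contiguous slot range; a per-level offset table over the
sorted array is the only supporting structure needed for searching.

Queries (fixed-radius and nearest-neighbor) walk the level tables, pruning
boxes whose padded bounds cannot intersect the search ball, and then filter
the surviving candidates by exact Euclidean distance.  Pruning uses a
conservative slack of a few ULPs of the box side, so results are *exact*:
they agree with exhaustive search on every input, including boundary points.
That exactness is what makes byte-identical brute/tree solver comparisons
possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class OutOfBoxError(ValueError):
    """A position lies outside the root box."""


class EmptyTreeError(ValueError):
    """Attempt to build a tree over zero particles."""


@dataclass
class QueryCounters:
    """Work counters for complexity measurements (hardware independent)."""
    box_tests: int = 0
    dist_evals: int = 0

    @property
    def total(self) -> int:
        return self.box_tests + self.dist_evals

    def reset(self) -> None:
        self.box_tests = 0
        self.dist_evals = 0


@dataclass(frozen=True)
class OctreeConfig:
    """Tree geometry: maximum depth and the cubic root box.

    The identifier bit length is ``3 * max_depth`` (e.g. depth 5 gives 15-bit
    keys).  The root box must enclose every indexed position; its upper faces
    are inclusive, all interior box boundaries follow the lower-inclusive /
    upper-exclusive convention (a coordinate equal to a box midpoint belongs
    to the upper child).
    """

    max_depth: int
    origin: tuple[float, float, float]
    side: float

    def __post_init__(self):
        if not (1 <= self.max_depth <= 20):
            raise ValueError("max_depth must be in [1, 20]")
        if self.side <= 0:
            raise ValueError("root box side must be positive")

    @property
    def id_bits(self) -> int:
        return 3 * self.max_depth


def root_box_for(positions: np.ndarray, max_depth: int = 10,
                 pad_rel: float = 1e-6) -> OctreeConfig:
    """Tight bounding cube of *positions*, expanded so boundary particles are
    interior (relative padding ``pad_rel``)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    lo = positions.min(axis=0)
    hi = positions.max(axis=0)
    side = float((hi - lo).max())
    side = (side if side > 0 else 1.0) * (1.0 + 2.0 * pad_rel)
    center = 0.5 * (lo + hi)
    origin = center - 0.5 * side
    return OctreeConfig(max_depth=max_depth, origin=tuple(origin), side=side)


def compute_box_id(positions: np.ndarray, config: OctreeConfig) -> np.ndarray:
    """3·d-bit identifier of the depth-d box containing each position.

    Accepts a single ``(3,)`` position or an ``(N, 3)`` array; returns uint64
    scalar/array.  Raises :class:`OutOfBoxError` for positions outside the
    root box (upper faces inclusive).
    """
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    d = config.max_depth
    t = (pos - np.asarray(config.origin)) / config.side
    if np.any(t < 0.0) or np.any(t > 1.0):
        bad = np.flatnonzero(np.any((t < 0.0) | (t > 1.0), axis=1))[0]
        raise OutOfBoxError(f"position {bad} outside root box")
    ncell = np.uint64(1) << np.uint64(d)
    cells = np.minimum((t * float(2 ** d)).astype(np.uint64), ncell - np.uint64(1))
    ix, iy, iz = cells[:, 0], cells[:, 1], cells[:, 2]
    ids = np.zeros(len(pos), dtype=np.uint64)
    one = np.uint64(1)
    for lev in range(d):
        shift = np.uint64(d - 1 - lev)
        trip = (((ix >> shift) & one) << np.uint64(2)) \
             | (((iy >> shift) & one) << one) \
             | ((iz >> shift) & one)
        ids = (ids << np.uint64(3)) | trip
    return ids[0] if single else ids


def _deinterleave(prefix: np.ndarray, k: int):
    """Split 3·k-bit prefixes into per-axis k-bit integer cell coordinates."""
    ix = np.zeros_like(prefix)
    iy = np.zeros_like(prefix)
    iz = np.zeros_like(prefix)
    one = np.uint64(1)
    for lev in range(k):
        shift = np.uint64(3 * (k - 1 - lev))
        bshift = np.uint64(k - 1 - lev)
        ix |= (((prefix >> (shift + np.uint64(2))) & one) << bshift)
        iy |= (((prefix >> (shift + one)) & one) << bshift)
        iz |= (((prefix >> shift) & one) << bshift)
    return ix, iy, iz


def _expand_ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate ``arange(s, s+c)`` for each (s, c) pair, vectorized."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    cum = np.cumsum(counts)
    offs = np.repeat(starts - np.concatenate(([0], cum[:-1])), counts)
    return np.arange(total, dtype=np.int64) + offs


@dataclass
class LinearOctree:
    """Sorted-key oct-tree plus per-level search index.

    ``ids`` is the nondecreasing array of box identifiers, ``perm`` the stable
    permutation from sorted slots to original particle indices (ties broken by
    original index).  ``level_prefix[k] / level_start[k] / level_end[k]`` give,
    for every *occupied* depth-k box, its key prefix and contiguous slot range;
    ``child_lo[k] / child_hi[k]`` index its children among the depth-(k+1)
    boxes.  Particles sharing a depth-d key (deeper than the tree resolves)
    are stored contiguously in one leaf.
    """

    config: OctreeConfig
    ids: np.ndarray
    perm: np.ndarray
    pos_sorted: np.ndarray
    level_prefix: list = field(repr=False, default_factory=list)
    level_start: list = field(repr=False, default_factory=list)
    level_end: list = field(repr=False, default_factory=list)
    child_lo: list = field(repr=False, default_factory=list)
    child_hi: list = field(repr=False, default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)

    def dump_index(self, path) -> None:
        """Debug TSV of (depth, id, slot range) for every occupied box."""
        with open(path, "w") as fh:
            fh.write("depth\tbox_id\tslot_start\tslot_end\n")
            for k in range(len(self.level_prefix)):
                for p, s, e in zip(self.level_prefix[k], self.level_start[k],
                                   self.level_end[k]):
                    fh.write(f"{k}\t{int(p)}\t{int(s)}\t{int(e)}\n")


def build(positions: np.ndarray, config: OctreeConfig | None = None,
          max_depth: int = 10) -> LinearOctree:
    """Build the linear oct-tree: keys, stable sort, per-level offset tables.

    O(Na log Na); deterministic (equal keys keep original particle order).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) == 0:
        raise EmptyTreeError("cannot build a tree over zero particles")
    if config is None:
        config = root_box_for(positions, max_depth=max_depth)
    ids = compute_box_id(positions, config)
    ids = np.atleast_1d(ids)
    perm = np.argsort(ids, kind="stable").astype(np.int64)
    ids_sorted = ids[perm]
    tree = LinearOctree(config=config, ids=ids_sorted, perm=perm,
                        pos_sorted=np.ascontiguousarray(positions[perm]))
    d = config.max_depth
    n = len(ids_sorted)
    for k in range(d + 1):
        prefix = ids_sorted >> np.uint64(3 * (d - k))
        newbox = np.concatenate(([True], prefix[1:] != prefix[:-1]))
        starts = np.flatnonzero(newbox).astype(np.int64)
        tree.level_prefix.append(prefix[starts])
        tree.level_start.append(starts)
        tree.level_end.append(np.concatenate((starts[1:], [n])).astype(np.int64))
    for k in range(d):
        parents_of_next = tree.level_prefix[k + 1] >> np.uint64(3)
        tree.child_lo.append(
            np.searchsorted(parents_of_next, tree.level_prefix[k], "left"))
        tree.child_hi.append(
            np.searchsorted(parents_of_next, tree.level_prefix[k], "right"))
    return tree


def squared_distance_cols(ax, ay, az, bx, by, bz):
    """Componentwise squared distance dx·dx + dy·dy + dz·dz.

    Both the brute-force scans and the tree searches compute distances through
    this one helper, so candidate distances carry identical floating-point bit
    patterns in either code path.
    """
    dx = ax - bx
    dy = ay - by
    dz = az - bz
    return dx * dx + dy * dy + dz * dz


_LEAF_CUTOFF = 8      # resolve boxes this small without descending further
_PAD_REL = 1e-9       # conservative pruning slack (fraction of root side)


def candidates_within(tree: LinearOctree, points: np.ndarray, r2: np.ndarray,
                      counters: QueryCounters | None = None):
    """All (query, particle) pairs surviving box-ball pruning.

    *points* is ``(Q, 3)``, *r2* the per-query squared search radius.  Returns
    ``(q_idx, slot, d2)``: candidate pairs with exact squared distances; the
    caller applies the final ``d2 <= r2`` filter.  Guaranteed superset of the
    true in-ball pairs (pruning bounds are padded outward).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), (len(points),))
    cfg = tree.config
    origin = np.asarray(cfg.origin)
    pad = cfg.side * _PAD_REL
    d = cfg.max_depth
    qidx = np.arange(len(points), dtype=np.int64)
    nidx = np.zeros(len(points), dtype=np.int64)
    out_q, out_s = [], []
    for k in range(d + 1):
        if len(qidx) == 0:
            break
        prefix = tree.level_prefix[k][nidx]
        ixyz = np.stack(_deinterleave(prefix, k), axis=1).astype(float)
        h = cfg.side / float(2 ** k)
        lo = origin + ixyz * h - pad
        hi = lo + h + 2.0 * pad
        p = points[qidx]
        if counters is not None:
            counters.box_tests += len(qidx)
        cl = np.clip(p, lo, hi)
        dd = p - cl
        d2box = np.einsum("ij,ij->i", dd, dd)
        keep = d2box <= r2[qidx]
        qidx, nidx = qidx[keep], nidx[keep]
        if len(qidx) == 0:
            break
        start = tree.level_start[k][nidx]
        end = tree.level_end[k][nidx]
        cnt = end - start
        final = (cnt <= _LEAF_CUTOFF) if k < d else np.ones(len(qidx), bool)
        if np.any(final):
            fs, fc = start[final], cnt[final]
            out_s.append(_expand_ranges(fs, fc))
            out_q.append(np.repeat(qidx[final], fc))
        if k == d:
            break
        open_ = ~final
        qidx, nidx = qidx[open_], nidx[open_]
        if len(qidx) == 0:
            break
        clo = tree.child_lo[k][nidx]
        ccnt = tree.child_hi[k][nidx] - clo
        qidx = np.repeat(qidx, ccnt)
        nidx = _expand_ranges(clo, ccnt)
    if not out_q:
        e = np.empty(0, dtype=np.int64)
        return e, e, np.empty(0, dtype=float)
    q = np.concatenate(out_q)
    s = np.concatenate(out_s)
    xs, ys, zs = tree.pos_sorted[:, 0], tree.pos_sorted[:, 1], tree.pos_sorted[:, 2]
    d2 = squared_distance_cols(points[q, 0], points[q, 1], points[q, 2],
                               xs[s], ys[s], zs[s])
    if counters is not None:
        counters.dist_evals += len(q)
    return q, s, d2


def neighbors_within(tree: LinearOctree, point: np.ndarray, r_max: float,
                     counters: QueryCounters | None = None) -> np.ndarray:
    """Original indices of all particles with distance <= r_max from *point*,
    ascending.  Exact (agrees with exhaustive search)."""
    if r_max < 0:
        raise ValueError("r_max must be >= 0")
    q, s, d2 = candidates_within(tree, np.asarray(point, float)[None, :],
                                 np.array([r_max * r_max]), counters)
    hit = d2 <= r_max * r_max
    return np.sort(tree.perm[s[hit]])


def nearest_within_batch(tree: LinearOctree, points: np.ndarray,
                         r_max: np.ndarray,
                         counters: QueryCounters | None = None):
    """Nearest indexed particle within a per-query radius, batched.

    Returns ``(idx, d2)`` with ``idx[q] = -1`` where no particle qualifies.
    Ties in distance are broken by the smallest original particle index,
    matching a brute-force first-minimum scan bit for bit.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    nq = len(points)
    r = np.broadcast_to(np.asarray(r_max, dtype=float), (nq,))
    r2 = r * r
    q, s, d2 = candidates_within(tree, points, r2, counters)
    hit = d2 <= r2[q]
    q, s, d2 = q[hit], s[hit], d2[hit]
    idx_out = np.full(nq, -1, dtype=np.int64)
    d2_out = np.full(nq, np.inf)
    if len(q):
        orig = tree.perm[s]
        order = np.lexsort((orig, d2, q))
        qo, oo, do = q[order], orig[order], d2[order]
        first = np.concatenate(([True], qo[1:] != qo[:-1]))
        idx_out[qo[first]] = oo[first]
        d2_out[qo[first]] = do[first]
    return idx_out, d2_out


def nearest_within(tree: LinearOctree, point: np.ndarray, r_max: float,
                   counters: QueryCounters | None = None):
    """Closest indexed particle within ``r_max`` of *point*.

    Returns ``(original_index, distance)`` or ``None``; ties broken by the
    smallest original index.
    """
    if r_max < 0:
        raise ValueError("r_max must be >= 0")
    idx, d2 = nearest_within_batch(tree, np.asarray(point, float)[None, :],
                                   np.array([r_max]), counters)
    if idx[0] < 0:
        return None
    return int(idx[0]), float(np.sqrt(d2[0]))
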