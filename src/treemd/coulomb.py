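"""Coulomb forces and potentials on charged particles.

Two interchangeable solvers:

* ``brute`` — exact all-pairs summation with Newton's-third-law symmetric
  accumulation, O(Nq²).  This is the reference every approximation is tested
  against.
* ``tree`` — Barnes–Hut over the linear oct-tree.  Each occupied box carries
  monopole (and optionally dipole) moments about its |q|-weighted center of
  charge; a box of side s at distance d from the target is evaluated through
  its multipole expansion when s/d < θ (the opening-angle criterion), opened
  otherwise, and leaf particles are summed directly.  θ = 0 never accepts a
  box, so the tree walk degenerates to the exact brute-force answer.

Both solvers report a hardware-independent work counter: unordered direct
pairs plus multipole evaluations.  In atomic units the interaction is simply
q_i q_j / r, softened to q_i q_j / sqrt(r² + ε²) to keep close electron–ion
encounters integrable; multipole contributions of well-separated boxes are
evaluated unsoftened.

The per-pair and per-target inner loops are numba-compiled; traversal and
accumulation order are fixed, so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .octree import LinearOctree, build
from .particles import SingularConfigurationError


@dataclass
class PairCounter:
    """Operation counts for one solver run.

    ``direct_ordered`` counts ordered particle–particle evaluations; the
    reported :attr:`count` folds them to unordered pairs so that a θ = 0 tree
    run reproduces the brute-force count Nq(Nq−1)/2 exactly.
    """
    direct_ordered: int = 0
    multipole_evals: int = 0

    @property
    def count(self) -> int:
        return int(round(self.direct_ordered / 2)) + self.multipole_evals

    def reset(self) -> None:
        self.direct_ordered = 0
        self.multipole_evals = 0


@dataclass(frozen=True)
class SolverConfig:
    """Coulomb solver selection and accuracy knobs.

    theta: opening angle (dimensionless); the recommended production range is
    [0.1, 0.6] and 0 forces full opening.  multipole_order: 0 = monopole,
    1 = monopole + dipole.  softening: Plummer regularization length [bohr].
    """
    method: str = "brute"
    theta: float = 0.4
    multipole_order: int = 1
    softening: float = 0.0
    max_depth: int = 10

    def __post_init__(self):
        if self.method not in ("brute", "tree"):
            raise ValueError("method must be 'brute' or 'tree'")
        if self.theta < 0 or self.softening < 0:
            raise ValueError("theta and softening must be >= 0")
        if self.multipole_order not in (0, 1):
            raise ValueError("multipole_order must be 0 or 1")
        if self.method == "tree" and self.theta != 0 and not (0.1 <= self.theta <= 0.6):
            warnings.warn(f"opening angle {self.theta} outside the recommended "
                          "[0.1, 0.6] range", stacklevel=2)


@njit(cache=True)
def _brute_kernel(x, y, z, q, eps2):
    n = len(q)
    F = np.zeros((n, 3))
    phi = np.zeros(n)
    singular = False
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            dz = z[i] - z[j]
            r2 = dx * dx + dy * dy + dz * dz + eps2
            if r2 == 0.0:
                singular = True
                continue
            inv = 1.0 / np.sqrt(r2)
            inv3 = inv / r2
            f = q[i] * q[j] * inv3
            F[i, 0] += f * dx
            F[i, 1] += f * dy
            F[i, 2] += f * dz
            F[j, 0] -= f * dx
            F[j, 1] -= f * dy
            F[j, 2] -= f * dz
            phi[i] += q[j] * inv
            phi[j] += q[i] * inv
    return F, phi, singular


def brute_forces(pos: np.ndarray, q: np.ndarray, softening: float = 0.0,
                 counter: PairCounter | None = None):
    """Exact pairwise forces [hartree/bohr] and potentials [hartree/e].

    F_i = sum_{j != i} q_i q_j (r_i − r_j) / (|r_i − r_j|² + ε²)^{3/2}; each
    unordered pair is evaluated once, in ascending (i, j) order, and
    accumulated symmetrically, so total momentum is conserved to round-off.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    q = np.asarray(q, dtype=float)
    n = len(q)
    F, phi, singular = _brute_kernel(
        np.ascontiguousarray(pos[:, 0]), np.ascontiguousarray(pos[:, 1]),
        np.ascontiguousarray(pos[:, 2]), q, softening * softening)
    if singular:
        raise SingularConfigurationError(
            "coincident charged particles with zero softening")
    if counter is not None:
        counter.direct_ordered += n * (n - 1)
    return F, phi


@dataclass
class MultipoleMoments:
    """Per-level box aggregates for Barnes–Hut evaluation.

    For every occupied box: total charge Q, |q|-weighted center of charge,
    and the dipole moment about that center.  Built bottom-up; parents are
    derived from children through the moment shift identities.
    """
    Q: list = field(default_factory=list)       # [k] -> (M_k,)
    W: list = field(default_factory=list)       # sum |q|
    coc: list = field(default_factory=list)     # (M_k, 3)
    dip: list = field(default_factory=list)     # (M_k, 3)


def compute_moments(tree: LinearOctree, charges: np.ndarray) -> MultipoleMoments:
    """Aggregate charges into per-box moments, leaves first.

    *charges* is given in original particle order (the same particle set the
    tree indexes); a leaf's moments are direct sums over its particles and a
    parent's follow from its children via the shift theorem.
    """
    q_sorted = np.asarray(charges, dtype=float)[tree.perm]
    absq = np.abs(q_sorted)
    pos = tree.pos_sorted
    d = tree.config.max_depth
    mom = MultipoleMoments()
    nlev = len(tree.level_start)
    mom.Q = [None] * nlev
    mom.W = [None] * nlev
    mom.coc = [None] * nlev
    mom.dip = [None] * nlev

    starts = tree.level_start[d]
    counts = tree.level_end[d] - starts
    Q = np.add.reduceat(q_sorted, starts)
    W = np.add.reduceat(absq, starts)
    coc = np.add.reduceat(absq[:, None] * pos, starts, axis=0) / W[:, None]
    rel = pos - np.repeat(coc, counts, axis=0)
    dip = np.add.reduceat(q_sorted[:, None] * rel, starts, axis=0)
    mom.Q[d], mom.W[d], mom.coc[d], mom.dip[d] = Q, W, coc, dip

    for k in range(d - 1, -1, -1):
        clo = tree.child_lo[k]
        Qc, Wc, cocc, dipc = mom.Q[k + 1], mom.W[k + 1], mom.coc[k + 1], mom.dip[k + 1]
        Q = np.add.reduceat(Qc, clo)
        W = np.add.reduceat(Wc, clo)
        coc = np.add.reduceat(Wc[:, None] * cocc, clo, axis=0) / W[:, None]
        ccnt = tree.child_hi[k] - clo
        shift = cocc - np.repeat(coc, ccnt, axis=0)
        dip = np.add.reduceat(dipc + Qc[:, None] * shift, clo, axis=0)
        mom.Q[k], mom.W[k], mom.coc[k], mom.dip[k] = Q, W, coc, dip
    return mom


def _flatten_nodes(tree: LinearOctree, mom: MultipoleMoments):
    """Concatenate the per-level node tables into flat arrays with child
    pointers, for the compiled tree walk."""
    d = tree.config.max_depth
    sizes = [len(tree.level_start[k]) for k in range(d + 1)]
    offset = np.concatenate(([0], np.cumsum(sizes))).astype(np.int64)
    level = np.concatenate([np.full(sizes[k], k, dtype=np.int64)
                            for k in range(d + 1)])
    start = np.concatenate(tree.level_start)
    end = np.concatenate(tree.level_end)
    child0 = np.zeros(offset[-1], dtype=np.int64)
    nchild = np.zeros(offset[-1], dtype=np.int64)
    for k in range(d):
        sl = slice(offset[k], offset[k + 1])
        child0[sl] = offset[k + 1] + tree.child_lo[k]
        nchild[sl] = tree.child_hi[k] - tree.child_lo[k]
    Q = np.concatenate(mom.Q)
    coc = np.concatenate(mom.coc, axis=0)
    dip = np.concatenate(mom.dip, axis=0)
    sides = tree.config.side / (2.0 ** np.arange(d + 1))
    return level, start, end, child0, nchild, Q, coc, dip, sides


_LEAF_CUTOFF = 8


@njit(cache=True)
def _tree_walk_kernel(tx, ty, tz, tq, slot_of, xs, ys, zs, qs, perm,
                      level, start, end, child0, nchild,
                      nQ, coc, dip, sides, theta, eps2, order, leaf_cutoff):
    n = len(tx)
    F = np.zeros((n, 3))
    phi = np.zeros(n)
    stack = np.empty(512, dtype=np.int64)
    n_direct = 0
    n_multi = 0
    singular = False
    for t in range(n):
        ex = 0.0
        ey = 0.0
        ez = 0.0
        p = 0.0
        myslot = slot_of[t]
        sp = 1
        stack[0] = 0
        while sp > 0:
            sp -= 1
            nd = stack[sp]
            dx = tx[t] - coc[nd, 0]
            dy = ty[t] - coc[nd, 1]
            dz = tz[t] - coc[nd, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            s = sides[level[nd]]
            inside = (start[nd] <= myslot) and (myslot < end[nd])
            if (not inside) and (s < theta * r):
                inv = 1.0 / r
                inv3 = inv / r2
                p += nQ[nd] * inv
                c0 = nQ[nd] * inv3
                ex += c0 * dx
                ey += c0 * dy
                ez += c0 * dz
                if order >= 1:
                    pd = dip[nd, 0] * dx + dip[nd, 1] * dy + dip[nd, 2] * dz
                    p += pd * inv3
                    c1 = 3.0 * pd * inv3 / r2
                    ex += c1 * dx - inv3 * dip[nd, 0]
                    ey += c1 * dy - inv3 * dip[nd, 1]
                    ez += c1 * dz - inv3 * dip[nd, 2]
                n_multi += 1
            else:
                cnt = end[nd] - start[nd]
                if nchild[nd] == 0 or cnt <= leaf_cutoff:
                    for sl in range(start[nd], end[nd]):
                        if perm[sl] == t:
                            continue
                        ddx = tx[t] - xs[sl]
                        ddy = ty[t] - ys[sl]
                        ddz = tz[t] - zs[sl]
                        rr2 = ddx * ddx + ddy * ddy + ddz * ddz + eps2
                        if rr2 == 0.0:
                            singular = True
                            continue
                        invr = 1.0 / np.sqrt(rr2)
                        invr3 = invr / rr2
                        p += qs[sl] * invr
                        cd = qs[sl] * invr3
                        ex += cd * ddx
                        ey += cd * ddy
                        ez += cd * ddz
                        n_direct += 1
                else:
                    for c in range(child0[nd], child0[nd] + nchild[nd]):
                        stack[sp] = c
                        sp += 1
        F[t, 0] = tq[t] * ex
        F[t, 1] = tq[t] * ey
        F[t, 2] = tq[t] * ez
        phi[t] = p
    return F, phi, n_direct, n_multi, singular


def tree_forces(tree: LinearOctree, moments: MultipoleMoments,
                charges: np.ndarray, config: SolverConfig,
                counter: PairCounter | None = None):
    """Barnes–Hut forces/potentials on the tree's own particles.

    A box is accepted (evaluated via its multipole expansion, unsoftened)
    when s/d < θ, with d the distance from the target to the box's center of
    charge, and the box does not contain the target; otherwise it is opened,
    and leaf particles are evaluated directly with softening ε, excluding
    self.  Fixed depth-first traversal order per target; results are in the
    original particle order.
    """
    q = np.ascontiguousarray(charges, dtype=float)
    n = tree.n
    inv = np.empty(n, dtype=np.int64)
    inv[tree.perm] = np.arange(n)
    tpos = tree.pos_sorted[inv]
    level, start, end, child0, nchild, Q, coc, dip, sides = \
        _flatten_nodes(tree, moments)
    F, phi, n_direct, n_multi, singular = _tree_walk_kernel(
        np.ascontiguousarray(tpos[:, 0]), np.ascontiguousarray(tpos[:, 1]),
        np.ascontiguousarray(tpos[:, 2]), q, inv,
        np.ascontiguousarray(tree.pos_sorted[:, 0]),
        np.ascontiguousarray(tree.pos_sorted[:, 1]),
        np.ascontiguousarray(tree.pos_sorted[:, 2]),
        q[tree.perm], tree.perm,
        level, start, end, child0, nchild, Q, coc, dip, sides,
        float(config.theta), config.softening ** 2,
        config.multipole_order, _LEAF_CUTOFF)
    if singular:
        raise SingularConfigurationError(
            "coincident charged particles with zero softening")
    if counter is not None:
        counter.direct_ordered += int(n_direct)
        counter.multipole_evals += int(n_multi)
    return F, phi


def forces(pos: np.ndarray, q: np.ndarray, config: SolverConfig,
           counter: PairCounter | None = None):
    """Dispatch to the configured solver; returns (F, phi)."""
    if config.method == "brute":
        return brute_forces(pos, q, config.softening, counter)
    tree = build(pos, max_depth=config.max_depth)
    mom = compute_moments(tree, q)
    return tree_forces(tree, mom, q, config, counter)
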