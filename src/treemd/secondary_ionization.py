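"""Secondary (electron-impact) ionization: brute-force and tree-based search.

Each free electron may ionize its *nearest* atom/ion, provided that target
lies within a cutoff radius estimated from the impact-ionization cross
section and the collision energy exceeds the orbital binding energy.  The
decision is a deterministic, pure function of the (electron, nearest-target)
pair — no random draw enters the search — which is what makes the two
interchangeable search implementations comparable at the byte level:

* ``brute`` scans every atom for every electron (O(Ne·Na) distances);
* ``tree`` builds the linear oct-tree over atoms/ions each step and runs a
  pruned nearest-neighbor query per electron (O(Ne·log Na)).

Both paths compute candidate distances through the same componentwise
helper and break distance ties by the smallest atom index, so they select
identical targets, apply identical updates, and produce bit-wise identical
event lists and post-states.

The packaged cross-section model is Lotz-type, σ(E) = a·N·ln(E/B)/(E·B)
above threshold B (N = orbital occupation), zero below; the search structure
is agnostic to the particular model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as C
from .octree import QueryCounters, build, nearest_within_batch, squared_distance_cols
from .particles import SystemState
from .rates import RateTables

_E_SEC_CAP_HA = 10.0 * C.EV_HARTREE    # secondary electron gets at most 10 eV
_E_SEC_FRACTION = 0.1                  # ... and at most 10% of the surplus
_EMISSION_OFFSET = 0.5                 # bohr


@dataclass(frozen=True)
class SIConfig:
    """implementation: 'brute' or 'tree'; max_depth applies to the tree."""
    implementation: str = "brute"
    max_depth: int = 10

    def __post_init__(self):
        if self.implementation not in ("brute", "tree"):
            raise ValueError("implementation must be 'brute' or 'tree'")


@dataclass(frozen=True)
class SIEvent:
    electron: int
    atom: int
    orbital: int
    step: int


def impact_cross_section(e_rel_ev, binding_ev, occupation,
                         lotz_a_mb_ev2: float):
    """Lotz-type impact-ionization cross section [bohr²].

    σ(E) = a·N·ln(E/B)/(E·B) for E > B, 0 at and below threshold; continuous
    at E = B and maximal at E = e·B.  Vectorized over any broadcastable
    combination of arguments.
    """
    e = np.asarray(e_rel_ev, dtype=float)
    b = np.asarray(binding_ev, dtype=float)
    n = np.asarray(occupation, dtype=float)
    above = (e > b) & (b > 0) & (n > 0)
    ratio = np.where(above, e / np.where(b > 0, b, 1.0), 1.0)
    sigma_mb = np.where(above,
                        lotz_a_mb_ev2 * n * np.log(ratio)
                        / (np.where(above, e, 1.0) * np.where(b > 0, b, 1.0)),
                        0.0)
    return sigma_mb * C.MBARN_BOHR2


def si_cutoff(e_rel_ev, tables: RateTables, elem: int | None = None,
              occupations: np.ndarray | None = None):
    """Pre-assessment cutoff radius [bohr]: r = sqrt(σ_max over orbitals / π).

    With *elem* (and optionally its current *occupations*) the maximum runs
    over that element's orbitals; otherwise over every orbital of every
    tabulated element at neutral occupation — the conservative radius used to
    bound the per-electron neighbor search.  Zero when every σ vanishes.
    """
    e = np.asarray(e_rel_ev, dtype=float)
    if elem is None:
        be = tables.binding_ev[tables.orbital_mask()]
        occ = tables.neutral_occ[tables.orbital_mask()]
    else:
        m = tables.orbital_mask()[elem]
        be = tables.binding_ev[elem][m]
        occ = (tables.neutral_occ[elem] if occupations is None
               else occupations)[m]
    sig = impact_cross_section(e[..., None], be, occ, tables.lotz_a_mb_ev2)
    return np.sqrt(sig.max(axis=-1) / math.pi)


def evaluate_pair(state: SystemState, electron: int, atom: int,
                  tables: RateTables | None = None,
                  occupations: np.ndarray | None = None,
                  is_nearest: bool = True):
    """Deterministic SI criterion for one electron–atom pair.

    Returns the :class:`SIEvent` (orbital = occupied orbital of largest σ at
    the relative collision energy, ties to the lowest index) or ``None``.
    Conditions: the atom is the electron's nearest target (caller-asserted),
    the pair distance does not exceed the cross-section cutoff at the
    relative energy, and the relative energy reaches at least one occupied
    orbital's binding energy.  *occupations* may supply a pre-block snapshot
    row for the atom.
    """
    tables = tables or state.tables
    if not is_nearest:
        return None
    occ = (state.occ[atom] if occupations is None else occupations)
    e = state.elem[atom]
    vrel = state.evel[electron] - state.avel[atom]
    e_rel_ha = 0.5 * float(vrel @ vrel)
    e_rel_ev = e_rel_ha * C.HARTREE_EV
    m = tables.orbital_mask()[e]
    sig = impact_cross_section(e_rel_ev, tables.binding_ev[e],
                               np.where(m, occ, 0), tables.lotz_a_mb_ev2)
    if not np.any(sig > 0):
        return None
    r_cut = math.sqrt(sig.max() / math.pi)
    d = state.apos[atom] - state.epos[electron]
    if float(d @ d) > r_cut * r_cut:
        return None
    orbital = int(np.argmax(sig))     # first maximum = lowest orbital index
    return SIEvent(electron=int(electron), atom=int(atom),
                   orbital=orbital, step=state.step_index)


def _query_radii(state: SystemState, tables: RateTables) -> np.ndarray:
    """Per-electron search radius from the lab-frame kinetic energy."""
    ke_ev = 0.5 * np.einsum("ij,ij->i", state.evel, state.evel) * C.HARTREE_EV
    return np.atleast_1d(si_cutoff(ke_ev, tables))


def _nearest_brute(state: SystemState, r: np.ndarray,
                   counters: QueryCounters):
    """Nearest atom within r per electron by full scan; first-minimum ties."""
    ne, na = state.n_electrons, state.n_atoms
    idx = np.full(ne, -1, dtype=np.int64)
    ax, ay, az = state.apos[:, 0], state.apos[:, 1], state.apos[:, 2]
    r2 = r * r
    block = max(1, (1 << 22) // max(na, 1))
    for i0 in range(0, ne, block):
        i1 = min(i0 + block, ne)
        d2 = squared_distance_cols(
            state.epos[i0:i1, 0, None], state.epos[i0:i1, 1, None],
            state.epos[i0:i1, 2, None], ax[None, :], ay[None, :], az[None, :])
        masked = np.where(d2 <= r2[i0:i1, None], d2, np.inf)
        best = np.argmin(masked, axis=1)
        found = np.isfinite(masked[np.arange(i1 - i0), best])
        idx[i0:i1][found] = best[found]
    counters.dist_evals += ne * na
    return idx


def _nearest_tree(state: SystemState, r: np.ndarray, max_depth: int,
                  counters: QueryCounters):
    tree = build(state.apos, max_depth=max_depth)
    idx, _ = nearest_within_batch(tree, state.epos, r, counters)
    return idx


def si_block(state: SystemState, config: SIConfig,
             tables: RateTables | None = None, seed: int = 0,
             counters: QueryCounters | None = None):
    """Run one SI pass: find targets, apply events, emit secondaries.

    Electrons are processed in ascending index order against the pre-block
    atom snapshot; the brute and tree implementations produce bit-wise
    identical event lists and post-states.  Returns ``(events, counters)``.
    """
    tables = tables or state.tables
    counters = counters if counters is not None else QueryCounters()
    step = state.step_index
    if state.n_electrons == 0 or state.n_atoms == 0:
        return [], counters
    occ_snapshot = state.occ.copy()
    r = _query_radii(state, tables)
    if config.implementation == "brute":
        nearest = _nearest_brute(state, r, counters)
    else:
        nearest = _nearest_tree(state, r, config.max_depth, counters)

    events: list[SIEvent] = []
    new_pos, new_vel = [], []
    for ei in np.flatnonzero(nearest >= 0):
        ai = int(nearest[ei])
        ev = evaluate_pair(state, int(ei), ai, tables,
                           occupations=occ_snapshot[ai])
        if ev is None:
            continue
        if state.occ[ai, ev.orbital] < 1:
            continue    # target orbital emptied earlier this block
        e = state.elem[ai]
        b_ha = tables.binding_ev[e, ev.orbital] * C.EV_HARTREE
        vrel = state.evel[ei] - state.avel[ai]
        e_rel = 0.5 * float(vrel @ vrel)
        surplus = e_rel - b_ha
        e_sec = min(_E_SEC_FRACTION * surplus, _E_SEC_CAP_HA)
        e_pri = surplus - e_sec
        # primary: same direction in the target frame, rescaled energy
        vmag = math.sqrt(float(vrel @ vrel))
        direction = vrel / vmag
        state.evel[ei] = state.avel[ai] + math.sqrt(2.0 * e_pri) * direction
        # secondary: isotropic, from the per-event keyed stream
        ev_rng = np.random.default_rng(
            [seed & 0x7FFFFFFF, 15485863, step, int(ei)])
        u = ev_rng.normal(size=3)
        u /= np.linalg.norm(u)
        new_pos.append(state.apos[ai] + _EMISSION_OFFSET * u)
        new_vel.append(state.avel[ai] + math.sqrt(2.0 * e_sec) * u)
        state.occ[ai, ev.orbital] -= 1
        events.append(ev)
    if new_pos:
        state.epos = np.concatenate([state.epos, np.asarray(new_pos)], axis=0)
        state.evel = np.concatenate([state.evel, np.asarray(new_vel)], axis=0)
    return events, counters
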