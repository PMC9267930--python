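"""Electron–ion recombination: the bookkeeping inverse of ionization.

An electron recombines with its nearest ion within the capture radius when
the pair is classically bound (relative kinetic energy below the Coulomb
binding at the pair distance).  On capture the electron particle is removed,
the ion's charge drops by one, and the outermost orbital with a vacancy
gains one electron; the electron's kinetic energy leaves the classical
ledger and is logged.  Each ion captures at most once per step — the
lowest-index claiming electron wins.

Like the SI block, the search exists in a brute-force O(Ne·Ni) variant and a
tree variant (oct-tree over ions only, O(Ne·log Ni)), with bit-wise
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .octree import QueryCounters, build, nearest_within_batch, squared_distance_cols
from .particles import BookkeepingError, SystemState
from .rates import RateTables


@dataclass(frozen=True)
class REConfig:
    """capture_radius [bohr] > 0; implementation 'brute' or 'tree'."""
    capture_radius: float = 2.0
    implementation: str = "brute"
    max_depth: int = 10

    def __post_init__(self):
        if self.capture_radius <= 0:
            raise ValueError("capture radius must be positive")
        if self.implementation not in ("brute", "tree"):
            raise ValueError("implementation must be 'brute' or 'tree'")


@dataclass(frozen=True)
class REEvent:
    electron: int
    ion: int          # atom index
    orbital: int      # orbital that received the electron
    step: int


def evaluate_recombination(state: SystemState, electron: int, ion: int,
                           r_rec: float, is_nearest: bool = True) -> bool:
    """Capture decision for one electron–ion pair.

    True iff the pair distance is within the capture radius, the pair is
    classically bound (½ μ v_rel² − q_ion/r < 0), and the ion is the
    electron's nearest ion within that radius (caller-asserted).
    """
    if not is_nearest:
        return False
    if state.charge_state[ion] < 1:
        raise ValueError("recombination target must be an ion (charge >= 1)")
    d = state.apos[ion] - state.epos[electron]
    r2 = float(d @ d)
    if r2 > r_rec * r_rec:
        return False
    if r2 == 0.0:
        return True     # coincident pair: infinitely bound
    m_ion = state.masses[ion]
    mu = m_ion / (1.0 + m_ion)
    vrel = state.evel[electron] - state.avel[ion]
    e_pair = 0.5 * mu * float(vrel @ vrel) \
        - float(state.charge_state[ion]) / np.sqrt(r2)
    return bool(e_pair < 0.0)


def _nearest_ion_brute(state: SystemState, ion_idx: np.ndarray, r_rec: float,
                       counters: QueryCounters) -> np.ndarray:
    ne, ni = state.n_electrons, len(ion_idx)
    out = np.full(ne, -1, dtype=np.int64)
    if ni == 0 or ne == 0:
        return out
    ip = state.apos[ion_idx]
    r2max = r_rec * r_rec
    block = max(1, (1 << 22) // ni)
    for i0 in range(0, ne, block):
        i1 = min(i0 + block, ne)
        d2 = squared_distance_cols(
            state.epos[i0:i1, 0, None], state.epos[i0:i1, 1, None],
            state.epos[i0:i1, 2, None],
            ip[None, :, 0], ip[None, :, 1], ip[None, :, 2])
        masked = np.where(d2 <= r2max, d2, np.inf)
        best = np.argmin(masked, axis=1)
        found = np.isfinite(masked[np.arange(i1 - i0), best])
        out[i0:i1][found] = best[found]
    counters.dist_evals += ne * ni
    return out


def _nearest_ion_tree(state: SystemState, ion_idx: np.ndarray, r_rec: float,
                      max_depth: int, counters: QueryCounters) -> np.ndarray:
    if len(ion_idx) == 0 or state.n_electrons == 0:
        return np.full(state.n_electrons, -1, dtype=np.int64)
    tree = build(state.apos[ion_idx], max_depth=max_depth)
    idx, _ = nearest_within_batch(tree, state.epos,
                                  np.full(state.n_electrons, r_rec), counters)
    return idx


def re_block(state: SystemState, config: REConfig,
             tables: RateTables | None = None,
             counters: QueryCounters | None = None):
    """Run one recombination pass.

    Electrons are processed in ascending index order against the pre-block
    ion snapshot; captured electrons are removed after the pass.  Returns
    ``(events, counters, released_energy_ha)`` where the energy is the
    kinetic energy of the captured electrons dropped from the classical
    ledger.
    """
    tables = tables or state.tables
    counters = counters if counters is not None else QueryCounters()
    ion_idx = np.flatnonzero(state.charge_state >= 1)
    events: list[REEvent] = []
    released = 0.0
    if len(ion_idx) == 0 or state.n_electrons == 0:
        return events, counters, released
    if config.implementation == "brute":
        nearest = _nearest_ion_brute(state, ion_idx, config.capture_radius,
                                     counters)
    else:
        nearest = _nearest_ion_tree(state, ion_idx, config.capture_radius,
                                    config.max_depth, counters)
    cap = state.tables.capacity[state.elem]
    claimed: set[int] = set()
    captured: list[int] = []
    for ei in np.flatnonzero(nearest >= 0):
        ai = int(ion_idx[nearest[ei]])
        if ai in claimed:
            continue
        if not evaluate_recombination(state, int(ei), ai,
                                      config.capture_radius):
            continue
        occ = state.occ[ai]
        open_orbs = np.flatnonzero(occ < cap[ai])
        n_orb = tables.n_orbitals[state.elem[ai]]
        open_orbs = open_orbs[open_orbs < n_orb]
        if len(open_orbs) == 0:
            raise BookkeepingError(f"capture onto closed-shell atom {ai}")
        orb = int(open_orbs[-1])      # outermost (lowest-binding) vacancy
        state.occ[ai, orb] += 1
        claimed.add(ai)
        captured.append(int(ei))
        released += 0.5 * float(state.evel[ei] @ state.evel[ei])
        events.append(REEvent(electron=int(ei), ion=ai, orbital=orb,
                              step=state.step_index))
    if captured:
        keep = np.ones(state.n_electrons, dtype=bool)
        keep[captured] = False
        state.epos = state.epos[keep]
        state.evel = state.evel[keep]
    return events, counters, released
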