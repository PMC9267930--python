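"""Classical particle state and electronic-configuration bookkeeping.

Atoms/ions and free electrons are classical point particles.  Each atom
carries per-orbital occupation numbers; its charge state is always the neutral
electron count minus the current occupation sum, and every ionization or
recombination event updates both sides of that identity together, so the net
charge of the whole system (ion charges minus free electrons) is conserved by
construction.

The state is stored struct-of-arrays (numpy) rather than as per-particle
objects: every solver in the package is vectorized over these arrays, and
byte-level state comparisons (used to verify cross-solver equivalence) reduce
to comparisons of array buffers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .rates import RateTables, default_tables


class SingularConfigurationError(ValueError):
    """Coincident charged particles with zero softening."""


class BookkeepingError(ValueError):
    """Electronic-configuration update that violates orbital capacities."""


@dataclass
class SystemState:
    """All classical particles plus the simulation clock.

    Attributes
    ----------
    elem : (Na,) int
        Index of each atom's species into ``tables.elements``.
    apos, avel : (Na, 3) float
        Atom positions [bohr] and velocities [bohr / a.t.u.].
    occ : (Na, n_orb) int
        Per-orbital electron counts.
    epos, evel : (Ne, 3) float
        Free-electron positions and velocities; electrons have mass 1 and
        charge −1 exactly (atomic units).
    time : float
        Simulation clock [a.t.u.].
    """

    elem: np.ndarray
    apos: np.ndarray
    avel: np.ndarray
    occ: np.ndarray
    epos: np.ndarray
    evel: np.ndarray
    time: float = 0.0
    step_index: int = 0
    tables: RateTables = field(default_factory=default_tables)

    # -- counts ---------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        """Na: atoms plus ions of every charge state."""
        return len(self.elem)

    @property
    def n_electrons(self) -> int:
        """Ne: free classical electrons."""
        return len(self.epos)

    @property
    def charge_state(self) -> np.ndarray:
        """Per-atom charge [e]: neutral electron count minus occupation sum."""
        neutral = self.tables.neutral_occ.sum(axis=1)[self.elem]
        return neutral - self.occ.sum(axis=1)

    @property
    def n_ions(self) -> int:
        """Ni: atoms with charge state >= 1."""
        return int(np.count_nonzero(self.charge_state >= 1))

    @property
    def n_charged(self) -> int:
        """Nq: charged particles (ions + free electrons); neutral atoms excluded."""
        return self.n_ions + self.n_electrons

    @property
    def masses(self) -> np.ndarray:
        return self.tables.mass_me[self.elem]

    def copy(self) -> "SystemState":
        return SystemState(
            elem=self.elem.copy(), apos=self.apos.copy(), avel=self.avel.copy(),
            occ=self.occ.copy(), epos=self.epos.copy(), evel=self.evel.copy(),
            time=self.time, step_index=self.step_index, tables=self.tables,
        )

    def validate(self) -> None:
        cap = self.tables.capacity[self.elem]
        if np.any(self.occ < 0) or np.any(self.occ > cap):
            raise BookkeepingError("orbital occupations out of [0, capacity]")

    def digest(self) -> str:
        """SHA-256 over the raw particle buffers (byte-level identity check)."""
        h = hashlib.sha256()
        for a in (self.elem, self.apos, self.avel, self.occ, self.epos, self.evel):
            h.update(np.ascontiguousarray(a).tobytes())
        h.update(np.float64(self.time).tobytes())
        return h.hexdigest()


def charged_particles(state: SystemState):
    """Positions/charges/velocities/masses of all Coulomb-active particles.

    Returns ``(pos, q, vel, mass, ion_index)`` where ``ion_index`` maps the
    first ``Ni`` rows back to atom indices (electron rows follow the ions).
    Neutral atoms carry no Coulomb interaction and are excluded.
    """
    cs = state.charge_state
    ion_idx = np.flatnonzero(cs >= 1)
    pos = np.concatenate([state.apos[ion_idx], state.epos], axis=0)
    q = np.concatenate([cs[ion_idx].astype(float), -np.ones(state.n_electrons)])
    vel = np.concatenate([state.avel[ion_idx], state.evel], axis=0)
    mass = np.concatenate([state.masses[ion_idx], np.ones(state.n_electrons)])
    return pos, q, vel, mass, ion_idx


def total_charge(state: SystemState) -> int:
    """Net system charge [e]: sum of ion charge states minus free electrons."""
    return int(state.charge_state.sum()) - state.n_electrons


def kinetic_energy(state: SystemState) -> float:
    """Total classical kinetic energy [hartree]."""
    ka = 0.5 * np.sum(state.masses * np.einsum("ij,ij->i", state.avel, state.avel))
    ke = 0.5 * np.sum(np.einsum("ij,ij->i", state.evel, state.evel))
    return float(ka + ke)


def potential_energy(state: SystemState, softening: float = 0.0) -> float:
    """Pairwise Coulomb energy of all charged particles [hartree].

    PE = sum over unordered charged pairs of q_i q_j / sqrt(r^2 + eps^2).
    Raises :class:`SingularConfigurationError` for coincident charges at
    eps = 0.
    """
    if softening < 0:
        raise ValueError("softening must be >= 0")
    pos, q, _, _, _ = charged_particles(state)
    n = len(q)
    if n < 2:
        return 0.0
    pe = 0.0
    eps2 = softening * softening
    block = 2048
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        for j0 in range(i0, n, block):
            j1 = min(j0 + block, n)
            d = pos[i0:i1, None, :] - pos[None, j0:j1, :]
            r2 = np.einsum("ijk,ijk->ij", d, d) + eps2
            qq = q[i0:i1, None] * q[None, j0:j1]
            if i0 == j0:
                iu = np.triu_indices(i1 - i0, k=1)
                r2u = r2[iu]
                if np.any(r2u == 0.0):
                    raise SingularConfigurationError(
                        "coincident charged particles with zero softening")
                pe += float(np.sum(qq[iu] / np.sqrt(r2u)))
            else:
                if np.any(r2 == 0.0):
                    raise SingularConfigurationError(
                        "coincident charged particles with zero softening")
                pe += float(np.sum(qq / np.sqrt(r2)))
    return pe


# -- extended-XYZ snapshot I/O ------------------------------------------------
# columns: species  x y z [Å]  vx vy vz [Å/fs]  charge_state; free electrons
# appear as species "e-".

def write_xyz(state: SystemState, path) -> None:
    cs = state.charge_state
    with open(path, "w") as fh:
        n = state.n_atoms + state.n_electrons
        fh.write(f"{n}\n")
        fh.write(
            'Properties=species:S:1:pos:R:3:velo:R:3:charge:I:1 '
            f'Time_fs={state.time * C.ATU_FS:.9g}\n')
        ap = state.apos * C.BOHR_ANGSTROM
        av = state.avel * C.AU_TO_ANGFS
        for i in range(state.n_atoms):
            sym = state.tables.elements[state.elem[i]]
            fh.write(f"{sym} {ap[i,0]:.12g} {ap[i,1]:.12g} {ap[i,2]:.12g} "
                     f"{av[i,0]:.12g} {av[i,1]:.12g} {av[i,2]:.12g} {cs[i]}\n")
        ep = state.epos * C.BOHR_ANGSTROM
        ev = state.evel * C.AU_TO_ANGFS
        for i in range(state.n_electrons):
            fh.write(f"e- {ep[i,0]:.12g} {ep[i,1]:.12g} {ep[i,2]:.12g} "
                     f"{ev[i,0]:.12g} {ev[i,1]:.12g} {ev[i,2]:.12g} -1\n")


def read_xyz(path, tables: RateTables | None = None) -> SystemState:
    """Read an extended-XYZ snapshot written by :func:`write_xyz`.

    Atom charge states are realized by stripping electrons from the
    lowest-binding occupied orbitals of the neutral configuration.
    """
    tables = tables or default_tables()
    with open(path) as fh:
        n = int(fh.readline())
        header = fh.readline()
        rows = [fh.readline().split() for _ in range(n)]
    time_fs = 0.0
    for tok in header.split():
        if tok.startswith("Time_fs="):
            time_fs = float(tok.split("=", 1)[1])
    elem, apos, avel, occ = [], [], [], []
    epos, evel = [], []
    for r in rows:
        sym = r[0]
        p = [float(x) for x in r[1:4]]
        v = [float(x) for x in r[4:7]]
        if sym == "e-":
            epos.append(p)
            evel.append(v)
            continue
        e = tables.element_index(sym)
        q = int(r[7])
        o = tables.neutral_occ[e].copy()
        k = tables.n_orbitals[e] - 1
        left = q
        while left > 0:
            if k < 0:
                raise BookkeepingError(f"charge {q} infeasible for {sym}")
            take = min(left, o[k])
            o[k] -= take
            left -= take
            k -= 1
        elem.append(e)
        apos.append(p)
        avel.append(v)
        occ.append(o)
    n_orb = tables.capacity.shape[1]
    return SystemState(
        elem=np.asarray(elem, dtype=np.int64),
        apos=np.asarray(apos, dtype=float).reshape(-1, 3) * C.ANGSTROM_BOHR,
        avel=np.asarray(avel, dtype=float).reshape(-1, 3) * C.ANGFS_TO_AU,
        occ=np.asarray(occ, dtype=np.int64).reshape(-1, n_orb),
        epos=np.asarray(epos, dtype=float).reshape(-1, 3) * C.ANGSTROM_BOHR,
        evel=np.asarray(evel, dtype=float).reshape(-1, 3) * C.ANGFS_TO_AU,
        time=time_fs * C.FS_ATU,
        tables=tables,
    )


def write_hdf5_frame(group, state: SystemState) -> None:
    """Write one trajectory frame (positions, velocities, species, charges)."""
    group.create_dataset("atom_positions", data=state.apos)
    group.create_dataset("atom_velocities", data=state.avel)
    group.create_dataset("species", data=state.elem)
    group.create_dataset("occupations", data=state.occ)
    group.create_dataset("charge_states", data=state.charge_state)
    group.create_dataset("electron_positions", data=state.epos)
    group.create_dataset("electron_velocities", data=state.evel)
    group.attrs["time_atu"] = state.time
    group.attrs["step"] = state.step_index
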