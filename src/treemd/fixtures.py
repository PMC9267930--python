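"""Deterministic synthetic test states.

Pure functions of their spec + seed: random plasmas at the benchmark
electron/atom composition (about 0.29 electrons and 0.21 ions per atom, the
ratio common to all five water presets), kept at water's atomic number
density so the physical neighbor density is size-independent — which is what
makes operation-count scaling measurements across a size ladder meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as C
from .particles import SystemState
from .rates import RateTables, default_tables
from .samplegen import ConfigurationError, assign_charges

#: atomic number density of liquid water [atoms/bohr³]
WATER_NUMBER_DENSITY = (3.0 * 0.997 * C.AVOGADRO / C.M_WATER_G_MOL) * C.BOHR_CM ** 3


@dataclass(frozen=True)
class PlasmaSpec:
    """Random-plasma fixture spec; fractions follow the water benchmarks."""
    n_atoms: int
    electron_fraction: float = 0.29
    ion_fraction: float = 0.21
    side_bohr: float | None = None      # default: water density
    electron_temperature_ev: float = 10.0
    atom_temperature_ev: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.ion_fraction <= 1 and 0 <= self.electron_fraction <= 1):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if self.n_atoms < 1:
            raise ConfigurationError("need at least one atom")


def make_plasma(spec: PlasmaSpec, tables: RateTables | None = None) -> SystemState:
    """Uniform positions, Maxwellian velocities, exact spec counts.

    Water stoichiometry (one O per two H); ion count round(ion_fraction·Na)
    with the minimal +1/+2 charge-state split totalling
    round(electron_fraction·Na) free electrons; byte-identical for equal
    (spec, seed).
    """
    tables = tables or default_tables()
    rng = np.random.default_rng(spec.seed)
    na = spec.n_atoms
    side = spec.side_bohr if spec.side_bohr is not None \
        else (na / WATER_NUMBER_DENSITY) ** (1.0 / 3.0)
    n_o = na // 3
    elem = np.full(na, tables.element_index("H"), dtype=np.int64)
    elem[:n_o] = tables.element_index("O")
    apos = rng.uniform(0.0, side, size=(na, 3))
    kt_atom = spec.atom_temperature_ev * C.EV_HARTREE
    masses = tables.mass_me[elem]
    avel = rng.normal(size=(na, 3)) * np.sqrt(kt_atom / masses)[:, None]
    state = SystemState(
        elem=elem, apos=apos, avel=avel,
        occ=tables.neutral_occ[elem].copy(),
        epos=np.zeros((0, 3)), evel=np.zeros((0, 3)), tables=tables,
    )
    n_ions = int(round(spec.ion_fraction * na))
    n_e = int(round(spec.electron_fraction * na))
    assign_charges(state, n_ions, n_e, rng)
    state.epos = rng.uniform(0.0, side, size=(n_e, 3))
    kt_e = spec.electron_temperature_ev * C.EV_HARTREE
    state.evel = rng.normal(scale=math.sqrt(kt_e), size=(n_e, 3))
    return state
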