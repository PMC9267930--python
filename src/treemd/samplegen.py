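"""Study-input builders: water cubes with optional pre-ionization.

A water cube of side L [Å] at density ρ [g/cm³] holds ⌊ρ·L³·N_A/M⌋ H₂O
units, placed on a jittered cubic lattice with the usual 0.96 Å / 104.5°
monomer geometry in random orientation and zero initial velocities.  When
exact target counts (atoms, ions, free electrons) are requested — as for the
packaged benchmark presets — the molecule count is trimmed/padded to hit the
atom count and the requested number of atoms is pre-ionized with the minimal
charge-state distribution (as many +1 as possible, the remainder +2) whose
stripped-electron total equals the free-electron count, so the net charge is
exactly zero.

The five packaged presets (47–150 Å) reproduce fixed (atoms&ions, ions,
electrons) triples at the common electron/atom composition of an X-ray
irradiated water benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as C
from .particles import SystemState
from .rates import RateTables, default_tables


class ConfigurationError(ValueError):
    """Infeasible sample targets."""


@dataclass(frozen=True)
class SampleSpec:
    """Water-cube specification; counts are optional exact targets."""
    side_angstrom: float
    density_g_cm3: float = 0.997
    n_atoms: int | None = None
    n_ions: int | None = None
    n_electrons: int | None = None
    electron_temperature_ev: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.side_angstrom <= 0:
            raise ValueError("cube side must be positive")
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")


#: benchmark presets: side [Å] -> (atoms&ions, ions of charge >= 1, electrons)
PRESETS: dict[str, tuple[float, int, int, int]] = {
    "47A": (47.0, 9722, 2102, 2806),
    "60A": (60.0, 20534, 4422, 5881),
    "75A": (75.0, 40358, 8717, 11603),
    "100A": (100.0, 97655, 21087, 28084),
    "150A": (150.0, 328475, 67828, 87369),
}


def molecule_count(side_angstrom: float, density_g_cm3: float = 0.997) -> int:
    """⌊ρ·V·N_A/M_water⌋ for a cube of the given side."""
    v_cm3 = (side_angstrom * 1e-8) ** 3
    return int(density_g_cm3 * v_cm3 * C.AVOGADRO / C.M_WATER_G_MOL)


_OH_ANGSTROM = 0.96
_HOH_DEG = 104.5
_JITTER_ANGSTROM = 0.25
_MARGIN_ANGSTROM = 1.3


def _water_geometry(n_mol: int, side: float, rng: np.random.Generator):
    """O and H positions [Å] for n_mol molecules on a jittered lattice."""
    m = max(1, math.ceil(n_mol ** (1.0 / 3.0)))
    while m ** 3 < n_mol:
        m += 1
    cells = np.arange(m ** 3)[:n_mol]
    ijk = np.stack([cells // (m * m), (cells // m) % m, cells % m], axis=1)
    span = side - 2.0 * _MARGIN_ANGSTROM
    if span <= 0:
        raise ConfigurationError("cube too small for a water lattice")
    o_pos = _MARGIN_ANGSTROM + (ijk + 0.5) / m * span
    o_pos = o_pos + rng.uniform(-_JITTER_ANGSTROM, _JITTER_ANGSTROM,
                                size=o_pos.shape)
    # random orientation: orthonormal bisector/in-plane pair per molecule
    a = rng.normal(size=(n_mol, 3))
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b = rng.normal(size=(n_mol, 3))
    b -= np.einsum("ij,ij->i", a, b)[:, None] * a
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    half = math.radians(_HOH_DEG / 2.0)
    h1 = o_pos + _OH_ANGSTROM * (math.cos(half) * a + math.sin(half) * b)
    h2 = o_pos + _OH_ANGSTROM * (math.cos(half) * a - math.sin(half) * b)
    return o_pos, h1, h2


def build_water_cube(spec: SampleSpec,
                     tables: RateTables | None = None) -> SystemState:
    """Neutral water cube; deterministic given the spec's seed.

    Without target counts the molecule number follows the density formula;
    with ``n_atoms`` set, ⌈n_atoms/3⌉ molecules are built and surplus
    hydrogens of the last molecule dropped.  ``pre_ionize`` is applied
    automatically when ion/electron targets are present.
    """
    tables = tables or default_tables()
    rng = np.random.default_rng(spec.seed)
    if spec.n_atoms is not None:
        n_mol = math.ceil(spec.n_atoms / 3)
        n_atoms = spec.n_atoms
    else:
        n_mol = molecule_count(spec.side_angstrom, spec.density_g_cm3)
        n_atoms = 3 * n_mol
    if n_mol < 1:
        raise ConfigurationError("cube holds no molecules")
    o_pos, h1, h2 = _water_geometry(n_mol, spec.side_angstrom, rng)
    # molecule-wise atom order O, H, H so trailing trims remove hydrogens
    pos = np.empty((3 * n_mol, 3))
    pos[0::3] = o_pos
    pos[1::3] = h1
    pos[2::3] = h2
    elem = np.empty(3 * n_mol, dtype=np.int64)
    i_h = tables.element_index("H")
    i_o = tables.element_index("O")
    elem[0::3] = i_o
    elem[1::3] = i_h
    elem[2::3] = i_h
    pos = pos[:n_atoms]
    elem = elem[:n_atoms]
    state = SystemState(
        elem=elem,
        apos=pos * C.ANGSTROM_BOHR,
        avel=np.zeros((n_atoms, 3)),
        occ=tables.neutral_occ[elem].copy(),
        epos=np.zeros((0, 3)),
        evel=np.zeros((0, 3)),
        tables=tables,
    )
    if spec.n_ions is not None or spec.n_electrons is not None:
        state = pre_ionize(state, spec, rng)
    return state


def assign_charges(state: SystemState, n_ions: int, n_electrons: int,
                   rng: np.random.Generator) -> None:
    """Strip electrons to make exactly n_ions ions summing to n_electrons.

    Minimal charge states: +2 on ``n_electrons − n_ions`` oxygens, +1 on the
    rest; stripping empties the lowest-binding occupied orbitals first.
    """
    tables = state.tables
    if n_ions < 0 or n_electrons < n_ions:
        raise ConfigurationError("need n_electrons >= n_ions >= 0")
    if n_electrons > 2 * n_ions:
        raise ConfigurationError("charge states above +2 not generated")
    if n_ions > state.n_atoms:
        raise ConfigurationError("more ions than atoms")
    n2 = n_electrons - n_ions
    i_o = tables.element_index("O")
    o_idx = np.flatnonzero(state.elem == i_o)
    if n2 > len(o_idx):
        raise ConfigurationError("not enough oxygens for +2 charge states")
    doubly = rng.choice(o_idx, size=n2, replace=False) if n2 else \
        np.empty(0, dtype=np.int64)
    rest = np.setdiff1d(np.arange(state.n_atoms), doubly, assume_unique=False)
    singly = rng.choice(rest, size=n_ions - n2, replace=False) \
        if n_ions - n2 else np.empty(0, dtype=np.int64)
    for idx, q in ((doubly, 2), (singly, 1)):
        for a in idx:
            left = q
            j = tables.n_orbitals[state.elem[a]] - 1
            while left > 0:
                take = min(left, state.occ[a, j])
                state.occ[a, j] -= take
                left -= take
                j -= 1


def pre_ionize(state: SystemState, spec: SampleSpec,
               rng: np.random.Generator | None = None) -> SystemState:
    """Apply the spec's ion/electron targets to a neutral state.

    Exactly ``n_ions`` atoms receive charge ≥ 1 with stripped-electron total
    ``n_electrons``; that many free electrons are placed uniformly in the
    cube with Maxwellian speeds at the configured temperature.  Net charge is
    zero by construction.  Deterministic given the RNG state.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_ions = spec.n_ions or 0
    n_electrons = spec.n_electrons or 0
    assign_charges(state, n_ions, n_electrons, rng)
    side_bohr = spec.side_angstrom * C.ANGSTROM_BOHR
    state.epos = rng.uniform(0.0, side_bohr, size=(n_electrons, 3))
    kt_ha = spec.electron_temperature_ev * C.EV_HARTREE
    state.evel = rng.normal(scale=math.sqrt(kt_ha), size=(n_electrons, 3))
    return state


def build_preset(name: str, seed: int = 0,
                 electron_temperature_ev: float = 10.0,
                 tables: RateTables | None = None) -> SystemState:
    """Build one of the packaged benchmark presets (47A/60A/75A/100A/150A)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    side, na, ni, ne = PRESETS[name]
    spec = SampleSpec(side_angstrom=side, n_atoms=na, n_ions=ni,
                      n_electrons=ne, seed=seed,
                      electron_temperature_ev=electron_temperature_ev)
    return build_water_cube(spec, tables=tables)
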