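"""Stochastic atomic processes: photoionization, Auger decay, fluorescence.

Each timestep, every atom draws exactly one uniform random number from the
global Monte-Carlo stream (in ascending atom-index order — a single
vectorized draw).  The number selects among the atom's open channels by
cumulative probability: per-orbital photoionization (σ_ph · flux · dt,
weighted by the current occupation), then Auger decay and fluorescence of a
deepest-orbital hole (Γ · n_holes · dt).  At most one event per atom per
step; a draw beyond the cumulative total means no event.

Emission directions and photoelectron kinematics come from a per-event
derived RNG keyed by (seed, step, atom index), so the global stream's
consumption is independent of outcomes and of the solver configuration —
which is what makes cross-solver trajectories comparable draw for draw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import constants as C
from .particles import BookkeepingError, SystemState
from .rates import RateTables


class TimestepTooLargeError(ValueError):
    """Per-atom event probability exceeded 1 within one step."""


@dataclass(frozen=True)
class PulseConfig:
    """Gaussian X-ray pulse envelope.

    photon_energy_ev: default 7120 (7.12 keV); fluence: time-integrated
    photons/μm² (default 3.5e12); fwhm_fs: temporal FWHM (default 15 fs);
    t0_fs: pulse-center time — simulations conventionally start there.
    """
    photon_energy_ev: float = 7120.0
    fluence_per_um2: float = 3.5e12
    fwhm_fs: float = 15.0
    t0_fs: float = 0.0

    def __post_init__(self):
        if self.fluence_per_um2 < 0 or self.fwhm_fs <= 0:
            raise ValueError("fluence must be >= 0 and fwhm > 0")


def gaussian_flux(t_fs, pulse: PulseConfig):
    """Instantaneous flux [photons/(μm²·fs)] at time t [fs].

    Normalized Gaussian: the time integral equals the fluence, and the flux
    falls to half its peak at t0 ± fwhm/2.
    """
    t = np.asarray(t_fs, dtype=float)
    ln2 = math.log(2.0)
    peak = pulse.fluence_per_um2 * 2.0 * math.sqrt(ln2 / math.pi) / pulse.fwhm_fs
    return peak * np.exp(-4.0 * ln2 * (t - pulse.t0_fs) ** 2 / pulse.fwhm_fs ** 2)


@dataclass(frozen=True)
class AtomicEvent:
    """One sampled event: kind in {'photo', 'auger', 'fluor'}."""
    kind: str
    atom: int
    orbital: int
    step: int


def channel_probabilities(state: SystemState, tables: RateTables,
                          pulse: PulseConfig, dt: float) -> np.ndarray:
    """Per-atom channel probability matrix for one step of length dt [a.t.u.].

    Columns: one photoionization channel per orbital, then Auger, then
    fluorescence.  Channels of empty orbitals carry zero probability.
    """
    elem = state.elem
    occ = state.occ
    t_fs = state.time * C.ATU_FS
    flux_au = (gaussian_flux(t_fs, pulse)
               * C.PER_UM2_TO_PER_BOHR2 * C.ATU_FS)   # photons/(bohr²·a.t.u.)
    sig = tables.sigma_ph_bohr2[elem]
    neutral = tables.neutral_occ[elem]
    ratio = np.divide(occ, neutral, out=np.zeros(occ.shape), where=neutral > 0)
    open_ph = (tables.binding_ev[elem] < pulse.photon_energy_ev) \
        & tables.orbital_mask()[elem] & (occ > 0)
    p_ph = sig * ratio * flux_au * dt * open_ph
    dt_fs = dt * C.ATU_FS
    holes0 = (tables.capacity[elem, 0] - occ[:, 0]).astype(float)
    outer = occ[:, 1:].sum(axis=1)
    p_aug = tables.auger_rate_per_fs[elem] * holes0 * dt_fs * (outer >= 2)
    p_flu = tables.fluor_rate_per_fs[elem] * holes0 * dt_fs * (outer >= 1)
    return np.column_stack([p_ph, p_aug, p_flu])


def sample_events(state: SystemState, tables: RateTables, pulse: PulseConfig,
                  dt: float, rng: np.random.Generator,
                  step: int | None = None) -> list[AtomicEvent]:
    """Draw one uniform per atom (ascending order) and select events.

    Raises :class:`TimestepTooLargeError` if any atom's total probability
    exceeds 1; warns above 0.1.
    """
    step = state.step_index if step is None else step
    probs = channel_probabilities(state, tables, pulse, dt)
    cum = np.cumsum(probs, axis=1)
    total = cum[:, -1] if cum.shape[1] else np.zeros(state.n_atoms)
    if np.any(total > 1.0):
        raise TimestepTooLargeError(
            f"per-atom event probability up to {total.max():.3g} > 1")
    if np.any(total > 0.1):
        warnings.warn(f"per-atom event probability up to {total.max():.3g} "
                      "> 0.1; consider a smaller timestep", stacklevel=2)
    u = rng.random(state.n_atoms)
    ch = (u[:, None] >= cum).sum(axis=1)
    nch = probs.shape[1]
    n_orb = tables.capacity.shape[1]
    events = []
    for atom in np.flatnonzero(ch < nch):
        c = int(ch[atom])
        if c < n_orb:
            events.append(AtomicEvent("photo", int(atom), c, step))
        elif c == n_orb:
            events.append(AtomicEvent("auger", int(atom), 0, step))
        else:
            events.append(AtomicEvent("fluor", int(atom), 0, step))
    return events


def _isotropic_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n == 0.0:            # pragma: no cover - measure-zero draw
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


_EMISSION_OFFSET = 0.5  # bohr; keeps new electrons off the parent singularity


def _emit_electron(state: SystemState, atom: int, ke_ha: float,
                   rng: np.random.Generator) -> None:
    direction = _isotropic_direction(rng)
    speed = math.sqrt(max(2.0 * ke_ha, 0.0))
    pos = state.apos[atom] + _EMISSION_OFFSET * direction
    vel = state.avel[atom] + speed * direction
    state.epos = np.concatenate([state.epos, pos[None, :]], axis=0)
    state.evel = np.concatenate([state.evel, vel[None, :]], axis=0)


def _outermost_occupied(state: SystemState, tables: RateTables, atom: int) -> int:
    occ = state.occ[atom]
    for j in range(tables.n_orbitals[state.elem[atom]] - 1, -1, -1):
        if occ[j] > 0:
            return j
    raise BookkeepingError(f"atom {atom} has no bound electrons left")


def apply_event(state: SystemState, event: AtomicEvent, pulse: PulseConfig,
                tables: RateTables, rng: np.random.Generator) -> None:
    """Apply one sampled event to the state (occupations, charge, electrons).

    Photoionization: the orbital loses one electron, the atom's charge rises
    by one, and a free electron is created with KE = photon energy − binding.
    Auger: the deepest hole is filled from the outermost occupied orbital and
    a second outer electron is emitted with the tabulated Auger energy.
    Fluorescence: the hole moves outward; no classical particle is created.
    Every branch conserves total charge (ions minus free electrons).
    """
    atom = event.atom
    e = state.elem[atom]
    if event.kind == "photo":
        if state.occ[atom, event.orbital] < 1:
            raise BookkeepingError(
                f"photoionization of empty orbital {event.orbital} on atom {atom}")
        state.occ[atom, event.orbital] -= 1
        ke = (pulse.photon_energy_ev - tables.binding_ev[e, event.orbital]) \
            * C.EV_HARTREE
        _emit_electron(state, atom, ke, rng)
    elif event.kind == "auger":
        if state.occ[atom, 0] >= tables.capacity[e, 0]:
            raise BookkeepingError(f"Auger decay without a core hole on atom {atom}")
        j = _outermost_occupied(state, tables, atom)
        if j == 0:
            raise BookkeepingError(f"Auger decay with no outer electrons on atom {atom}")
        state.occ[atom, j] -= 1
        state.occ[atom, 0] += 1
        j2 = _outermost_occupied(state, tables, atom)
        if j2 == 0:
            raise BookkeepingError(f"Auger emission with no outer electrons on atom {atom}")
        state.occ[atom, j2] -= 1
        _emit_electron(state, atom, tables.auger_energy_ev[e] * C.EV_HARTREE, rng)
    elif event.kind == "fluor":
        if state.occ[atom, 0] >= tables.capacity[e, 0]:
            raise BookkeepingError(f"fluorescence without a core hole on atom {atom}")
        j = _outermost_occupied(state, tables, atom)
        if j == 0:
            raise BookkeepingError(f"fluorescence with no outer electrons on atom {atom}")
        state.occ[atom, j] -= 1
        state.occ[atom, 0] += 1
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")


def mc_block(state: SystemState, tables: RateTables, pulse: PulseConfig,
             dt: float, rng: np.random.Generator, seed: int,
             step: int | None = None) -> list[AtomicEvent]:
    """Sample and apply this step's atomic events.

    *rng* is the global MC stream (one uniform per atom per step); per-event
    kinematics use generators derived from (seed, step, atom).
    """
    step = state.step_index if step is None else step
    events = sample_events(state, tables, pulse, dt, rng, step)
    for ev in events:
        ev_rng = np.random.default_rng([seed & 0x7FFFFFFF, 104729, step, ev.atom])
        apply_event(state, ev, pulse, tables, ev_rng)
    return events
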