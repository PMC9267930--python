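"""Real-space propagation: velocity Verlet.

The symplectic two-kick form: x advances by v·dt + a·dt²/2, accelerations are
recomputed at the new positions, and v receives the average of old and new
accelerations.  Only one fresh force evaluation is needed per step; the
caller may pass the accelerations cached from the previous step's second
evaluation (event blocks that mutate the particle lists invalidate that
cache).  Neutral atoms feel no Coulomb force but still drift ballistically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .particles import SystemState


class PropagationError(RuntimeError):
    """Non-finite forces fed to the integrator."""


@dataclass(frozen=True)
class IntegratorConfig:
    """dt in atomic time units; the default is 1 attosecond."""
    dt: float = C.AS_ATU

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _check_finite(acc: np.ndarray, label: str) -> None:
    if not np.all(np.isfinite(acc)):
        bad = int(np.flatnonzero(~np.all(np.isfinite(acc), axis=1))[0])
        raise PropagationError(f"non-finite force on {label} {bad}")


def velocity_verlet_step(state: SystemState, dt: float, force_provider,
                         accel=None):
    """Advance all classical particles by one step of velocity Verlet.

    *force_provider(state)* must return per-particle accelerations
    ``(a_atoms (Na,3), a_electrons (Ne,3))`` [hartree/(bohr·m)].  *accel* may
    carry the accelerations already valid for the current positions; when
    omitted they are computed afresh.  Returns the accelerations at the new
    positions for reuse by the next step.  The state is updated in place.
    """
    if accel is None:
        accel = force_provider(state)
    aa, ae = accel
    _check_finite(aa, "atom")
    _check_finite(ae, "electron")
    state.apos += state.avel * dt + 0.5 * aa * dt * dt
    state.epos += state.evel * dt + 0.5 * ae * dt * dt
    aa2, ae2 = force_provider(state)
    _check_finite(aa2, "atom")
    _check_finite(ae2, "electron")
    state.avel += 0.5 * (aa + aa2) * dt
    state.evel += 0.5 * (ae + ae2) * dt
    state.time += dt
    return aa2, ae2


def total_momentum(state: SystemState) -> np.ndarray:
    """Sum of m·v over all classical particles [m_e·bohr/a.t.u.]."""
    return (state.masses[:, None] * state.avel).sum(axis=0) + state.evel.sum(axis=0)
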