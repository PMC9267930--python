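"""Main time loop: RE → SI → MC → MD, once per timestep.

Each cycle first lets electrons recombine, then checks for impact
ionization, then samples photoionization/decay events from the pulse
envelope, and finally propagates every classical particle by one velocity
Verlet step.  All event-block mutations happen between MD steps, never mid
step; the MD force evaluation of a step therefore sees all particles the
step's events created.  One seeded global RNG stream drives the MC block
(one uniform per atom per step); SI/MC per-event kinematics use derived
streams keyed by (seed, step, particle), so swapping any solver
implementation never shifts random-number consumption — two runs with the
same seed and the same physics are byte-identical, whichever solvers they
use for the searches.

Per-step diagnostics record particle counts, event counts, energies (the
O(N²) potential energy only at a configurable cadence) and the
pair-evaluation counters that stand in for wall-clock cost as a
hardware-independent complexity measure.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from . import coulomb as _coulomb
from .mc_events import PulseConfig, mc_block
from .octree import QueryCounters
from .particles import (SystemState, charged_particles, kinetic_energy,
                        potential_energy, total_charge, write_hdf5_frame,
                        write_xyz)
from .rates import RateTables, default_tables
from .recombination import REConfig, re_block
from .secondary_ionization import SIConfig, si_block


@dataclass(frozen=True)
class SimulationConfig:
    n_steps: int = 100
    dt: float = C.AS_ATU
    pulse: PulseConfig = field(default_factory=PulseConfig)
    coulomb: _coulomb.SolverConfig = field(
        default_factory=lambda: _coulomb.SolverConfig(softening=0.05))
    si: SIConfig = field(default_factory=SIConfig)
    re: REConfig = field(default_factory=REConfig)
    seed: int = 0
    snapshot_every: int = 0     # 0 disables trajectory frames
    energy_every: int = 0       # 0 disables the O(N²) potential-energy ledger


def _force_provider(config: SimulationConfig, counter: _coulomb.PairCounter):
    def provider(state: SystemState):
        aa = np.zeros_like(state.apos)
        ae = np.zeros_like(state.epos)
        pos, q, _, mass, ion_idx = charged_particles(state)
        if len(q) >= 2:
            F, _ = _coulomb.forces(pos, q, config.coulomb, counter)
            acc = F / mass[:, None]
            aa[ion_idx] = acc[: len(ion_idx)]
            ae[:] = acc[len(ion_idx):]
        return aa, ae
    return provider


@dataclass
class StepRecord:
    step: int
    time_fs: float
    n_atoms: int
    n_ions: int
    n_electrons: int
    n_charged: int
    events_re: int
    events_si: int
    events_mc: int
    count_coulomb: int
    count_si: int
    count_re: int
    kinetic_ha: float
    potential_ha: float
    total_charge: int
    wall_s: float


def step(state: SystemState, config: SimulationConfig,
         rng: np.random.Generator, tables: RateTables | None = None,
         accel=None):
    """Execute RE, SI, MC, MD in order; advance time by dt.

    Returns ``(record, events, accel)`` where *accel* carries the MD block's
    final accelerations for reuse when no event mutates the particle lists.
    """
    tables = tables or state.tables
    t_start = _time.perf_counter()
    re_ctr, si_ctr = QueryCounters(), QueryCounters()
    ev_re, _, _ = re_block(state, config.re, tables, counters=re_ctr)
    ev_si, _ = si_block(state, config.si, tables, seed=config.seed,
                        counters=si_ctr)
    ev_mc = mc_block(state, tables, config.pulse, config.dt, rng,
                     seed=config.seed)
    mutated = bool(ev_re or ev_si or ev_mc)
    if mutated:
        accel = None
    cou_ctr = _coulomb.PairCounter()
    provider = _force_provider(config, cou_ctr)
    from .md import velocity_verlet_step
    accel = velocity_verlet_step(state, config.dt, provider, accel=accel)
    state.step_index += 1
    pe = np.nan
    if config.energy_every and state.step_index % config.energy_every == 0:
        pe = potential_energy(state, config.coulomb.softening)
    rec = StepRecord(
        step=state.step_index,
        time_fs=state.time * C.ATU_FS,
        n_atoms=state.n_atoms, n_ions=state.n_ions,
        n_electrons=state.n_electrons, n_charged=state.n_charged,
        events_re=len(ev_re), events_si=len(ev_si), events_mc=len(ev_mc),
        count_coulomb=cou_ctr.count, count_si=si_ctr.total,
        count_re=re_ctr.total,
        kinetic_ha=kinetic_energy(state), potential_ha=pe,
        total_charge=total_charge(state),
        wall_s=_time.perf_counter() - t_start,
    )
    return rec, (ev_re, ev_si, ev_mc), accel


def run(config: SimulationConfig, state: SystemState,
        output_dir=None, tables: RateTables | None = None):
    """Run ``n_steps`` cycles; returns ``(state, diagnostics, event_log)``.

    *diagnostics* is a per-step DataFrame; *event_log* a list of
    (step, block, payload) tuples.  With *output_dir* set, writes an HDF5
    trajectory, extended-XYZ snapshots at the snapshot cadence, TSV
    event/diagnostic tables and a JSON run manifest.
    """
    tables = tables or state.tables
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    records: list[StepRecord] = []
    event_log: list[tuple] = []
    accel = None
    h5 = None
    if output_dir is not None:
        import os
        os.makedirs(output_dir, exist_ok=True)
        if config.snapshot_every:
            import h5py
            h5 = h5py.File(f"{output_dir}/trajectory.h5", "w")
    try:
        for _ in range(config.n_steps):
            rec, (ev_re, ev_si, ev_mc), accel = step(
                state, config, rng, tables, accel)
            records.append(rec)
            for ev in ev_re:
                event_log.append((rec.step, "re", ev))
            for ev in ev_si:
                event_log.append((rec.step, "si", ev))
            for ev in ev_mc:
                event_log.append((rec.step, "mc", ev))
            if output_dir is not None and config.snapshot_every and \
                    rec.step % config.snapshot_every == 0:
                if h5 is not None:
                    write_hdf5_frame(h5.create_group(f"step_{rec.step:07d}"),
                                     state)
                write_xyz(state, f"{output_dir}/snapshot_{rec.step:07d}.xyz")
    finally:
        if h5 is not None:
            h5.close()
    diag = pd.DataFrame([asdict(r) for r in records])
    if output_dir is not None:
        diag.to_csv(f"{output_dir}/diagnostics.tsv", sep="\t", index=False)
        with open(f"{output_dir}/events.tsv", "w") as fh:
            fh.write("step\tblock\telectron\tatom\torbital\tkind\n")
            for s, block, ev in event_log:
                if block == "re":
                    fh.write(f"{s}\tre\t{ev.electron}\t{ev.ion}\t{ev.orbital}\t-\n")
                elif block == "si":
                    fh.write(f"{s}\tsi\t{ev.electron}\t{ev.atom}\t{ev.orbital}\t-\n")
                else:
                    fh.write(f"{s}\tmc\t-\t{ev.atom}\t{ev.orbital}\t{ev.kind}\n")
        manifest = {
            "n_steps": config.n_steps, "dt_atu": config.dt,
            "seed": config.seed,
            "pulse": asdict(config.pulse),
            "coulomb": asdict(config.coulomb),
            "si": asdict(config.si), "re": asdict(config.re),
        }
        with open(f"{output_dir}/manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return state, diag, event_log


# -- hardware-independent complexity measurement ------------------------------

def block_counts(state: SystemState, coulomb_cfg: _coulomb.SolverConfig,
                 si_cfg: SIConfig, re_cfg: REConfig, seed: int = 0) -> dict:
    """Pair-evaluation counts for one evaluation of each block on *state*.

    The SI/RE blocks run on copies so the probe leaves the state untouched.
    These per-evaluation counts are the measurable proxy for per-step cost:
    the MD block performs a fixed small number of force evaluations per step,
    so fitted scaling slopes are unaffected.
    """
    ctr = _coulomb.PairCounter()
    pos, q, _, _, _ = charged_particles(state)
    if len(q) >= 2:
        _coulomb.forces(pos, q, coulomb_cfg, ctr)
    si_ctr, re_ctr = QueryCounters(), QueryCounters()
    si_block(state.copy(), si_cfg, state.tables, seed=seed, counters=si_ctr)
    re_block(state.copy(), re_cfg, state.tables, counters=re_ctr)
    return {
        "n": state.n_atoms, "nq": len(q),
        "ne": state.n_electrons, "ni": state.n_ions,
        "coulomb": ctr.count, "si": si_ctr.total, "re": re_ctr.total,
        "total": ctr.count + si_ctr.total + re_ctr.total,
    }


def fit_loglog_slope(ns, counts) -> float:
    """Least-squares slope of log(count) versus log(N)."""
    ns = np.asarray(ns, dtype=float)
    counts = np.asarray(counts, dtype=float)
    return float(np.polyfit(np.log(ns), np.log(counts), 1)[0])
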