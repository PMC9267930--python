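"""Per-element atomic data: orbitals, cross sections, decay rates.

The electronic structure of each species is a flat list of orbitals with
capacities, neutral occupations and binding energies.  Photoionization cross
sections, core-hole decay rates and the impact-ionization model constant live
in the same table.  The packaged default (``data/rate_tables.yaml``) covers H
and O, which is all a water study needs; any YAML file with the same schema
can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from . import constants as C


@dataclass(frozen=True)
class RateTables:
    """Array-packed per-element atomic data.

    All 2-d arrays are shaped ``(n_elements, max_orbitals)`` and padded with
    zeros beyond ``n_orbitals[e]``.  Orbitals are ordered deepest (largest
    binding energy) first.
    """

    elements: tuple[str, ...]
    mass_me: np.ndarray            # (E,) atomic masses [electron masses]
    n_orbitals: np.ndarray         # (E,)
    capacity: np.ndarray           # (E, O) int
    neutral_occ: np.ndarray        # (E, O) int
    binding_ev: np.ndarray         # (E, O) float
    sigma_ph_mb: np.ndarray        # (E, O) float, at the configured photon energy
    auger_rate_per_fs: np.ndarray  # (E,) decay rate of a deepest-orbital hole
    fluor_rate_per_fs: np.ndarray  # (E,)
    auger_energy_ev: np.ndarray    # (E,)
    lotz_a_mb_ev2: float           # impact-ionization model constant

    # -- derived conveniences -------------------------------------------------
    def element_index(self, symbol: str) -> int:
        return self.elements.index(symbol)

    @property
    def binding_ha(self) -> np.ndarray:
        return self.binding_ev * C.EV_HARTREE

    @property
    def sigma_ph_bohr2(self) -> np.ndarray:
        return self.sigma_ph_mb * C.MBARN_BOHR2

    def orbital_mask(self) -> np.ndarray:
        """Boolean (E, O) mask of real (non-padding) orbitals."""
        o = np.arange(self.capacity.shape[1])
        return o[None, :] < self.n_orbitals[:, None]

    @classmethod
    def from_dict(cls, d: dict) -> "RateTables":
        elems = tuple(d["elements"].keys())
        n_e = len(elems)
        n_o = max(len(v["orbitals"]) for v in d["elements"].values())
        cap = np.zeros((n_e, n_o), dtype=np.int64)
        occ = np.zeros((n_e, n_o), dtype=np.int64)
        be = np.zeros((n_e, n_o))
        sig = np.zeros((n_e, n_o))
        mass = np.zeros(n_e)
        norb = np.zeros(n_e, dtype=np.int64)
        aug = np.zeros(n_e)
        flu = np.zeros(n_e)
        aen = np.zeros(n_e)
        for i, sym in enumerate(elems):
            ed = d["elements"][sym]
            mass[i] = ed["mass_amu"] * C.AMU_ME
            orbs = ed["orbitals"]
            norb[i] = len(orbs)
            for j, ob in enumerate(orbs):
                cap[i, j] = ob["capacity"]
                occ[i, j] = ob["occupation"]
                be[i, j] = ob["binding_ev"]
                sig[i, j] = ob["sigma_ph_mb"]
            aug[i] = ed.get("auger_rate_per_fs", 0.0)
            flu[i] = ed.get("fluor_rate_per_fs", 0.0)
            aen[i] = ed.get("auger_energy_ev", 0.0)
        for i in range(n_e):
            b = be[i, : norb[i]]
            if not np.all(np.diff(b) <= 0):
                raise ValueError(f"orbitals of {elems[i]} must be ordered deepest first")
        if np.any(cap < occ):
            raise ValueError("neutral occupation exceeds orbital capacity")
        if np.any(be < 0) or np.any(sig < 0) or np.any(aug < 0) or np.any(flu < 0):
            raise ValueError("rate-table entries must be nonnegative")
        return cls(
            elements=elems, mass_me=mass, n_orbitals=norb, capacity=cap,
            neutral_occ=occ, binding_ev=be, sigma_ph_mb=sig,
            auger_rate_per_fs=aug, fluor_rate_per_fs=flu, auger_energy_ev=aen,
            lotz_a_mb_ev2=float(d["impact_ionization"]["lotz_a_mb_ev2"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "RateTables":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "RateTables":
        text = resources.files("treemd.data").joinpath("rate_tables.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


_DEFAULT: RateTables | None = None


def default_tables() -> RateTables:
    """Cached packaged H/O toy tables."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = RateTables.default()
    return _DEFAULT
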