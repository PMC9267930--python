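"""Unit system and physical constants.

All internal math is done in Hartree atomic units: length in bohr, energy in
hartree, mass in electron masses, time in ``hbar/E_h`` (1 a.t.u. = 24.188843
attoseconds).  In these units Coulomb's law carries no prefactor.  Configuration
and reports use the field's customary units (Å, eV, fs, attoseconds, Mbarn,
photons/μm²); the conversion constants below are the only place where the two
systems meet.
"""

import numpy as np

# CODATA 2018
BOHR_ANGSTROM = 0.529177210903          # 1 bohr in Å
ANGSTROM_BOHR = 1.0 / BOHR_ANGSTROM
HARTREE_EV = 27.211386245988            # 1 hartree in eV
EV_HARTREE = 1.0 / HARTREE_EV
ATU_FS = 2.4188843265857e-2             # 1 atomic time unit in fs
FS_ATU = 1.0 / ATU_FS
AS_ATU = 1.0e-3 * FS_ATU                # 1 attosecond in a.t.u. (~0.041341)
AMU_ME = 1822.888486209                 # 1 unified amu in electron masses
AVOGADRO = 6.02214076e23

# cross sections / fluence
MBARN_CM2 = 1.0e-18
BOHR_CM = BOHR_ANGSTROM * 1.0e-8
MBARN_BOHR2 = MBARN_CM2 / BOHR_CM**2    # 1 Mbarn in bohr² (~0.0357106)
UM_BOHR = 1.0e4 * ANGSTROM_BOHR         # 1 μm in bohr
PER_UM2_TO_PER_BOHR2 = 1.0 / UM_BOHR**2  # photons/μm² -> photons/bohr²

M_WATER_G_MOL = 18.01528


def angstrom_to_bohr(x):
    return np.asarray(x, dtype=float) * ANGSTROM_BOHR


def bohr_to_angstrom(x):
    return np.asarray(x, dtype=float) * BOHR_ANGSTROM


def ev_to_hartree(e):
    return np.asarray(e, dtype=float) * EV_HARTREE


def hartree_to_ev(e):
    return np.asarray(e, dtype=float) * HARTREE_EV


def fs_to_atu(t):
    return np.asarray(t, dtype=float) * FS_ATU


def atu_to_fs(t):
    return np.asarray(t, dtype=float) * ATU_FS


# velocity: Å/fs -> bohr/a.t.u.
ANGFS_TO_AU = ANGSTROM_BOHR * ATU_FS
AU_TO_ANGFS = 1.0 / ANGFS_TO_AU
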