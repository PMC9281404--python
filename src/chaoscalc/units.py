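"""Unit conversions used throughout the package.

Internal conventions: pressures in bar, lengths in nm, areas in nm^2,
tensions in mN/m (with bar*nm as the raw pressure-tensor scale), energies
in kJ/mol *per molecule of interest* (molar energies, as customary for
free-energy calculations).
"""

from __future__ import annotations

#: Avogadro constant, 1/mol (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: 1 bar*nm = 1e5 Pa * 1e-9 m = 1e-4 N/m = 0.1 mN/m.
BAR_NM_TO_MN_PER_M = 0.1

#: 1 mN/m * nm^2 = 1e-21 J; times N_A and /1000 -> kJ/mol.
MN_PER_M_NM2_TO_KJ_PER_MOL = 1e-21 * AVOGADRO / 1e3  # 0.60221408 kJ/mol

#: 1 mN/m expressed as an energy density kJ/mol per nm^2 (same constant).
MN_PER_M_TO_KJ_PER_MOL_NM2 = MN_PER_M_NM2_TO_KJ_PER_MOL

#: 1 bar*nm^3 = 1e-22 J -> kJ/mol.
BAR_NM3_TO_KJ_PER_MOL = 1e-22 * AVOGADRO / 1e3  # 0.060221408


def bar_nm_to_mn_per_m(sigma_bar_nm):
    """Convert a tension from bar*nm to mN/m."""
    return sigma_bar_nm * BAR_NM_TO_MN_PER_M


def mn_per_m_to_bar_nm(sigma_mn_per_m):
    """Convert a tension from mN/m to bar*nm."""
    return sigma_mn_per_m / BAR_NM_TO_MN_PER_M


def mech_work_to_kj_per_mol(work_mn_per_m_nm2):
    """Convert mechanical work (tension * area, mN/m * nm^2) to kJ/mol."""
    return work_mn_per_m_nm2 * MN_PER_M_NM2_TO_KJ_PER_MOL


def tension_to_energy_density(sigma_mn_per_m):
    """Convert a tension (mN/m) to an energy density (kJ/mol/nm^2)."""
    return sigma_mn_per_m * MN_PER_M_TO_KJ_PER_MOL_NM2
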