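"""Physical constants and unit conversions.

Internal simulation units are angstrom (length), kJ/mol (energy) and
picosecond (time); forces are reported in pN and extensions in nm at the
interfaces.  All conversion factors are derived from CODATA values in
:mod:`scipy.constants` so they stay mutually consistent.
"""

from __future__ import annotations

import scipy.constants as _sc

#: Avogadro constant, 1/mol.
N_AVOGADRO: float = _sc.N_A

#: Molar gas constant in kJ/(mol K).
R_KJ_MOL_K: float = _sc.R * 1e-3

#: One kJ mol^-1 A^-1 expressed in pN (~16.61 pN).
KJ_MOL_ANG_TO_PN: float = 1e3 / _sc.N_A / 1e-10 * 1e12

#: One pN expressed in kJ mol^-1 A^-1.
PN_TO_KJ_MOL_ANG: float = 1.0 / KJ_MOL_ANG_TO_PN

#: One N/m expressed in kJ mol^-1 A^-2 (spring constants).
N_PER_M_TO_KJ_MOL_ANG2: float = _sc.N_A * 1e-3 * 1e-20

ANG_PER_NM = 10.0
PS_PER_S = 1e12


def thermal_energy(temperature_k: float) -> float:
    """k_B T in kJ/mol at the given temperature."""
    return R_KJ_MOL_K * temperature_k


def stokes_friction(viscosity_pa_s: float, bead_radius_ang: float) -> float:
    """Stokes friction gamma = 6 pi eta a in kJ mol^-1 ps A^-2.

    For water viscosity (1e-3 Pa s) and a 3.8 A bead this is about
    43 kJ mol^-1 ps A^-2, i.e. a free-bead diffusivity k_B T / gamma of
    roughly 0.06 A^2/ps at 298 K.
    """
    gamma_si = 6.0 * _sc.pi * viscosity_pa_s * bead_radius_ang * 1e-10  # kg/s
    # kg/s = J s / m^2; convert J->kJ/mol, m^2->A^2, s->ps
    return gamma_si * _sc.N_A * 1e-3 * 1e-20 * 1e12


def speed_um_s_to_ang_ps(speed_um_s: float) -> float:
    """Pulling speed, um/s -> A/ps (1 um/s = 1e-8 A/ps)."""
    return speed_um_s * 1e4 / PS_PER_S


def spring_pn_nm_to_internal(k_pn_nm: float) -> float:
    """Cantilever spring constant, pN/nm -> kJ mol^-1 A^-2."""
    return k_pn_nm * PN_TO_KJ_MOL_ANG / ANG_PER_NM
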