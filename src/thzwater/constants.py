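"""Unit system and physical constants.

Internal units are Angstrom (length), picosecond (time), elementary charge
(charge), Debye (dipole moment) and Kelvin (temperature).  Spectra are
reported on a wavenumber grid in cm^-1 and the absorption coefficient
(times the real refractive index) alpha*n' in cm^-1.

Electric fields follow the Gaussian-style convention E = q / r^2 in units of
e/A^2, so that an isotropic polarizability alpha in A^3 yields an induced
dipole mu = alpha * E in e*A.  Conversion to Debye happens at module
boundaries via :data:`EA_TO_DEBYE`.
"""

from __future__ import annotations

import scipy.constants as _sc

#: 1 e*Angstrom expressed in Debye.
EA_TO_DEBYE = 4.80321

#: 1 Debye in Coulomb*metre.
DEBYE_SI = 1e-21 / _sc.c  # = 3.33564e-30 C m

#: Speed of light in cm/ps (wavenumber <-> angular frequency conversions).
C_CM_PER_PS = _sc.c * 1e2 * 1e-12  # 0.0299792458

#: Prefactor K such that  eps(omega) - eps_inf = K / (V[A^3] T[K]) * X[D^2]
#: where X = <M_D^2> + i omega Integral(Phi_D e^{-i omega t}) in D^2 with
#: omega in rad/ps and t in ps.  K = D^2 / (3 * 1e-30 m^3 * k_B * eps0).
EPS_PREFACTOR = DEBYE_SI**2 / (3.0 * 1e-30 * _sc.k * _sc.epsilon_0)  # ~30338.6 K A^3 / D^2


def omega_from_wavenumber(nu_cm: float) -> float:
    """Angular frequency in rad/ps for a wavenumber in cm^-1."""
    return 2.0 * _sc.pi * C_CM_PER_PS * nu_cm


def wavenumber_from_omega(omega: float) -> float:
    """Wavenumber in cm^-1 for an angular frequency in rad/ps."""
    return omega / (2.0 * _sc.pi * C_CM_PER_PS)
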