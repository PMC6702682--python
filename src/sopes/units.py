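"""Physical constants and unit conversions.

All energies inside the package are wavenumbers (cm^-1). Toy surfaces use a
natural unit system with hbar = 1 in which energies are cm^-1, coordinates
are dimensionless and the unit of mass is chosen such that the kinetic term
(1/2m) d^2/dq^2 is also in cm^-1; a 1D oscillator V = a q^2 / 2 with unit
mass then has harmonic frequency sqrt(a) cm^-1.  Conversion factors below
are derived from scipy's CODATA tables at import time and frozen into the
module namespace.
"""

import math

import scipy.constants as _c

#: cm^-1 per hartree
CM1_PER_HARTREE: float = _c.physical_constants["hartree-inverse meter relationship"][0] / 100.0

#: cm^-1 per kcal/mol (thermochemical calorie)
CM1_PER_KCALMOL: float = _c.calorie * 1000.0 / _c.N_A / (_c.h * _c.c * 100.0)

#: cm^-1 per eV
CM1_PER_EV: float = _c.physical_constants["electron volt-inverse meter relationship"][0] / 100.0

#: fs per natural time unit of the cm^-1 / hbar=1 system, i.e. 1/(2 pi c * 1 cm^-1)
NATURAL_TIME_FS: float = 1.0e15 / (2.0 * math.pi * _c.c * 100.0)

#: frequency conversion for a mass-weighted Hessian in hartree / (bohr^2 amu):
#: nu[cm^-1] = AU_AMU_FREQ_CM1 * sqrt(lambda)
AU_AMU_FREQ_CM1: float = (
    math.sqrt(
        _c.physical_constants["Hartree energy"][0]
        / (_c.physical_constants["atomic mass constant"][0]
           * _c.physical_constants["Bohr radius"][0] ** 2)
    )
    / (2.0 * math.pi * _c.c * 100.0)
)


def kcalmol_to_cm1(x: float) -> float:
    """Convert kcal/mol to cm^-1 (chemical accuracy, 1 kcal/mol, is ~350 cm^-1)."""
    return x * CM1_PER_KCALMOL


def fs_to_natural(t_fs: float) -> float:
    """Convert a time in femtoseconds to the hbar=1 / cm^-1 natural time unit."""
    return t_fs / NATURAL_TIME_FS
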