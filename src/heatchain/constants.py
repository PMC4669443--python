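"""Physical constants and unit conversions.

The physical unit family used throughout is (eV, nm, u, K).  The implied
time unit is t0 = sqrt(u nm^2 / eV) ~ 101.8 fs, so that a mass in u, a
stiffness in eV/nm^2 and a friction coefficient in u/t0 are mutually
consistent without conversion factors inside the dynamics.
"""

import math

#: Boltzmann constant in eV/K.
KB_EV_PER_K = 8.617333262e-5

#: One internal time unit t0 = sqrt(u nm^2/eV), expressed in femtoseconds.
T0_FS = math.sqrt(1.66053906660e-27 / 1.602176634e-19) * 1.0e-9 / 1.0e-15


def fs_to_internal(t_fs: float) -> float:
    """Convert a time in femtoseconds to internal units of t0."""
    return t_fs / T0_FS


def internal_to_fs(t_internal: float) -> float:
    return t_internal * T0_FS
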