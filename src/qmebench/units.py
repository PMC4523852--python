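"""Spectroscopic unit conversions.

The package works internally with ħ = 1, time in femtoseconds and every
energy expressed as an angular frequency in rad/fs.  All user-facing
parameters are wavenumbers (cm⁻¹) and temperatures (K).  The conversion
ω = 2πc·ν̃ pins the convention: a cutoff of 50 cm⁻¹ corresponds to a bath
relaxation time 1/ω ≈ 106 fs, and 20 cm⁻¹ to ≈ 265 fs.
"""

from __future__ import annotations

import numpy as np

#: speed of light in cm/fs
SPEED_OF_LIGHT_CM_PER_FS = 2.99792458e-5

#: k_B/(h c) in cm⁻¹ per kelvin (CODATA)
KB_WAVENUMBER_PER_KELVIN = 0.6950348004


def wavenumber_to_angular(nu_cm):
    """Convert a wavenumber in cm⁻¹ to an angular frequency in rad/fs."""
    nu_cm = np.asarray(nu_cm, dtype=float)
    if not np.all(np.isfinite(nu_cm)):
        raise ValueError("wavenumber must be finite")
    out = 2.0 * np.pi * SPEED_OF_LIGHT_CM_PER_FS * nu_cm
    return out if out.ndim else float(out)


def angular_to_wavenumber(omega_rad_fs):
    """Inverse of :func:`wavenumber_to_angular`."""
    omega = np.asarray(omega_rad_fs, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("angular frequency must be finite")
    out = omega / (2.0 * np.pi * SPEED_OF_LIGHT_CM_PER_FS)
    return out if out.ndim else float(out)


def thermal_wavenumber(T_kelvin: float) -> float:
    """k_B·T expressed as a wavenumber (cm⁻¹).

    Raises ``ValueError`` for non-positive temperatures.
    """
    if not np.isfinite(T_kelvin) or T_kelvin <= 0:
        raise ValueError(f"temperature must be positive, got {T_kelvin}")
    return KB_WAVENUMBER_PER_KELVIN * float(T_kelvin)


def thermal_angular(T_kelvin: float) -> float:
    """k_B·T as an angular frequency (rad/fs, ħ = 1)."""
    return wavenumber_to_angular(thermal_wavenumber(T_kelvin))


def inverse_temperature_fs(T_kelvin: float) -> float:
    """β = ħ/(k_B T) in fs (ħ = 1 internal units)."""
    return 1.0 / thermal_angular(T_kelvin)
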