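"""Physical constants and unit conventions.

Internal units are fixed throughout the package: length in Å, time in fs,
mass in amu (unified atomic mass units) and temperature in K.  The derived
energy unit is therefore amu·Å²/fs² (≈ 103.64 eV).  Frequencies are carried
internally in fs⁻¹ and converted to wavenumbers (cm⁻¹) only at the spectrum
boundary, through the exact CODATA speed of light.
"""

#: Boltzmann constant in amu·Å²/fs²/K (CODATA 2018, exact k_B / exact amu).
KB = 8.31446261815324e-7

#: Speed of light in cm/fs (exact).
C_CM_PER_FS = 2.99792458e-5

#: Conversion: 1 fs⁻¹ expressed in cm⁻¹ (= 1 / C_CM_PER_FS).
FS_INV_TO_CM = 1.0 / C_CM_PER_FS

TWO_PI = 6.283185307179586


def frequency_to_wavenumber(f_fs: float) -> float:
    """Convert an ordinary frequency in fs⁻¹ to a wavenumber in cm⁻¹."""
    return f_fs / C_CM_PER_FS


def wavenumber_to_frequency(nu_cm: float) -> float:
    """Convert a wavenumber in cm⁻¹ to an ordinary frequency in fs⁻¹."""
    return nu_cm * C_CM_PER_FS


def wavenumber_to_angular(nu_cm: float) -> float:
    """Convert a wavenumber in cm⁻¹ to an angular frequency in rad/fs."""
    return TWO_PI * C_CM_PER_FS * nu_cm


def angular_to_wavenumber(omega: float) -> float:
    """Convert an angular frequency in rad/fs to a wavenumber in cm⁻¹."""
    return omega / (TWO_PI * C_CM_PER_FS)
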