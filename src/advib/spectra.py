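"""Vibrational density of states from mass-weighted velocities.

The central quantity is the one-sided power spectral density of the
mass-weighted velocity,

    S(ν̃) = Σ_a m_a Σ_i PSD[v_{a,i}](ν̃),

on a wavenumber grid (cm⁻¹).  The normalisation convention is fixed so that
∫ S dν̃ equals the time-mean of Σ_a m_a |v_a|², i.e. twice the mean kinetic
energy of the selected atoms.  Under equipartition each thermalised mode
then carries k_B·T of integrated weight, so band integrals divided by k_B·T
count modes directly.

The same spectrum can be reached through the mass-weighted velocity
autocorrelation function (VACF): by the Wiener–Khintchine theorem the cosine
transform of the unbiased VACF with a full-length Bartlett lag window is
*identical* to the rectangular-window periodogram, which the test-suite
exploits as an internal consistency oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .constants import C_CM_PER_FS, KB
from .errors import PreconditionError
from .trajectory import AtomSelection, Trajectory, full_selection

__all__ = [
    "Spectrum",
    "Correlation",
    "DEFAULT_BANDS",
    "mass_weighted_psd",
    "vacf",
    "psd_from_vacf",
    "band_mode_count",
    "normalize_per_adsorbate",
    "normalize_unit_area",
]

#: Default analysis bands (cm⁻¹): substrate phonons, frustrated modes give
#: way to the fingerprint region, then CH2 and NH2 stretches.
DEFAULT_BANDS = {
    "phonon": (0.0, 250.0),
    "fingerprint": (500.0, 1550.0),
    "ch2_stretch": (2850.0, 3200.0),
    "nh2_stretch": (3200.0, 3650.0),
}


@dataclass
class Spectrum:
    """Intensity on a strictly increasing wavenumber grid.

    ``intensity`` units depend on normalisation: for ``raw`` it is
    amu·Å²/fs² per cm⁻¹ under the convention stated in the module docstring.
    """

    wavenumbers: np.ndarray        # (n,) cm⁻¹
    intensity: np.ndarray          # (n,)
    normalization: str = "raw"     # raw | per_adsorbate | unit_area
    window: str = "hann"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumbers.shape != self.intensity.shape:
            raise PreconditionError("grid/intensity shape mismatch")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise PreconditionError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise PreconditionError("intensity contains non-finite values")

    @property
    def resolution(self) -> float:
        """Grid spacing, cm⁻¹."""
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.wavenumbers))

    def peak_wavenumber(self, band: tuple[float, float] | None = None) -> float:
        """Wavenumber of the intensity maximum (optionally within a band)."""
        w, s = self.wavenumbers, self.intensity
        if band is not None:
            m = (w >= band[0]) & (w <= band[1])
            if not m.any():
                raise PreconditionError("band outside spectrum grid")
            w, s = w[m], s[m]
        return float(w[np.argmax(s)])


@dataclass
class Correlation:
    """Mass-weighted velocity autocorrelation C(τ), amu·Å²/fs²."""

    lags: np.ndarray              # (L+1,) fs, starting at 0
    values: np.ndarray
    timestep: float
    n_samples: int                # frames of the source series

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


def _selected_velocities(traj: Trajectory, selection: AtomSelection | None,
                         detrend: bool = True):
    if traj.velocities is None:
        raise PreconditionError(
            "trajectory has no velocities; run derive_velocities first")
    sel = selection if selection is not None else full_selection(traj)
    sel.validate(traj.n_atoms)
    idx = sel.asarray()
    v = traj.velocities[:, idx, :]
    if detrend:
        v = v - v.mean(axis=0, keepdims=True)   # remove per-atom drift
    m = traj.masses[idx]
    return v, m


def mass_weighted_psd(traj: Trajectory,
                      selection: AtomSelection | None = None,
                      window: str = "hann",
                      segments: int = 1,
                      detrend: bool = True) -> Spectrum:
    """One-sided mass-weighted velocity power spectral density.

    Parameters
    ----------
    window
        ``"hann"`` (default, suppresses leakage) or ``"none"`` (rectangular;
        required for exact Wiener–Khintchine/Parseval identities).
    segments
        Number of non-overlapping Welch segments to average; more segments
        trade frequency resolution for lower estimator variance.
    """
    v, m = _selected_velocities(traj, selection, detrend)
    n = v.shape[0]
    if segments < 1 or n // segments < 2:
        raise PreconditionError("not enough frames for the requested segments")
    win = "boxcar" if window in (None, "none") else window
    nperseg = n // segments
    fs = 1.0 / traj.timestep
    f, S = signal.welch(v, fs=fs, window=win, nperseg=nperseg, noverlap=0,
                        detrend=False, scaling="density", axis=0)
    intensity = np.einsum("fac,a->f", S, m)
    # change of variable f [fs⁻¹] → ν̃ [cm⁻¹] keeps the integral invariant
    return Spectrum(wavenumbers=f / C_CM_PER_FS,
                    intensity=intensity * C_CM_PER_FS,
                    normalization="raw",
                    window="none" if win == "boxcar" else win,
                    metadata={"segments": segments, "n_frames": n,
                              "timestep_fs": traj.timestep,
                              "convention": "integral = 2<KE>"})


def vacf(traj: Trajectory,
         selection: AtomSelection | None = None,
         max_lag: float | None = None,
         detrend: bool = True) -> Correlation:
    """Unbiased mass-weighted velocity autocorrelation function.

    C(τ) = ⟨Σ_a m_a v_a(t)·v_a(t+τ)⟩_t with the unbiased 1/(N−τ) time
    average, computed by FFT.  ``max_lag`` (fs) defaults to the full span
    (N−1 steps); C(0) equals twice the mean mass-weighted kinetic energy.
    """
    v, m = _selected_velocities(traj, selection, detrend)
    n = v.shape[0]
    if max_lag is None:
        lmax = n - 1
    else:
        if max_lag >= traj.duration:
            raise PreconditionError("max_lag must be below the duration")
        lmax = int(max_lag / traj.timestep)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    F = np.fft.rfft(v, n=nfft, axis=0)
    acf = np.fft.irfft(F * np.conj(F), n=nfft, axis=0)[:lmax + 1]
    acf /= (n - np.arange(lmax + 1))[:, None, None]      # unbiased
    values = np.einsum("lac,a->l", acf, m)
    return Correlation(lags=traj.timestep * np.arange(lmax + 1),
                       values=values, timestep=traj.timestep, n_samples=n)


def psd_from_vacf(corr: Correlation, window: str = "bartlett") -> Spectrum:
    """One-sided PSD as the cosine transform of a lag-windowed VACF.

    With the default full-length Bartlett lag window the result equals the
    rectangular-window periodogram exactly (Wiener–Khintchine); a Hann lag
    window gives a smoothed (Blackman–Tukey) estimate.
    """
    c = corr.values
    L = len(c) - 1
    tau = np.arange(L + 1)
    if window in (None, "none"):
        w = np.ones(L + 1)
    elif window == "bartlett":
        w = 1.0 - tau / corr.n_samples
    elif window == "hann":
        w = 0.5 * (1.0 + np.cos(np.pi * tau / (L + 1)))
    else:
        raise PreconditionError(f"unknown lag window {window!r}")
    cw = c * w
    # two-sided spectrum of the symmetric extension, evaluated by FFT on the
    # periodogram grid of the original N-sample record
    nfft = corr.n_samples
    if L + 1 > nfft:
        raise PreconditionError("more lags than source samples")
    spec2 = 2.0 * np.real(np.fft.rfft(cw, n=nfft)) - cw[0]
    dt = corr.timestep
    S_f = dt * spec2
    f = np.fft.rfftfreq(nfft, d=dt)
    one_sided = 2.0 * S_f
    one_sided[0] = S_f[0]
    if nfft % 2 == 0:
        one_sided[-1] = S_f[-1]
    return Spectrum(wavenumbers=f / C_CM_PER_FS,
                    intensity=one_sided * C_CM_PER_FS,
                    normalization="raw", window=f"vacf-{window}",
                    metadata={"route": "wiener-khintchine",
                              "convention": "integral = 2<KE>"})


def band_mode_count(spec: Spectrum, band: tuple[float, float], T: float) -> float:
    """Effective number of modes in a wavenumber band at temperature T.

    Integrates the raw-convention spectrum over [ν_lo, ν_hi] and divides by
    k_B·T, the per-mode integrated weight under equipartition (each mode
    carries ½k_B·T of kinetic energy, and the convention counts 2×KE).
    """
    if spec.normalization not in ("raw", "per_adsorbate"):
        raise PreconditionError("band_mode_count needs a raw-convention spectrum")
    if T <= 0:
        raise PreconditionError("temperature must be positive")
    lo, hi = band
    w = spec.wavenumbers
    if hi <= lo or lo > w[-1] or hi < w[0]:
        raise PreconditionError(f"band {band} outside spectrum grid")
    m = (w >= lo) & (w <= hi)
    if m.sum() < 2:
        raise PreconditionError("band covers fewer than 2 grid points")
    integral = np.trapezoid(spec.intensity[m], w[m])
    return float(integral / (KB * T))


def normalize_per_adsorbate(spec: Spectrum, n_adsorbates: int) -> Spectrum:
    """Divide intensity by the number of adsorbate molecules in the cell."""
    if n_adsorbates < 1:
        raise PreconditionError("n_adsorbates must be >= 1")
    return Spectrum(wavenumbers=spec.wavenumbers.copy(),
                    intensity=spec.intensity / n_adsorbates,
                    normalization="per_adsorbate", window=spec.window,
                    metadata={**spec.metadata, "n_adsorbates": n_adsorbates})


def normalize_unit_area(spec: Spectrum) -> Spectrum:
    """Rescale so the spectrum integrates to exactly 1."""
    area = spec.integral()
    if area <= 0:
        raise PreconditionError("cannot unit-normalize a zero spectrum")
    return Spectrum(wavenumbers=spec.wavenumbers.copy(),
                    intensity=spec.intensity / area,
                    normalization="unit_area", window=spec.window,
                    metadata=dict(spec.metadata))
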